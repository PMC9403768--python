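"""Epoch construction, feature extraction, SVC decoding and the
circular-shift null."""

import collections

import numpy as np
import pandas as pd
import pytest

from csds_lfp.decoder import (
    DecoderDataset,
    build_epochs,
    circular_shift_null,
    decode_with_null,
    extract_features,
    train_eval,
    _shifted_labels,
)
from conftest import make_session


def _visit_session(visits, dt=0.5):
    """With-CD1 zone visits: list of (zone, duration s); the No-CD1 phase is
    filled with 'other'."""
    total = sum(d for _, d in visits)
    seq = ["other"] * int(total / dt)
    for zone, d in visits:
        seq.extend([zone] * int(d / dt))
    return make_session(seq, dt=dt, phase_duration=total)


def _noise_dataset(rng, n_animals=8, per_animal=30, n_features=10, labels=None):
    n = n_animals * per_animal
    states = labels if labels is not None else rng.choice(
        ["control|interaction", "control|corner", "defeated|interaction", "defeated|corner"],
        size=n,
    )
    return DecoderDataset(
        features=rng.standard_normal((n, n_features)),
        labels=np.asarray(states, dtype=object),
        animal_ids=np.repeat([f"a{i}" for i in range(n_animals)], per_animal),
        start_times=np.tile(np.arange(per_animal, dtype=float), n_animals),
        feature_names=tuple(f"f{i:02d}" for i in range(n_features)),
    )


class TestBuildEpochs:
    def test_floor_division_of_visit(self):
        sess = _visit_session([("corner", 12.0)])
        tab = build_epochs([("a1", "control", sess)], epoch_length=5.0).table
        assert len(tab) == 2
        assert (tab["state"] == "control|corner").all()

    def test_short_visit_yields_nothing(self):
        sess = _visit_session([("corner", 4.5), ("interaction", 30.0)])
        tab = build_epochs([("a1", "control", sess)], epoch_length=5.0).table
        assert (tab["zone"] == "interaction").all()

    def test_non_susceptible_defeated_excluded(self):
        # interaction time with CD1 exceeds without -> SI ratio > 1
        seq = ["interaction"] * 40 + ["other"] * 40  # No-CD1: 20 s interaction
        seq += ["interaction"] * 60 + ["corner"] * 20  # With-CD1: 30 s interaction
        sess = make_session(seq, dt=0.5)
        with pytest.raises(ValueError, match="no eligible"):
            build_epochs([("d1", "defeated", sess)], epoch_length=5.0)

    def test_no_eligible_epochs_raises(self):
        sess = _visit_session([("corner", 3.0)])
        with pytest.raises(ValueError, match="no eligible"):
            build_epochs([("a1", "control", sess)], epoch_length=5.0)


class TestExtractFeatures:
    def _epochs_and_z(self, z_value=2.0):
        sess = _visit_session([("corner", 12.0), ("corner", 12.0)])
        epochs = build_epochs([("a1", "control", sess)], epoch_length=5.0)
        t0, t1 = sess.phases["with_cd1"]
        times = np.arange(t0, t1, 0.25)
        z = np.full((5, len(times)), z_value)
        return epochs, {"a1": (times, z)}

    def test_constant_z_gives_mean_and_zero_sd(self):
        epochs, band_z = self._epochs_and_z(2.0)
        ds = extract_features(epochs, band_z)
        assert ds.features.shape[1] == 10
        assert np.allclose(ds.features[:, 0::2], 2.0)  # per-band means
        assert np.allclose(ds.features[:, 1::2], 0.0)  # per-band SDs

    def test_identical_epochs_identical_rows(self):
        epochs, band_z = self._epochs_and_z(1.3)
        ds = extract_features(epochs, band_z)
        assert np.allclose(ds.features[0], ds.features[1])

    def test_ten_columns_for_any_five_band_config(self):
        epochs, band_z = self._epochs_and_z()
        ds = extract_features(epochs, band_z, band_names=["x1", "x2", "x3", "x4", "x5"])
        assert ds.features.shape[1] == 10
        assert ds.feature_names[:2] == ("x1_mean", "x1_sd")


class TestTrainEval:
    def test_separable_clusters_decode_perfectly(self):
        rng = np.random.default_rng(0)
        centers = np.eye(4)[:, :4] * 10  # inter-mean distance ~10 SD
        feats, labels = [], []
        for i, lab in enumerate(
            ["control|interaction", "control|corner", "defeated|interaction", "defeated|corner"]
        ):
            feats.append(rng.standard_normal((40, 10)) + np.pad(centers[i], (0, 6)))
            labels += [lab] * 40
        ds = DecoderDataset(
            features=np.vstack(feats),
            labels=np.array(labels, dtype=object),
            animal_ids=np.array(["a"] * 160),
            start_times=np.arange(160.0),
            feature_names=tuple(f"f{i}" for i in range(10)),
        )
        assert train_eval(ds, seed=1) == 100.0

    def test_chance_level_for_label_independent_features(self):
        rng = np.random.default_rng(1)
        accs = [train_eval(_noise_dataset(rng, per_animal=50), seed=s) for s in range(50)]
        sem = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 25.0) <= 3 * sem + 1.0

    def test_deterministic_given_seed(self):
        ds = _noise_dataset(np.random.default_rng(2))
        assert train_eval(ds, seed=7) == train_eval(ds, seed=7)

    def test_single_class_rejected(self):
        ds = _noise_dataset(np.random.default_rng(3), labels=["defeated|corner"] * 240)
        with pytest.raises(ValueError):
            train_eval(ds, seed=0)


class TestCircularShift:
    def test_identity_offsets_keep_labels(self):
        ds = _noise_dataset(np.random.default_rng(4))
        rng = np.random.default_rng(0)
        same = _shifted_labels(ds, rng, offsets={f"a{i}": 0 for i in range(8)})
        assert np.array_equal(same, ds.labels)
        full = _shifted_labels(ds, rng, offsets=ds.n_epochs, scope="global")
        assert np.array_equal(full, ds.labels)

    def test_shift_preserves_label_multiset(self):
        ds = _noise_dataset(np.random.default_rng(5))
        rng = np.random.default_rng(1)
        for scope in ("animal", "global"):
            shifted = _shifted_labels(ds, rng, scope=scope)
            assert collections.Counter(shifted) == collections.Counter(ds.labels)
            if scope == "animal":
                # group identity is an animal property: it survives shifting
                for aid in np.unique(ds.animal_ids):
                    m = ds.animal_ids == aid
                    orig = {l.split("|")[0] for l in ds.labels[m]}
                    new = {l.split("|")[0] for l in shifted[m]}
                    assert new == orig

    def test_null_distribution_bookkeeping(self):
        ds = _noise_dataset(np.random.default_rng(6))
        null = circular_shift_null(ds, n_shifts=2, seed=0)
        assert null.shape == (2,)

    def test_single_epoch_animal_left_unshifted(self):
        ds = _noise_dataset(np.random.default_rng(7), n_animals=2, per_animal=1)
        rng = np.random.default_rng(2)
        assert np.array_equal(_shifted_labels(ds, rng), ds.labels)


class TestDecodeWithNull:
    def test_separable_data_maximally_significant(self):
        # aperiodic labels with a 12-SD feature offset: real decoding is
        # perfect and every shift misaligns at least part of the sequence
        rng = np.random.default_rng(8)
        labels = rng.choice(["control|interaction", "defeated|corner"], size=240)
        ds = _noise_dataset(rng, labels=np.array(labels, dtype=object))
        ds.features[ds.labels == "control|interaction", 0] += 12.0
        res = decode_with_null(ds, n_repeats=3, n_shifts=50, seed=0)
        assert res.real_mean > 95.0
        assert res.empirical_p == pytest.approx(1 / 51)
        assert res.null_mean < res.real_mean

    def test_label_independent_features_not_significant(self):
        misses = 0
        for s in range(20):
            ds = _noise_dataset(np.random.default_rng(100 + s), n_animals=6, per_animal=20)
            res = decode_with_null(ds, n_repeats=3, n_shifts=40, seed=s)
            misses += res.empirical_p > 0.05
        assert misses >= 16

    def test_sem_shrinks_with_repeats(self):
        rng = np.random.default_rng(9)
        ds = _noise_dataset(rng)
        ds.features[:, 0] += np.where(ds.labels == "defeated|corner", 1.5, 0.0)
        r_small = decode_with_null(ds, n_repeats=8, n_shifts=2, seed=1)
        r_big = decode_with_null(ds, n_repeats=128, n_shifts=2, seed=1)
        ratio = r_small.real_sem / r_big.real_sem
        assert 2 <= ratio <= 8  # expected factor 4 = sqrt(128/8)
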