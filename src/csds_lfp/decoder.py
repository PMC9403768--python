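"""Decoding the four social behavioral states from LFP band power.

Epochs are fixed-length (default 5 s) tiles of contiguous interaction- or
corner-zone visits during the With-CD1 phase; each carries one of four
state labels, {control, defeated} x {interaction, corner}.  Only defeated
animals that are susceptible (interaction-zone SI ratio < 1) contribute.
Features are, per epoch, the mean and within-epoch SD of the
channel-averaged z-scored band power in each of the five analysis bands
(10 features).  A support-vector classifier with a quadratic (degree-2
polynomial) kernel is trained on a random 80% split and scored on the held
out 20%; significance is assessed against a circular-shift null that
rotates each animal's time-ordered label sequence by a random offset,
preserving label autocorrelation and exact class counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .behavior import (
    PHASE_WITH_CD1,
    ZONE_CORNER,
    ZONE_INTERACTION,
    zone_times,
    is_susceptible,
    social_interaction_ratio,
)
from .spectral import CANONICAL_BANDS, session_band_z

logger = logging.getLogger(__name__)

#: Quadratic-kernel SVC hyperparameters, recorded alongside every result.
SVC_PARAMS = dict(kernel="poly", degree=2, C=1.0, coef0=1.0, gamma="scale")


@dataclass
class EpochTable:
    """Non-overlapping fixed-length epochs with behavioral-state labels.

    ``table`` columns: epoch_id, animal_id, group, zone, state, start_s,
    end_s; state is "<group>|<zone>".
    """

    table: pd.DataFrame
    epoch_length: float


@dataclass
class DecoderDataset:
    """Feature matrix (epochs x 10) with state labels and animal ids,
    time-ordered within animal."""

    features: np.ndarray
    labels: np.ndarray
    animal_ids: np.ndarray
    start_times: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def base_rate_pct(self) -> float:
        _, counts = np.unique(self.labels, return_counts=True)
        return 100.0 * counts.max() / counts.sum()


@dataclass
class DecoderResult:
    """Real vs circular-shift-null decoding accuracy (percent)."""

    real_accuracies: np.ndarray
    null_accuracies: np.ndarray
    empirical_p: float
    base_rate_pct: float
    per_class_recall: dict[str, float]
    svc_params: dict = field(default_factory=lambda: dict(SVC_PARAMS))
    seed: int | None = None

    @property
    def real_mean(self) -> float:
        return float(np.mean(self.real_accuracies))

    @property
    def real_sem(self) -> float:
        n = len(self.real_accuracies)
        return float(np.std(self.real_accuracies, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_accuracies))

    @property
    def null_sem(self) -> float:
        n = len(self.null_accuracies)
        return float(np.std(self.null_accuracies, ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def state_label(group: str, zone: str) -> str:
    return f"{group}|{zone}"


def build_epochs(
    sessions: Sequence[tuple[str, str, "BehaviorSession"]],
    epoch_length: float = 5.0,
) -> EpochTable:
    """Tile contiguous With-CD1 interaction/corner visits into epochs.

    ``sessions`` holds (animal_id, group, behavior) triples.  A visit of
    duration d yields floor(d / epoch_length) epochs.  Defeated animals with
    an SI ratio >= 1 (non-susceptible) are excluded, mirroring the
    susceptible-only analysis convention.
    """
    rows = []
    eid = 0
    for animal_id, group, session in sessions:
        t_no = zone_times(session, "no_cd1")
        t_with = zone_times(session, PHASE_WITH_CD1)
        if group == "defeated":
            ratio = social_interaction_ratio(
                t_with[ZONE_INTERACTION], t_no[ZONE_INTERACTION]
            )
            if not is_susceptible(ratio):
                logger.info("excluding non-susceptible animal %s (SI=%.3f)", animal_id, ratio)
                continue
        t0, t1 = session.phases[PHASE_WITH_CD1]
        t = session.track["time_s"].to_numpy()
        mask = (t >= t0) & (t < t1)
        times = t[mask]
        zones = session.zone_labels()[mask]
        if len(times) == 0:
            continue
        # contiguous runs of constant zone label
        change = np.flatnonzero(zones[1:] != zones[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(zones)]))
        for s, e in zip(starts, ends):
            zone = zones[s]
            if zone not in (ZONE_INTERACTION, ZONE_CORNER):
                continue
            run_start = times[s]
            run_end = times[e] if e < len(times) else t1
            n_ep = int((run_end - run_start) // epoch_length)
            for k in range(n_ep):
                rows.append(
                    dict(
                        epoch_id=eid,
                        animal_id=animal_id,
                        group=group,
                        zone=zone,
                        state=state_label(group, zone),
                        start_s=run_start + k * epoch_length,
                        end_s=run_start + (k + 1) * epoch_length,
                    )
                )
                eid += 1
    if not rows:
        raise ValueError("no eligible epochs in any session")
    return EpochTable(table=pd.DataFrame(rows), epoch_length=epoch_length)


def extract_features(
    epochs: EpochTable,
    band_z: dict[str, tuple[np.ndarray, np.ndarray]],
    band_names: Sequence[str] | None = None,
) -> DecoderDataset:
    """Mean and within-epoch SD of z-band-power per band, per epoch.

    ``band_z`` maps animal_id -> (bin_times, z) with z of shape
    (n_bands, n_bins), as returned by :func:`csds_lfp.spectral.session_band_z`.
    Features are ordered (band1 mean, band1 sd, band2 mean, ...).
    """
    band_names = list(band_names or [b.name for b in CANONICAL_BANDS])
    feature_names = tuple(
        f"{b}_{stat}" for b in band_names for stat in ("mean", "sd")
    )
    feats = []
    df = epochs.table.sort_values(["animal_id", "start_s"], kind="stable")
    for _, row in df.iterrows():
        times, z = band_z[row["animal_id"]]
        mask = (times >= row["start_s"]) & (times < row["end_s"])
        if not mask.any():
            raise ValueError(f"epoch {row['epoch_id']} covers no spectrogram bins")
        sub = z[:, mask]
        feats.append(np.column_stack((sub.mean(axis=1), sub.std(axis=1))).ravel())
    return DecoderDataset(
        features=np.asarray(feats),
        labels=df["state"].to_numpy(),
        animal_ids=df["animal_id"].to_numpy(),
        start_times=df["start_s"].to_numpy(),
        feature_names=feature_names,
    )


def train_eval(dataset: DecoderDataset, train_fraction: float = 0.8, seed=None) -> float:
    """One 80/20 split -> held-out accuracy (%).

    Standardization statistics come from the training split only.  If a
    random split leaves a class out of the training set it is re-drawn, up
    to 100 times.
    """
    classes = np.unique(dataset.labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = dataset.n_epochs
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError("train fraction leaves an empty split")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(np.unique(dataset.labels[train])) == len(classes):
            break
    else:
        raise RuntimeError("could not draw a split containing every class in training")
    scaler = StandardScaler().fit(dataset.features[train])
    clf = SVC(**SVC_PARAMS)
    clf.fit(scaler.transform(dataset.features[train]), dataset.labels[train])
    pred = clf.predict(scaler.transform(dataset.features[test]))
    return 100.0 * float(np.mean(pred == dataset.labels[test]))


def _shifted_labels(
    dataset: DecoderDataset,
    rng: np.random.Generator,
    offsets=None,
    scope: str = "animal",
) -> np.ndarray:
    """Rotate time-ordered label sequences by a random offset, keeping
    features fixed.

    ``scope="animal"`` (default) rolls each animal's own sequence by an
    offset in 1..n-1, preserving within-animal label autocorrelation;
    ``scope="global"`` rolls the one concatenated sequence (animals in
    stable order), which also decouples labels from animal identity.
    """
    labels = dataset.labels.copy()
    if scope == "global":
        order = np.lexsort((dataset.start_times, dataset.animal_ids))
        n = len(order)
        off = offsets if isinstance(offsets, int) else int(rng.integers(1, n))
        labels[order] = np.roll(dataset.labels[order], off)
        return labels
    if scope != "animal":
        raise ValueError(f"unknown shift scope {scope!r}")
    for aid in np.unique(dataset.animal_ids):
        idx = np.flatnonzero(dataset.animal_ids == aid)
        order = idx[np.argsort(dataset.start_times[idx], kind="stable")]
        if len(order) < 2:
            logger.info("animal %s has <2 epochs; excluded from shifting", aid)
            continue
        if offsets is not None:
            off = offsets.get(aid, 0)
        else:
            off = int(rng.integers(1, len(order)))
        labels[order] = np.roll(dataset.labels[order], off)
    return labels


def circular_shift_null(
    dataset: DecoderDataset,
    n_shifts: int = 1000,
    seed=None,
    train_fraction: float = 0.8,
    offsets=None,
    scope: str = "animal",
) -> np.ndarray:
    """Null accuracy distribution: per shift, rotate the time-ordered label
    sequence (within animal by default, or globally with ``scope="global"``)
    and retrain/re-score the decoder.  Shifting preserves the label multiset
    exactly, so the null base rate equals the real one."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    shift_seeds = ss.spawn(n_shifts)
    accs = np.empty(n_shifts)
    for i, child in enumerate(shift_seeds):
        rng = np.random.default_rng(child)
        shifted = DecoderDataset(
            features=dataset.features,
            labels=_shifted_labels(dataset, rng, offsets=offsets, scope=scope),
            animal_ids=dataset.animal_ids,
            start_times=dataset.start_times,
            feature_names=dataset.feature_names,
        )
        accs[i] = train_eval(shifted, train_fraction, seed=rng)
    return accs


def _per_class_recall(dataset: DecoderDataset, seed, train_fraction: float) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    n = dataset.n_epochs
    n_train = int(round(train_fraction * n))
    classes = np.unique(dataset.labels)
    for _ in range(100):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(np.unique(dataset.labels[train])) == len(classes):
            break
    scaler = StandardScaler().fit(dataset.features[train])
    clf = SVC(**SVC_PARAMS)
    clf.fit(scaler.transform(dataset.features[train]), dataset.labels[train])
    pred = clf.predict(scaler.transform(dataset.features[test]))
    out = {}
    for c in classes:
        m = dataset.labels[test] == c
        out[str(c)] = float(np.mean(pred[m] == c)) if m.any() else float("nan")
    return out


def decode_with_null(
    dataset: DecoderDataset,
    n_repeats: int = 20,
    n_shifts: int = 1000,
    seed=None,
    train_fraction: float = 0.8,
    scope: str = "global",
) -> DecoderResult:
    """Full decoding readout: real accuracy (mean +/- SEM over random
    splits), circular-shift null distribution, and the empirical p-value
    p = (1 + #{null >= real mean}) / (n_shifts + 1).

    The null defaults to the global-sequence shift, under which the shuffled
    labels are decoupled from animal identity as well as from time, so the
    null accuracy falls toward the majority-class base rate; per-animal
    shifting (``scope="animal"``) is stricter in that group identity, an
    animal-level property, survives it.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_real, s_null, s_recall = ss.spawn(3)
    real = np.array(
        [train_eval(dataset, train_fraction, seed=c) for c in s_real.spawn(n_repeats)]
    )
    null = circular_shift_null(
        dataset, n_shifts, seed=s_null, train_fraction=train_fraction, scope=scope
    )
    real_mean = float(real.mean())
    p = (1 + int(np.sum(null >= real_mean))) / (n_shifts + 1)
    return DecoderResult(
        real_accuracies=real,
        null_accuracies=null,
        empirical_p=p,
        base_rate_pct=dataset.base_rate_pct(),
        per_class_recall=_per_class_recall(dataset, s_recall, train_fraction),
        seed=seed if isinstance(seed, int) else None,
    )


def cohort_dataset(
    animals,
    bands=CANONICAL_BANDS,
    epoch_length: float = 5.0,
    mode: str = "session",
    **stft_kwargs,
) -> DecoderDataset:
    """Convenience: epochs + features for a simulated cohort (animals with
    ``animal_id``, ``group``, ``behavior`` and ``lfp`` attributes)."""
    sessions = [(a.animal_id, a.group, a.behavior) for a in animals]
    epochs = build_epochs(sessions, epoch_length=epoch_length)
    keep = set(epochs.table["animal_id"])
    band_z = {
        a.animal_id: session_band_z(a.lfp, bands, mode=mode, **stft_kwargs)
        for a in animals
        if a.animal_id in keep
    }
    return extract_features(epochs, band_z, [b.name for b in bands])
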