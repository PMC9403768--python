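"""Synthetic cohort generator: determinism, calibration, effect injection."""

import numpy as np
import pytest

from csds_lfp.behavior import (
    is_susceptible,
    social_interaction_ratio,
    summaries_to_frame,
    summarize_behavior,
    zone_times,
)
from csds_lfp.cohort import (
    DEFAULT_ASSAY_PARAMS,
    CohortConfig,
    ConfigError,
    simulate_assays,
    simulate_behavior,
    simulate_cohort,
    simulate_lfp,
)
from csds_lfp.spectral import band_power_summary, band_power, compute_spectrogram


class TestConfigValidation:
    def test_empty_cohort(self):
        cfg = CohortConfig(n_control=0, n_defeat=0, sampling_rate=400, n_channels=1)
        assert simulate_cohort(cfg) == []

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(n_control=-1), "n_control"),
            (dict(session_phase_duration=0), "session_phase_duration"),
            (dict(sampling_rate=100.0), "sampling_rate"),  # Nyquist vs 80 Hz band
            (dict(envelope_smoothing_s=0.1), "envelope_smoothing"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, match):
        with pytest.raises(ConfigError, match=match):
            CohortConfig(**kwargs)

    def test_nonpositive_multiplier_rejected(self):
        effects = {("defeated", "corner", "with_cd1", "2-7Hz"): 0.0}
        with pytest.raises(ConfigError, match="band_effects"):
            CohortConfig(band_effects=effects)


class TestDeterminism:
    def test_identical_seed_bitwise_identical(self, tiny_config):
        a1 = simulate_cohort(tiny_config)
        a2 = simulate_cohort(tiny_config)
        for x, y in zip(a1, a2):
            assert x.animal_id == y.animal_id and x.group == y.group
            assert np.array_equal(x.lfp.samples, y.lfp.samples)
            assert x.behavior.track.equals(y.behavior.track)
            assert x.assays == y.assays

    def test_different_seeds_differ(self, tiny_config):
        import dataclasses

        other = dataclasses.replace(tiny_config, seed=tiny_config.seed + 1)
        a1, a2 = simulate_cohort(tiny_config), simulate_cohort(other)
        assert not np.array_equal(a1[0].lfp.samples, a2[0].lfp.samples)


class TestBehaviorGenerator:
    def test_group_separation_in_si_ratio(self):
        # over 20 small cohorts, defeated mean SI ratio < 1 < control mean
        ok = 0
        for s in range(20):
            cfg = CohortConfig(seed=s, sampling_rate=400, n_channels=1)
            ratios = {"control": [], "defeated": []}
            rng_children = np.random.SeedSequence(s).spawn(16)
            for i, group in enumerate(["control"] * 8 + ["defeated"] * 8):
                beh = simulate_behavior(group, cfg, rng_children[i])
                tn = zone_times(beh, "no_cd1")["interaction"]
                tw = zone_times(beh, "with_cd1")["interaction"]
                ratios[group].append(social_interaction_ratio(tw, tn))
            if np.mean(ratios["defeated"]) < 1 < np.mean(ratios["control"]):
                ok += 1
        assert ok >= 19

    def test_defeated_with_cd1_prefers_corner(self):
        # mean corner/interaction time ratio across simulations is large
        cfg = CohortConfig(sampling_rate=400, n_channels=1)
        corner, inter = [], []
        for s in range(100):
            beh = simulate_behavior("defeated", cfg, 100 + s)
            t = zone_times(beh, "with_cd1")
            corner.append(t["corner"])
            inter.append(t["interaction"])
        assert np.mean(corner) / np.mean(inter) > 3

    def test_symmetric_visit_parameters_give_unit_ratio(self):
        sym = {z: (1 / 3, 2.0) for z in ("interaction", "corner", "other")}
        params = {(g, p): sym for g in ("control", "defeated") for p in ("no_cd1", "with_cd1")}
        cfg = CohortConfig(
            sampling_rate=400, n_channels=1, visit_params=params, occupancy_jitter_sd=0.0
        )
        ratios = []
        for s in range(60):
            beh = simulate_behavior("control", cfg, s)
            tn = zone_times(beh, "no_cd1")["interaction"]
            tw = zone_times(beh, "with_cd1")["interaction"]
            ratios.append(social_interaction_ratio(tw, tn))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_tracking_covers_both_phases(self, tiny_cohort):
        a = tiny_cohort[0]
        dur = a.behavior.track["time_s"].iloc[-1]
        assert dur == pytest.approx(2 * 120.0, abs=0.1)
        assert a.lfp.duration >= dur


class TestAssays:
    def test_zero_sd_degenerates_to_mean(self):
        params = {
            g: dict(p, sucrose_pct_sd=0.0, immobility_sd=0.0)
            for g, p in DEFAULT_ASSAY_PARAMS.items()
        }
        cfg = CohortConfig(sampling_rate=400, n_channels=1, assay_params=params)
        rec = simulate_assays("control", cfg, 0)
        pct = 100 * rec.sucrose_consumption_g / (
            rec.sucrose_consumption_g + rec.water_consumption_g
        )
        assert pct == pytest.approx(77.5475, abs=1e-6)
        assert rec.immobility_s == pytest.approx(76.0125)

    def test_sucrose_calibration_at_group_level(self):
        # 1000 cohorts of n=8: the mean of control sample means stays near
        # the calibrated 77.55% preference
        cfg = CohortConfig(sampling_rate=400, n_channels=1)
        means = []
        for s in range(1000):
            children = np.random.SeedSequence(50_000 + s).spawn(8)
            pcts = []
            for ch in children:
                rec = simulate_assays("control", cfg, ch)
                pcts.append(
                    100 * rec.sucrose_consumption_g
                    / (rec.sucrose_consumption_g + rec.water_consumption_g)
                )
            means.append(np.mean(pcts))
        assert abs(np.mean(means) - 77.55) < 1.0

    def test_defeated_immobility_exceeds_control(self):
        cfg = CohortConfig(sampling_rate=400, n_channels=1)
        wins = 0
        for s in range(300):
            children = np.random.SeedSequence(60_000 + s).spawn(16)
            ctrl = np.mean([simulate_assays("control", cfg, c).immobility_s for c in children[:8]])
            dft = np.mean([simulate_assays("defeated", cfg, c).immobility_s for c in children[8:]])
            wins += dft > ctrl
        assert wins >= 297  # >=99%


class TestLfpGenerator:
    CFG = dict(sampling_rate=200.0, n_channels=1, session_phase_duration=60.0)

    def test_null_effect_matrix_is_stationary(self):
        # all multipliers 1: band power indistinguishable across conditions
        from scipy.stats import ttest_ind

        cfg = CohortConfig(band_effects={}, **self.CFG)
        calm = 0
        n_runs = 100
        for s in range(n_runs):
            beh = simulate_behavior("defeated", cfg, 2 * s)
            lfp = simulate_lfp("defeated", beh, cfg, 2 * s + 1)
            spec = compute_spectrogram(lfp, 0)
            bp = band_power(spec, next(b for b in cfg.bands if b.name == "2-7Hz"))
            half = len(bp) // 2
            a, b = bp[:half:2], bp[half::2]  # No-CD1 vs With-CD1, decimated
            calm += ttest_ind(a, b).pvalue > 0.01
        assert calm >= 95

    def test_injected_suppression_yields_negative_change(self):
        # 2-7 Hz x0.7 in the defeated interaction zone with the CD1 present
        effects = {("defeated", "interaction", "with_cd1", "2-7Hz"): 0.7}
        cfg = CohortConfig(
            sampling_rate=200.0, n_channels=1, band_effects=effects,
        )
        neg = 0
        for s in range(100):
            ss = np.random.SeedSequence(70_000 + s).spawn(2)
            beh = simulate_behavior("defeated", cfg, ss[0])
            lfp = simulate_lfp("defeated", beh, cfg, ss[1])
            tbl = band_power_summary([("a", "defeated", lfp, beh)]).table
            cell = tbl[(tbl.band == "2-7Hz") & (tbl.zone == "interaction")]["change"].iloc[0]
            neg += cell < 0
        assert neg >= 95

    def test_bimodal_low_frequency_spectrum(self):
        # the 2-12 Hz group-mean spectrum carries two distinct peaks
        cfg = CohortConfig(**self.CFG)
        psds = []
        for s in range(4):
            ss = np.random.SeedSequence(80_000 + s).spawn(2)
            beh = simulate_behavior("control", cfg, ss[0])
            lfp = simulate_lfp("control", beh, cfg, ss[1])
            spec = compute_spectrogram(lfp, 0)
            psds.append(spec.power.mean(axis=0))
        mean_psd = np.mean(psds, axis=0)
        freqs = spec.freqs
        smooth = np.convolve(mean_psd, np.ones(5) / 5, mode="same")
        sel = (freqs >= 2) & (freqs <= 12)
        seg, f = smooth[sel], freqs[sel]
        local_max = [
            f[i] for i in range(1, len(seg) - 1) if seg[i] > seg[i - 1] and seg[i] >= seg[i + 1]
        ]
        assert len(local_max) == 2
        assert abs(local_max[0] - 4.0) < 2.0 and abs(local_max[1] - 9.5) < 2.0

    def test_downstream_epoch_count_near_reported_total(self, tiny_cohort):
        # at full phase length the tiling lands near 396 epochs; the
        # 120 s fixture should scale to roughly a fifth of that
        from csds_lfp.decoder import build_epochs

        epochs = build_epochs(
            [(a.animal_id, a.group, a.behavior) for a in tiny_cohort], epoch_length=5.0
        )
        assert 30 <= len(epochs.table) <= 160
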