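"""Synthetic CSDS cohort generator: behavior, assays and LFP.

Generates control and socially-defeated animals whose data carry the
statistical structure the downstream analysis assumes, so the whole
pipeline is testable without any recordings:

* **Behavior** -- a semi-Markov zone-visit process over {interaction,
  corner, other} with exponential dwell times.  Zone-selection propensities
  are calibrated per (group, phase) to the occupancy pattern of a social
  interaction test: defeated animals spend most of the With-CD1 phase in
  the corner zones, controls in the interaction zone.
* **Assays** -- sucrose preference (%) and tail-suspension immobility (s)
  drawn from truncated group-level normals whose means/SDs reproduce the
  expected group separation at n = 8.
* **LFP** -- per channel, a 1/f (pink) background plus band-limited
  oscillations (Gaussian noise band-pass filtered per spectral peak, not
  sinusoids), with instantaneous amplitude scaled by a (group, zone, phase,
  band) effect matrix.  Default peaks near 4 and 9 Hz give the bimodal
  2-12 Hz spectrum; the default effect matrix reproduces the qualitative
  group x zone change-in-power pattern (e.g. defeated animals lose 2-7 Hz
  power and gain 14-30 Hz power in the interaction zone when the aggressor
  is present).

One master seed deterministically spawns per-animal, per-component
substreams, so identical (config, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from .behavior import (
    PHASE_NO_CD1,
    PHASE_WITH_CD1,
    ZONE_CORNER,
    ZONE_INTERACTION,
    ZONE_OTHER,
    ArenaGeometry,
    AssayRecord,
    BehaviorSession,
)
from .spectral import CANONICAL_BANDS, BandDefinition, LfpRecording

GROUP_CONTROL = "control"
GROUP_DEFEAT = "defeated"
GROUPS = (GROUP_CONTROL, GROUP_DEFEAT)


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


#: Zone-visit parameters per (group, phase): ``zone -> (visit probability,
#: mean visit duration s)``.  Expected occupancy fraction of a zone is
#: prob * mean / sum(prob * mean); the defaults reproduce the canonical SIT
#: occupancy pattern (defeated: ~55 s interaction / ~457 s corner out of
#: 600 s with the CD1 present; control the reverse) while also calibrating
#: 5 s epoch tiling: the preferred zone is visited often but briefly, the
#: avoided zone rarely but in long bouts, so every one of the four
#: behavioral states yields a usable number of epochs and the cohort total
#: lands near 396.
DEFAULT_VISIT_PARAMS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    (GROUP_CONTROL, PHASE_NO_CD1): {
        ZONE_INTERACTION: (0.30, 2.869),
        ZONE_CORNER: (0.12, 2.907),
        ZONE_OTHER: (0.58, 1.363),
    },
    (GROUP_DEFEAT, PHASE_NO_CD1): {
        ZONE_INTERACTION: (0.35, 2.870),
        ZONE_CORNER: (0.20, 2.693),
        ZONE_OTHER: (0.45, 1.016),
    },
    (GROUP_CONTROL, PHASE_WITH_CD1): {
        ZONE_INTERACTION: (0.55, 0.743),
        ZONE_CORNER: (0.004, 7.605),
        ZONE_OTHER: (0.446, 0.362),
    },
    (GROUP_DEFEAT, PHASE_WITH_CD1): {
        ZONE_INTERACTION: (0.004, 14.97),
        ZONE_CORNER: (0.55, 0.901),
        ZONE_OTHER: (0.446, 0.212),
    },
}

#: Assay distribution parameters per group.  SDs are the reported SEMs
#: scaled by sqrt(8) (the study never states within-group SDs directly).
DEFAULT_ASSAY_PARAMS: dict[str, dict[str, float]] = {
    GROUP_CONTROL: {
        "sucrose_pct_mean": 77.5475,
        "sucrose_pct_sd": 2.4564,
        "immobility_mean": 76.0125,
        "immobility_sd": 5.5298,
    },
    GROUP_DEFEAT: {
        "sucrose_pct_mean": 60.3250,
        "sucrose_pct_sd": 3.6422,
        "immobility_mean": 121.1125,
        "immobility_sd": 10.4305,
    },
}

#: Oscillatory amplitude multipliers, (group, zone, phase, band) -> factor.
#: Applied to the band-limited component amplitude while the animal occupies
#: that zone in that phase; unlisted cells are 1.  The defaults encode the
#: qualitative group x zone pattern: in the interaction zone defeated
#: animals lose 2-7 Hz and gain 14-30 Hz power with the aggressor present
#: (controls the opposite), while corner-zone changes are large for controls
#: (2-7 Hz up, 7-12 Hz down) and comparatively minor (but positive) for
#: defeated animals.  The directions make each band's change-in-power
#: correlate with the SI ratio the way the avoidance phenotype predicts:
#: positively for interaction/corner 2-7 Hz, negatively for interaction
#: 14-30 Hz and corner 7-12 Hz.
DEFAULT_BAND_EFFECTS: dict[tuple[str, str, str, str], float] = {
    (GROUP_CONTROL, ZONE_INTERACTION, PHASE_WITH_CD1, "2-7Hz"): 1.25,
    (GROUP_CONTROL, ZONE_INTERACTION, PHASE_WITH_CD1, "14-30Hz"): 0.85,
    (GROUP_CONTROL, ZONE_CORNER, PHASE_WITH_CD1, "2-7Hz"): 1.35,
    (GROUP_CONTROL, ZONE_CORNER, PHASE_WITH_CD1, "7-12Hz"): 0.75,
    (GROUP_DEFEAT, ZONE_INTERACTION, PHASE_WITH_CD1, "2-7Hz"): 0.75,
    (GROUP_DEFEAT, ZONE_INTERACTION, PHASE_WITH_CD1, "14-30Hz"): 1.30,
    (GROUP_DEFEAT, ZONE_CORNER, PHASE_WITH_CD1, "2-7Hz"): 1.12,
    (GROUP_DEFEAT, ZONE_CORNER, PHASE_WITH_CD1, "7-12Hz"): 1.10,
}

#: Band-limited oscillation components: (center Hz, bandwidth Hz, RMS
#: amplitude uV).  The 4 and 9.5 Hz peaks produce the bimodal 2-12 Hz
#: spectrum; weaker beta/gamma components give every analysis band
#: modulatable content.
DEFAULT_SPECTRAL_PEAKS: tuple[tuple[float, float, float], ...] = (
    (4.0, 3.0, 14.0),
    (9.5, 3.0, 10.0),
    (22.0, 12.0, 5.0),
    (40.0, 14.0, 3.5),
    (65.0, 20.0, 2.5),
)


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; defaults match the study conditions
    (n = 8 + 8, two 600 s phases, 16 channels at 2000 Hz)."""

    n_control: int = 8
    n_defeat: int = 8
    seed: int = 0
    session_phase_duration: float = 600.0
    sampling_rate: float = 2000.0
    n_channels: int = 16
    tracking_rate: float = 25.0
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    band_effects: Mapping[tuple[str, str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EFFECTS)
    )
    spectral_peaks: tuple[tuple[float, float, float], ...] = DEFAULT_SPECTRAL_PEAKS
    background_exponent: float = 1.0
    background_rms_uv: float = 12.0
    visit_params: Mapping[tuple[str, str], Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_VISIT_PARAMS.items()}
    )
    occupancy_jitter_sd: float = 0.25
    assay_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ASSAY_PARAMS.items()}
    )
    envelope_smoothing_s: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_control", "n_defeat", "n_channels"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in (
            "session_phase_duration",
            "sampling_rate",
            "tracking_rate",
            "background_rms_uv",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        for key, zones in self.visit_params.items():
            for zone, (prob, mean) in zones.items():
                if prob <= 0 or mean <= 0:
                    raise ConfigError(
                        f"visit_params[{key}][{zone}] probability and mean must be positive"
                    )
        if self.envelope_smoothing_s < 0.25:
            raise ConfigError("envelope_smoothing_s must be >= 0.25 s")
        for key, mult in self.band_effects.items():
            if mult <= 0:
                raise ConfigError(f"band_effects[{key}] must be strictly positive")
        for c, bw, amp in self.spectral_peaks:
            if bw <= 0 or amp <= 0 or c <= 0:
                raise ConfigError("spectral_peaks entries must be strictly positive")
        top = max(b.high for b in self.bands)
        if self.sampling_rate <= 2 * top:
            raise ConfigError(
                f"sampling_rate {self.sampling_rate} Hz below twice the highest "
                f"band edge ({top} Hz)"
            )

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Reduced-cost configuration used by the analyses: full 600 s
        phases and n = 8 + 8, but 400 Hz sampling and 2 channels."""
        defaults = dict(seed=seed, sampling_rate=400.0, n_channels=2)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticAnimal:
    """One simulated animal: group label plus behavior, assays and LFP."""

    animal_id: str
    group: str
    behavior: BehaviorSession
    assays: AssayRecord
    lfp: LfpRecording | None = None


def _phases(config: CohortConfig) -> dict[str, tuple[float, float]]:
    d = config.session_phase_duration
    return {PHASE_NO_CD1: (0.0, d), PHASE_WITH_CD1: (d, 2 * d)}


def _draw_positions(
    rng: np.random.Generator, zone: str, n: int, geometry: ArenaGeometry
) -> np.ndarray:
    """Uniform positions inside a zone's rectangle(s); 'other' positions are
    rejection-sampled over the arena outside all zones."""
    if zone == ZONE_INTERACTION:
        x0, y0, x1, y1 = geometry.interaction_zone
        return rng.uniform((x0, y0), (x1, y1), size=(n, 2))
    if zone == ZONE_CORNER:
        rect = geometry.corner_zones[rng.integers(len(geometry.corner_zones))]
        x0, y0, x1, y1 = rect
        return rng.uniform((x0, y0), (x1, y1), size=(n, 2))
    ax0, ay0, ax1, ay1 = geometry.arena
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform((ax0, ay0), (ax1, ay1), size=(n - filled, 2))
        bad = np.zeros(len(cand), dtype=bool)
        for x0, y0, x1, y1 in (geometry.interaction_zone, *geometry.corner_zones):
            bad |= (
                (cand[:, 0] >= x0)
                & (cand[:, 0] <= x1)
                & (cand[:, 1] >= y0)
                & (cand[:, 1] <= y1)
            )
        good = cand[~bad]
        out[filled : filled + len(good)] = good
        filled += len(good)
    return out


def simulate_behavior(group: str, config: CohortConfig, seed) -> BehaviorSession:
    """Semi-Markov zone-visit tracking for one animal, both phases.

    Visits are drawn i.i.d. from per-(group, phase) zone probabilities with
    exponential dwell times whose means are zone-specific, so expected
    occupancy equals prob x mean (normalized).  Visit probabilities carry a
    shared per-animal log-normal jitter, which is what spreads the
    social-interaction ratio across animals.  Consecutive same-zone visits
    merge into longer bouts.
    """
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    geometry = ArenaGeometry()
    dur = config.session_phase_duration
    dt = 1.0 / config.tracking_rate
    times = np.arange(0.0, 2 * dur, dt)
    n_per_phase = int(round(dur / dt))
    xy = np.empty((len(times), 2))
    zone_names = (ZONE_INTERACTION, ZONE_CORNER, ZONE_OTHER)
    # one shared per-animal propensity perturbation across phases
    jitter = rng.normal(0.0, config.occupancy_jitter_sd, size=3)
    for pi, phase in enumerate((PHASE_NO_CD1, PHASE_WITH_CD1)):
        params = config.visit_params[(group, phase)]
        props = np.array([params[z][0] for z in zone_names])
        means = np.array([params[z][1] for z in zone_names])
        props = props * np.exp(jitter)
        props /= props.sum()
        # draw the visit sequence in bulk until it covers the phase
        mean_visit = float(props @ means)
        n_guess = int(1.5 * dur / mean_visit) + 30
        zones = rng.choice(3, size=n_guess, p=props)
        dwells = rng.exponential(means[zones])
        while dwells.sum() < dur:
            more = rng.choice(3, size=n_guess, p=props)
            zones = np.concatenate([zones, more])
            dwells = np.concatenate([dwells, rng.exponential(means[more])])
        stops = np.cumsum(dwells)
        n_vis = int(np.searchsorted(stops, dur)) + 1
        bounds = np.concatenate(([0.0], stops[:n_vis]))
        bounds[-1] = dur
        zones = zones[:n_vis]
        edges = np.ceil(np.round(bounds / dt, 9)).astype(int)
        edges = np.clip(edges, 0, n_per_phase)
        counts = np.diff(edges)
        zone_per_sample = np.repeat(zones, counts)
        sl = slice(pi * n_per_phase, (pi + 1) * n_per_phase)
        pxy = np.empty((n_per_phase, 2))
        # interaction-zone samples: uniform in the zone rectangle
        m = zone_per_sample == 0
        x0, y0, x1, y1 = geometry.interaction_zone
        pxy[m] = rng.uniform((x0, y0), (x1, y1), size=(int(m.sum()), 2))
        # corner samples: pick one square per visit, uniform within it
        square_per_visit = rng.integers(len(geometry.corner_zones), size=n_vis)
        square_per_sample = np.repeat(square_per_visit, counts)
        for si, rect in enumerate(geometry.corner_zones):
            m = (zone_per_sample == 1) & (square_per_sample == si)
            x0, y0, x1, y1 = rect
            pxy[m] = rng.uniform((x0, y0), (x1, y1), size=(int(m.sum()), 2))
        # 'other' samples: anywhere in the arena outside the zones
        m = zone_per_sample == 2
        pxy[m] = _draw_positions(rng, ZONE_OTHER, int(m.sum()), geometry)
        xy[sl] = pxy
    track = pd.DataFrame({"time_s": times, "x_cm": xy[:, 0], "y_cm": xy[:, 1]})
    return BehaviorSession(track=track, phases=_phases(config), geometry=geometry)


def simulate_assays(group: str, config: CohortConfig, seed) -> AssayRecord:
    """Sucrose preference and immobility from truncated group normals.

    Preference is drawn as a percentage (truncated to [0, 100]) and
    converted to sucrose/water masses against a ~4 g total fluid intake;
    immobility is truncated to the 300 s test length.
    """
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    p = config.assay_params[group]

    def trunc(mean, sd, lo, hi):
        if sd == 0:
            return float(mean)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))

    pct = trunc(p["sucrose_pct_mean"], p["sucrose_pct_sd"], 0.0, 100.0)
    total_g = max(0.5, rng.normal(4.0, 0.5))
    immob = trunc(p["immobility_mean"], p["immobility_sd"], 0.0, 300.0)
    return AssayRecord(
        sucrose_consumption_g=pct / 100.0 * total_g,
        water_consumption_g=(1 - pct / 100.0) * total_g,
        immobility_s=immob,
    )


def _pink_noise(
    rng: np.random.Generator, n_ch: int, n: int, exponent: float, rms: float
) -> np.ndarray:
    """1/f background by spectral shaping: amplitude ~ f^(-exponent/2);
    one independent realization per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n, axis=-1)
    return x * (rms / x.std(axis=-1, keepdims=True))


def _band_of_peak(center: float, bands: Sequence[BandDefinition]) -> str | None:
    for b in bands:
        if b.low <= center < b.high:
            return b.name
    return None


def _sample_condition_codes(
    behavior: BehaviorSession, n_samples: int, fs: float
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """(zone, phase) combo code per LFP sample, from the tracking trace."""
    t = np.arange(n_samples) / fs
    track_t = behavior.track["time_s"].to_numpy()
    zones = behavior.zone_labels()
    idx = np.clip(np.searchsorted(track_t, t, side="right") - 1, 0, len(track_t) - 1)
    zone_per_sample = zones[idx]
    phase_per_sample = behavior.phase_of(t)
    combos = [
        (z, p)
        for z in (ZONE_INTERACTION, ZONE_CORNER, ZONE_OTHER)
        for p in (PHASE_NO_CD1, PHASE_WITH_CD1)
    ]
    code = np.zeros(n_samples, dtype=np.int8)
    for ci, (z, p) in enumerate(combos):
        code[(zone_per_sample == z) & (phase_per_sample == p)] = ci
    return code, combos


def simulate_lfp(
    group: str, behavior: BehaviorSession, config: CohortConfig, seed
) -> LfpRecording:
    """Multi-channel LFP whose band-limited amplitudes track behavior.

    Each channel is an independent pink background plus, per spectral peak,
    band-pass-filtered Gaussian noise (4th-order Butterworth, zero-phase)
    scaled by the effect-matrix multiplier for the animal's current (zone,
    phase).  The amplitude envelope is smoothed with a 300 ms window to
    avoid edge artifacts at zone transitions.  Channels share the behavioral
    envelope but have independent noise and a small gain jitter.
    """
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n = int(round(2 * config.session_phase_duration * fs))
    code, combos = _sample_condition_codes(behavior, n, fs)

    # smoothed amplitude-envelope per band that has any non-unit multiplier
    from scipy.ndimage import uniform_filter1d

    kernel_n = max(3, int(round(config.envelope_smoothing_s * fs)))
    envelopes: dict[str, np.ndarray] = {}
    for band in config.bands:
        mults = np.array(
            [config.band_effects.get((group, z, p, band.name), 1.0) for z, p in combos]
        )
        if np.allclose(mults, 1.0):
            continue
        envelopes[band.name] = uniform_filter1d(mults[code], kernel_n, mode="nearest")

    sos_per_peak = [
        signal.butter(
            4,
            [max(0.1, c - bw / 2), min(fs / 2 * 0.99, c + bw / 2)],
            btype="bandpass",
            fs=fs,
            output="sos",
        )
        for c, bw, _ in config.spectral_peaks
    ]
    n_ch = config.n_channels
    chans = _pink_noise(rng, n_ch, n, config.background_exponent, config.background_rms_uv)
    for (c, bw, amp), sos in zip(config.spectral_peaks, sos_per_peak):
        comp = signal.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=-1)
        comp *= amp / comp.std(axis=-1, keepdims=True)
        band_name = _band_of_peak(c, config.bands)
        if band_name in envelopes:
            comp *= envelopes[band_name]
        chans += comp
    chans *= rng.uniform(0.9, 1.1, size=(n_ch, 1))
    return LfpRecording(samples=chans, sampling_rate=fs, bandpass=(0.5, min(250.0, fs / 2)))


def simulate_cohort(config: CohortConfig, include_lfp: bool = True) -> list[SyntheticAnimal]:
    """Simulate the full cohort; per-animal substreams spawn from the master
    seed so the result is reproducible bit-for-bit."""
    master = np.random.SeedSequence(config.seed)
    n_total = config.n_control + config.n_defeat
    children = master.spawn(n_total) if n_total else []
    animals: list[SyntheticAnimal] = []
    idx = 0
    for group, count in ((GROUP_CONTROL, config.n_control), (GROUP_DEFEAT, config.n_defeat)):
        for k in range(count):
            s_beh, s_lfp, s_assay = children[idx].spawn(3)
            idx += 1
            behavior = simulate_behavior(group, config, s_beh)
            assays = simulate_assays(group, config, s_assay)
            lfp = simulate_lfp(group, behavior, config, s_lfp) if include_lfp else None
            animal_id = f"{group}_{k:02d}"
            if lfp is not None:
                lfp.animal_id = animal_id
            animals.append(
                SyntheticAnimal(
                    animal_id=animal_id,
                    group=group,
                    behavior=behavior,
                    assays=assays,
                    lfp=lfp,
                )
            )
    return animals
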