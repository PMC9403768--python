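"""Band-resolved LFP spectral power and the change-in-power statistic.

Power spectra are estimated with a short-time Fourier transform using a
0.5 s Hamming window stepped by 0.25 s; each window is zero-padded to a 2 s
FFT so the spectrum lands on a 0.5 Hz grid (a 0.5 s window's native
resolution is 2 Hz).  Band power is summed over five canonical bands
(2-7, 7-12, 14-30, 30-50, 50-80 Hz; the 12-14 Hz gap is excluded),
z-scored per channel over the whole session, averaged across channels, and
averaged within each (zone, phase) condition.  The central statistic is

    change in power = z-power(With CD1) - z-power(No CD1)

per animal, band and zone, plus an occupancy-time-weighted total change
across zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import (
    PHASE_NO_CD1,
    PHASE_WITH_CD1,
    ZONE_CORNER,
    ZONE_INTERACTION,
    BehaviorSession,
    zone_times,
)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, half-open in frequency: low <= f < high."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high <= 80:
            raise ValueError(f"band {self.name}: require 0 < low < high <= 80 Hz")


#: The five analysis bands.  2-7 and 7-12 Hz cover the bimodal low-frequency
#: power distribution; 14-30 Hz is the beta range the group contrast loads on;
#: 30-50 and 50-80 Hz complete the five-band set used for decoding.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("2-7Hz", 2.0, 7.0),
    BandDefinition("7-12Hz", 7.0, 12.0),
    BandDefinition("14-30Hz", 14.0, 30.0),
    BandDefinition("30-50Hz", 30.0, 50.0),
    BandDefinition("50-80Hz", 50.0, 80.0),
)


@dataclass
class LfpRecording:
    """Continuous multi-channel LFP: ``samples`` is channels x time, in uV."""

    samples: np.ndarray
    sampling_rate: float
    animal_id: str = ""
    bandpass: tuple[float, float] = (0.5, 250.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if np.isnan(self.samples).any():
            raise ValueError("LFP contains NaN samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class Spectrogram:
    """STFT power: ``power`` is time-bin x frequency-bin, uV^2/Hz."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    @property
    def freq_resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def compute_spectrogram(
    lfp: LfpRecording,
    channel: int,
    window_s: float = 0.5,
    step_s: float = 0.25,
    fft_s: float = 2.0,
) -> Spectrogram:
    """Per-channel STFT power with a Hamming taper on a 0.5 Hz grid.

    Times are window centers; power is a one-sided PSD (density scaling) so
    that summing over frequency bins times the 0.5 Hz bin width recovers the
    windowed signal variance (Parseval).
    """
    if not 0 <= channel < lfp.n_channels:
        raise IndexError(f"channel {channel} out of range [0, {lfp.n_channels})")
    fs = lfp.sampling_rate
    nperseg = int(round(window_s * fs))
    if lfp.samples.shape[1] < nperseg:
        raise ValueError("signal shorter than one STFT window")
    freqs, times, sxx = signal.spectrogram(
        lfp.samples[channel],
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg - int(round(step_s * fs)),
        nfft=int(round(fft_s * fs)),
        scaling="density",
        mode="psd",
        detrend=False,
    )
    return Spectrogram(power=sxx.T, freqs=freqs, times=times)


def band_power(spec: Spectrogram, band: BandDefinition) -> np.ndarray:
    """Power time series for one band: per-bin sum over low <= f < high,
    times the bin width (uV^2)."""
    mask = (spec.freqs >= band.low) & (spec.freqs < band.high)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    return spec.power[:, mask].sum(axis=1) * spec.freq_resolution


def zscore_band_power(series: np.ndarray) -> np.ndarray:
    """Z-score a band-power series against its own session mean and SD."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = series.std()
    if sd == 0:
        raise ValueError("zero-variance series cannot be z-scored")
    return (series - series.mean()) / sd


def bin_condition_labels(
    times: np.ndarray, session: BehaviorSession
) -> tuple[np.ndarray, np.ndarray]:
    """Zone and phase label per spectrogram time bin (assigned by bin center).

    The zone at a bin center is that of the most recent tracking sample.
    """
    track_t = session.track["time_s"].to_numpy()
    zones = session.zone_labels()
    idx = np.clip(np.searchsorted(track_t, times, side="right") - 1, 0, len(track_t) - 1)
    return zones[idx], session.phase_of(times)


def condition_mean_power(
    z_series: np.ndarray,
    times: np.ndarray,
    session: BehaviorSession,
    zone: str,
    phase: str,
) -> float:
    """Mean z-power over time bins whose centers fall in (zone, phase).

    Returns NaN (a propagating missing-condition marker) when no bin
    qualifies, e.g. an animal that never entered the zone in that phase.
    """
    zone_lab, phase_lab = bin_condition_labels(np.asarray(times), session)
    mask = (zone_lab == zone) & (phase_lab == phase)
    if not mask.any():
        return float("nan")
    return float(np.mean(np.asarray(z_series)[mask]))


def power_change(z_with: float, z_no: float) -> float:
    """Change in power: z-power with CD1 minus z-power without.  NaN inputs
    (missing conditions) propagate."""
    return z_with - z_no


def total_power_change(
    change_interaction: float,
    change_corner: float,
    t_interaction: float,
    t_corner: float,
) -> float:
    """Occupancy-time-weighted total change across the two zones."""
    if t_interaction < 0 or t_corner < 0:
        raise ValueError("zone times must be non-negative")
    total = t_interaction + t_corner
    if total == 0:
        raise ValueError("total zone time is zero; weighted change undefined")
    # a zone with zero occupancy contributes nothing, even if its change is
    # a missing-condition NaN
    if t_interaction == 0:
        return float(change_corner)
    if t_corner == 0:
        return float(change_interaction)
    return (change_interaction * t_interaction + change_corner * t_corner) / total


def session_band_z(
    lfp: LfpRecording,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    mode: str = "session",
    baseline_mask: np.ndarray | None = None,
    **stft_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged z-scored band power for a whole recording.

    Per channel and band, the band-power series is z-scored -- against the
    full session (``mode="session"``, default) or against baseline bins only
    (``mode="baseline"`` with ``baseline_mask``) -- then averaged across
    channels.  Returns ``(times, z)`` with ``z`` of shape (n_bands, n_bins).
    Z-scoring makes the result invariant to per-channel gain and offset.
    """
    if mode not in ("session", "baseline"):
        raise ValueError(f"unknown z-scoring mode {mode!r}")
    z_sum = None
    times = None
    for ch in range(lfp.n_channels):
        spec = compute_spectrogram(lfp, ch, **stft_kwargs)
        if times is None:
            times = spec.times
            z_sum = np.zeros((len(bands), len(times)))
        for bi, band in enumerate(bands):
            bp = band_power(spec, band)
            if mode == "baseline":
                if baseline_mask is None:
                    raise ValueError("baseline mode requires baseline_mask")
                mu, sd = bp[baseline_mask].mean(), bp[baseline_mask].std()
                if sd == 0:
                    raise ValueError("zero-variance baseline")
                z_sum[bi] += (bp - mu) / sd
            else:
                z_sum[bi] += zscore_band_power(bp)
    return times, z_sum / lfp.n_channels


@dataclass
class BandPowerSummary:
    """Tidy per-(animal, band, zone) z-power summary with change-in-power."""

    table: pd.DataFrame  # animal_id, group, band, zone, z_no_cd1, z_with_cd1, change
    total_change: pd.DataFrame  # animal_id, group, band, total_change


def band_power_summary(
    animals: Sequence[tuple[str, str, LfpRecording, BehaviorSession]],
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    mode: str = "session",
    **stft_kwargs,
) -> BandPowerSummary:
    """Compute the change-in-power table for a cohort.

    ``animals`` is a sequence of (animal_id, group, lfp, behavior).  The
    total change per band weights the two zones' changes by With-CD1
    occupancy time.
    """
    rows = []
    tot_rows = []
    for animal_id, group, lfp, session in animals:
        baseline_mask = None
        if mode == "baseline":
            t0, t1 = session.phases[PHASE_NO_CD1]
            # mask computed lazily against the first channel's bin grid
            spec0 = compute_spectrogram(lfp, 0, **stft_kwargs)
            baseline_mask = (spec0.times >= t0) & (spec0.times < t1)
        times, z = session_band_z(
            lfp, bands, mode=mode, baseline_mask=baseline_mask, **stft_kwargs
        )
        tw = zone_times(session, PHASE_WITH_CD1)
        zone_lab, phase_lab = bin_condition_labels(times, session)
        masks = {
            (zone, phase): (zone_lab == zone) & (phase_lab == phase)
            for zone in (ZONE_INTERACTION, ZONE_CORNER)
            for phase in (PHASE_NO_CD1, PHASE_WITH_CD1)
        }

        def cond_mean(zi, zone, phase):
            m = masks[(zone, phase)]
            return float(zi[m].mean()) if m.any() else float("nan")

        changes = {}
        for bi, band in enumerate(bands):
            for zone in (ZONE_INTERACTION, ZONE_CORNER):
                z_no = cond_mean(z[bi], zone, PHASE_NO_CD1)
                z_with = cond_mean(z[bi], zone, PHASE_WITH_CD1)
                ch = power_change(z_with, z_no)
                changes[(band.name, zone)] = ch
                rows.append(
                    dict(
                        animal_id=animal_id,
                        group=group,
                        band=band.name,
                        zone=zone,
                        z_no_cd1=z_no,
                        z_with_cd1=z_with,
                        change=ch,
                    )
                )
            tot_rows.append(
                dict(
                    animal_id=animal_id,
                    group=group,
                    band=band.name,
                    total_change=total_power_change(
                        changes[(band.name, ZONE_INTERACTION)],
                        changes[(band.name, ZONE_CORNER)],
                        tw[ZONE_INTERACTION],
                        tw[ZONE_CORNER],
                    ),
                )
            )
    return BandPowerSummary(table=pd.DataFrame(rows), total_change=pd.DataFrame(tot_rows))
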