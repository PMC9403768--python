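"""Behavioral metrics for the social interaction test and companion assays.

The social interaction test (SIT) places a mouse in a 50 cm x 50 cm arena
containing a wire-mesh enclosure against one wall.  An "interaction zone"
(14 cm x 24 cm) surrounds the enclosure and two "corner zones" (9 cm x 9 cm
each) sit in the corners of the opposite wall.  Each session has two 600 s
phases: one with the enclosure empty ("No CD1") and one with an aggressor
CD1 mouse inside it ("With CD1").  The social interaction ratio --
interaction-zone time with the CD1 present divided by interaction-zone time
with it absent -- quantifies social avoidance; a ratio below 1 marks a
susceptible animal.

This module also computes the sucrose-preference rate (anhedonia assay) and
tail-suspension immobility time (behavioral-despair assay).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PHASE_NO_CD1 = "no_cd1"
PHASE_WITH_CD1 = "with_cd1"
PHASES = (PHASE_NO_CD1, PHASE_WITH_CD1)

ZONE_INTERACTION = "interaction"
ZONE_CORNER = "corner"
ZONE_OTHER = "other"
ZONES = (ZONE_INTERACTION, ZONE_CORNER, ZONE_OTHER)


class OutOfArenaError(ValueError):
    """Raised when a tracked position lies outside the arena."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio's denominator is zero."""


def _rect(x0: float, y0: float, x1: float, y1: float) -> tuple[float, float, float, float]:
    return (float(x0), float(y0), float(x1), float(y1))


@dataclass(frozen=True)
class ArenaGeometry:
    """SIT arena geometry in centimetres.

    Rectangles are ``(x0, y0, x1, y1)`` with closed boundaries.  The mesh
    enclosure sits against the top wall (y = 50); the interaction zone is a
    24 cm-wide, 14 cm-deep rectangle centred on it, and the two corner zones
    are 9 cm squares against the opposite (y = 0) wall.
    """

    arena: tuple[float, float, float, float] = _rect(0, 0, 50, 50)
    interaction_zone: tuple[float, float, float, float] = _rect(13, 36, 37, 50)
    corner_zones: tuple[tuple[float, float, float, float], ...] = (
        _rect(0, 0, 9, 9),
        _rect(41, 0, 50, 9),
    )

    def __post_init__(self) -> None:
        ax0, ay0, ax1, ay1 = self.arena
        for r in (self.interaction_zone, *self.corner_zones):
            x0, y0, x1, y1 = r
            if not (ax0 <= x0 < x1 <= ax1 and ay0 <= y0 < y1 <= ay1):
                raise ValueError(f"zone {r} does not lie inside the arena {self.arena}")
        ix0, iy0, ix1, iy1 = self.interaction_zone
        for x0, y0, x1, y1 in self.corner_zones:
            if ix0 < x1 and x0 < ix1 and iy0 < y1 and y0 < iy1:
                raise ValueError("interaction and corner zones overlap")


def _in_rect(x: float, y: float, rect: Sequence[float]) -> bool:
    x0, y0, x1, y1 = rect
    return x0 <= x <= x1 and y0 <= y <= y1


def classify_zone(x: float, y: float, geometry: ArenaGeometry | None = None) -> str:
    """Label a position as interaction / corner / other.

    Boundaries are closed (a point on a zone edge belongs to the zone) and
    the interaction zone takes priority, although by construction the zones
    are disjoint.
    """
    geometry = geometry or ArenaGeometry()
    if not _in_rect(x, y, geometry.arena):
        raise OutOfArenaError(f"position ({x}, {y}) outside arena {geometry.arena}")
    if _in_rect(x, y, geometry.interaction_zone):
        return ZONE_INTERACTION
    for rect in geometry.corner_zones:
        if _in_rect(x, y, rect):
            return ZONE_CORNER
    return ZONE_OTHER


def classify_zones(x: np.ndarray, y: np.ndarray, geometry: ArenaGeometry | None = None) -> np.ndarray:
    """Vectorized :func:`classify_zone`; returns an object array of labels."""
    geometry = geometry or ArenaGeometry()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ax0, ay0, ax1, ay1 = geometry.arena
    if np.any((x < ax0) | (x > ax1) | (y < ay0) | (y > ay1)):
        raise OutOfArenaError("tracked positions fall outside the arena")
    labels = np.full(x.shape, ZONE_OTHER, dtype=object)
    for rect in geometry.corner_zones:
        x0, y0, x1, y1 = rect
        labels[(x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)] = ZONE_CORNER
    x0, y0, x1, y1 = geometry.interaction_zone
    labels[(x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)] = ZONE_INTERACTION
    return labels


@dataclass
class BehaviorSession:
    """Tracking trace plus phase boundaries for one SIT session.

    ``track`` holds columns ``time_s, x_cm, y_cm``; ``phases`` maps phase
    label -> ``(t_start, t_end)`` half-open intervals in seconds.
    """

    track: pd.DataFrame
    phases: Mapping[str, tuple[float, float]]
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        required = {"time_s", "x_cm", "y_cm"}
        missing = required - set(self.track.columns)
        if missing:
            raise ValueError(f"track missing columns: {sorted(missing)}")
        t = self.track["time_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("track time must be strictly increasing")
        ivals = sorted(self.phases.values())
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError("phases overlap")

    def zone_labels(self) -> np.ndarray:
        """Zone label per tracking sample (cached; the track is immutable by
        convention)."""
        cache = getattr(self, "_zone_cache", None)
        if cache is None:
            cache = classify_zones(
                self.track["x_cm"].to_numpy(), self.track["y_cm"].to_numpy(), self.geometry
            )
            object.__setattr__(self, "_zone_cache", cache)
        return cache

    def phase_of(self, times: np.ndarray) -> np.ndarray:
        """Phase label for each time (empty string outside all phases)."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, "", dtype=object)
        for name, (t0, t1) in self.phases.items():
            out[(times >= t0) & (times < t1)] = name
        return out


@dataclass(frozen=True)
class AssayRecord:
    """Companion-assay measurements for one animal."""

    sucrose_consumption_g: float
    water_consumption_g: float
    immobility_s: float

    def __post_init__(self) -> None:
        if self.sucrose_consumption_g < 0 or self.water_consumption_g < 0:
            raise ValueError("fluid consumption must be non-negative")
        if not 0 <= self.immobility_s <= 300:
            raise ValueError("immobility must lie in [0, 300] s")


def _sample_durations(times: np.ndarray, t_end: float) -> np.ndarray:
    """Duration attributed to each sample: hold position until the next
    sample, the last sample until ``t_end``."""
    dt = np.empty(len(times))
    dt[:-1] = np.diff(times)
    dt[-1] = max(t_end - times[-1], 0.0)
    return dt


def zone_times(session: BehaviorSession, phase: str) -> dict[str, float]:
    """Seconds spent per zone during one phase.

    Each tracking sample contributes the interval to the next sample (the
    last one runs to the phase end), so the per-zone times sum to at most
    the phase duration.
    """
    if phase not in session.phases:
        raise KeyError(f"phase {phase!r} not in session (has {list(session.phases)})")
    t0, t1 = session.phases[phase]
    t = session.track["time_s"].to_numpy()
    mask = (t >= t0) & (t < t1)
    if not mask.any():
        raise ValueError(f"no tracking samples in phase {phase!r}")
    labels = session.zone_labels()[mask]
    dt = _sample_durations(t[mask], t1)
    out = {z: 0.0 for z in ZONES}
    for z in ZONES:
        out[z] = float(dt[labels == z].sum())
    return out


def social_interaction_ratio(time_with: float, time_without: float) -> float:
    """(interaction time with CD1 present) / (interaction time with CD1 absent)."""
    if time_with < 0 or time_without < 0:
        raise ValueError("zone times must be non-negative")
    if time_without == 0:
        raise UndefinedRatioError("social interaction ratio undefined: zero time without CD1")
    return time_with / time_without


def is_susceptible(si_ratio_interaction: float) -> bool:
    """Susceptible (socially avoidant) iff the interaction-zone SI ratio < 1, strictly."""
    return si_ratio_interaction < 1.0


def sucrose_preference(sucrose_g: float, water_g: float) -> float:
    """Sucrose preference rate, percent: 100 * sucrose / (sucrose + water)."""
    if sucrose_g < 0 or water_g < 0:
        raise ValueError("consumption must be non-negative")
    total = sucrose_g + water_g
    if total == 0:
        raise UndefinedRatioError("sucrose preference undefined: zero total consumption")
    return 100.0 * sucrose_g / total


def immobility_time(times: np.ndarray, motion_energy: np.ndarray, threshold: float) -> float:
    """Total time (s) the motion-energy trace stays strictly below ``threshold``.

    Each sample holds its value until the next sample; the final sample
    contributes the median sampling interval.
    """
    times = np.asarray(times, dtype=float)
    motion_energy = np.asarray(motion_energy, dtype=float)
    if times.size == 0:
        raise ValueError("empty motion-energy series")
    if times.size != motion_energy.size:
        raise ValueError("times and motion_energy lengths differ")
    if times.size == 1:
        return 0.0
    med = float(np.median(np.diff(times)))
    dt = _sample_durations(times, times[-1] + med)
    return float(dt[motion_energy < threshold].sum())


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-animal behavioral readout: zone times, SI ratios, assays."""

    animal_id: str
    group: str
    time_interaction_no_cd1: float
    time_corner_no_cd1: float
    time_interaction_with_cd1: float
    time_corner_with_cd1: float
    si_ratio_interaction: float
    si_ratio_corner: float | None
    susceptible: bool
    sucrose_pct: float | None = None
    immobility_s: float | None = None


def summarize_behavior(
    animal_id: str,
    group: str,
    session: BehaviorSession,
    assays: AssayRecord | None = None,
) -> BehaviorSummary:
    """Full SIT summary for one animal.

    The corner-zone SI ratio uses the same with/without formula on summed
    corner-zone times (both corner squares pooled); it is ``None`` when the
    animal never visited a corner in the No-CD1 phase.
    """
    no = zone_times(session, PHASE_NO_CD1)
    with_ = zone_times(session, PHASE_WITH_CD1)
    si_int = social_interaction_ratio(with_[ZONE_INTERACTION], no[ZONE_INTERACTION])
    try:
        si_cor = social_interaction_ratio(with_[ZONE_CORNER], no[ZONE_CORNER])
    except UndefinedRatioError:
        si_cor = None
    sucrose = immob = None
    if assays is not None:
        sucrose = sucrose_preference(assays.sucrose_consumption_g, assays.water_consumption_g)
        immob = assays.immobility_s
    return BehaviorSummary(
        animal_id=animal_id,
        group=group,
        time_interaction_no_cd1=no[ZONE_INTERACTION],
        time_corner_no_cd1=no[ZONE_CORNER],
        time_interaction_with_cd1=with_[ZONE_INTERACTION],
        time_corner_with_cd1=with_[ZONE_CORNER],
        si_ratio_interaction=si_int,
        si_ratio_corner=si_cor,
        susceptible=is_susceptible(si_int),
        sucrose_pct=sucrose,
        immobility_s=immob,
    )


def summaries_to_frame(summaries: Sequence[BehaviorSummary]) -> pd.DataFrame:
    """Tidy one-row-per-animal table of behavior summaries."""
    return pd.DataFrame([s.__dict__ for s in summaries])
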