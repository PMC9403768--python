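import numpy as np
import pandas as pd
import pytest

from csds_lfp.behavior import ArenaGeometry, BehaviorSession
from csds_lfp.cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def geometry():
    return ArenaGeometry()


def make_session(zone_sequence, dt=0.1, phase_duration=None, geometry=None):
    """Session whose track sits at the center of the named zone for each
    sample; ``zone_sequence`` is an iterable of zone names, one per sample,
    covering both phases back to back."""
    geometry = geometry or ArenaGeometry()
    centers = {
        "interaction": _center(geometry.interaction_zone),
        "corner": _center(geometry.corner_zones[0]),
        "other": (25.0, 20.0),
    }
    zones = list(zone_sequence)
    n = len(zones)
    if phase_duration is None:
        phase_duration = n * dt / 2
    times = np.arange(n) * dt
    xy = np.array([centers[z] for z in zones])
    track = pd.DataFrame({"time_s": times, "x_cm": xy[:, 0], "y_cm": xy[:, 1]})
    phases = {"no_cd1": (0.0, phase_duration), "with_cd1": (phase_duration, 2 * phase_duration)}
    return BehaviorSession(track=track, phases=phases, geometry=geometry)


def _center(rect):
    x0, y0, x1, y1 = rect
    return ((x0 + x1) / 2, (y0 + y1) / 2)


@pytest.fixture(scope="session")
def tiny_config():
    """Cheap full-pipeline config: short phases, low rate, one channel."""
    return CohortConfig.desk_scale(
        seed=11, sampling_rate=200.0, n_channels=1, session_phase_duration=120.0
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)
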