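"""Shared configuration for the numbered analysis drivers.

Every driver regenerates the same deterministic cohort from (config, seed),
so the steps can be run independently without shipping bulky intermediate
LFP files.
"""

from pathlib import Path

from csds_lfp.cohort import CohortConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
DEFAULT_SEED = 0


def cohort_config(seed: int = DEFAULT_SEED) -> CohortConfig:
    """The analysis-scale study configuration: n = 8 + 8, two 600 s phases,
    2 channels at 400 Hz."""
    return CohortConfig.desk_scale(seed=seed)
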