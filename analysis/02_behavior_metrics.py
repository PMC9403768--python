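"""Behavioral battery: zone occupancy, SI ratios, sucrose preference,
immobility, and the control-vs-defeated t-tests.

Reads the tracking/assay CSVs written by 01_simulate_cohort.py, computes
the per-animal behavior summary and prints the group comparisons (the
expected pattern: defeated animals show lower sucrose preference, longer
immobility, and an interaction-zone SI ratio below 1).
"""

import argparse
import json

from common import RESULTS
from csds_lfp.behavior import summaries_to_frame, summarize_behavior
from csds_lfp.io import read_assays_csv, read_tracking_csv
from csds_lfp.stats import unpaired_t


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    args = ap.parse_args()

    cohort_dir = RESULTS / "cohort"
    assays = read_assays_csv(cohort_dir / "assays.csv")
    summaries = []
    for path in sorted(cohort_dir.glob("tracking_*.csv")):
        animal_id = path.stem.replace("tracking_", "")
        group, rec = assays[animal_id]
        session = read_tracking_csv(path)
        summaries.append(summarize_behavior(animal_id, group, session, rec))
    df = summaries_to_frame(summaries)
    df.to_csv(RESULTS / "behavior_summary.csv", index=False, float_format="%.6f")

    ctrl, dft = df[df.group == "control"], df[df.group == "defeated"]
    stats = {}
    for col in ("sucrose_pct", "immobility_s", "si_ratio_interaction",
                "time_interaction_with_cd1", "time_corner_with_cd1"):
        r = unpaired_t(ctrl[col].to_numpy(), dft[col].to_numpy())
        stats[col] = dict(
            control_mean=float(ctrl[col].mean()),
            defeated_mean=float(dft[col].mean()),
            t=r.statistic, p=r.p_two_tailed,
        )
        print(
            f"{col:28s} control {ctrl[col].mean():8.2f}  defeated {dft[col].mean():8.2f}"
            f"  t={r.statistic:7.2f}  p={r.p_two_tailed:.2e}"
        )
    n_susceptible = int(dft["susceptible"].sum())
    print(f"susceptible defeated animals (SI ratio < 1): {n_susceptible}/{len(dft)}")
    stats["n_susceptible_defeated"] = n_susceptible
    (RESULTS / "behavior_stats.json").write_text(json.dumps(stats, indent=2) + "\n")


if __name__ == "__main__":
    main()
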