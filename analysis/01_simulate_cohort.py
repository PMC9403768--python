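"""Simulate the synthetic CSDS cohort and write its behavioral raw data.

Generates n = 8 control + 8 defeated animals (two 600 s social-interaction
phases each) and writes tracking and assay tables under results/cohort/.
LFP stays in memory for later stages (each driver regenerates it
deterministically from the same seed) unless --write-lfp is given.
"""

import argparse

from common import RESULTS, cohort_config
from csds_lfp.cohort import simulate_cohort
from csds_lfp.io import write_assays_csv, write_lfp_csv, write_tracking_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--write-lfp", action="store_true", help="also write LFP CSVs (large)")
    args = ap.parse_args()

    outdir = RESULTS / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    animals = simulate_cohort(cohort_config(args.seed), include_lfp=args.write_lfp)
    for a in animals:
        write_tracking_csv(a.behavior, outdir / f"tracking_{a.animal_id}.csv")
        if args.write_lfp and a.lfp is not None:
            write_lfp_csv(a.lfp, outdir / f"lfp_{a.animal_id}.csv")
    write_assays_csv({a.animal_id: (a.group, a.assays) for a in animals}, outdir / "assays.csv")
    print(f"wrote tracking + assays for {len(animals)} animals to {outdir}")


if __name__ == "__main__":
    main()
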