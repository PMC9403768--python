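"""Group statistics on the change-in-power tables: mixed two-way ANOVA
(group x band) with Bonferroni post hoc per zone, and Pearson correlations
between each band's change-in-power and the interaction-zone SI ratio
across all 16 animals.

Reads behavior_summary.csv and band_power_summary.csv written by drivers
02 and 03.
"""

import argparse
import json

import pandas as pd

from common import RESULTS
from csds_lfp.pipeline import group_statistics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    args = ap.parse_args()

    behavior = pd.read_csv(RESULTS / "behavior_summary.csv")
    band_table = pd.read_csv(RESULTS / "band_power_summary.csv")
    results = group_statistics(behavior, band_table)
    serializable = {
        k: {kk: vv for kk, vv in v.items() if kk != "anova_table"}
        for k, v in results.items()
    }
    (RESULTS / "group_stats.json").write_text(json.dumps(serializable, indent=2, default=str) + "\n")

    for zone in ("interaction", "corner"):
        a = results.get(f"anova_{zone}", {})
        if "F" in a:
            print(f"{zone} zone: group main effect F{tuple(a['df'])} = {a['F']:.3f}, p = {a['p']:.4f}")
            for row in a["posthoc"]:
                flag = "*" if row["significant"] else " "
                print(f"   {row['band']:>8s}: t = {row['t']:6.2f}, Bonferroni p = {row['p_bonferroni']:.4f} {flag}")
    print("\nchange-in-power vs interaction-zone SI ratio (n = 16):")
    for k, v in results.items():
        if k.startswith("correlation_"):
            print(f"   {k.replace('correlation_', ''):22s} r = {v['r']:6.3f}, p = {v['p']:.4f}")


if __name__ == "__main__":
    main()
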