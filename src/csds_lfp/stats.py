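"""Group-level statistics: unpaired t, mixed two-way ANOVA with Bonferroni
post hoc, and Pearson correlation / linear regression with exact t-transform
p-values.

The battery mirrors common practice in behavioral electrophysiology:
between-group behavioral comparisons use Student's (pooled-variance)
unpaired t; band-resolved change-in-power tables use a mixed ANOVA with
group as the between factor and frequency band as the within (repeated)
factor, followed by per-band Bonferroni-corrected group contrasts; and
brain-behavior relationships use Pearson's r with the exact two-tailed
p-value from t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """One test's outcome: statistic, df, two-tailed p, effect estimate, n."""

    statistic_name: str  # "t", "F" or "r"
    statistic: float
    df: tuple[float, ...]
    p_two_tailed: float
    estimate: float
    n: tuple[int, ...]
    extra: dict | None = None


def unpaired_t(sample_a, sample_b, welch: bool = False) -> StatResult:
    """Student's two-sample t-test (pooled variance unless ``welch``).

    ``estimate`` is mean(a) - mean(b); df = n_a + n_b - 2 for the pooled
    form.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        diff = float(a.mean() - b.mean())
        t_stat = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
        return StatResult(
            statistic_name="t",
            statistic=t_stat,
            df=(float(len(a) + len(b) - 2),),
            p_two_tailed=1.0 if diff == 0 else 0.0,
            estimate=diff,
            n=(len(a), len(b)),
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return StatResult(
        statistic_name="t",
        statistic=float(res.statistic),
        df=(float(res.df),),
        p_two_tailed=float(res.pvalue),
        estimate=float(a.mean() - b.mean()),
        n=(len(a), len(b)),
    )


def pearson_p_from_r(r: float, n: int) -> float:
    """Exact two-tailed p for a Pearson r at sample size n via the
    t-transform t = r*sqrt(n-2)/sqrt(1-r^2), Student's t with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * sps.t.sf(t, n - 2))


def pearson_with_p(x, y) -> StatResult:
    """Pearson correlation with exact t-transform p, plus the least-squares
    slope and intercept (in ``extra``).

    Perfectly collinear data yield r = +/-1 with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need matched samples with n >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    slope = r * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return StatResult(
        statistic_name="r",
        statistic=r,
        df=(float(n - 2),),
        p_two_tailed=pearson_p_from_r(r, n),
        estimate=r,
        n=(n,),
        extra={"slope": float(slope), "intercept": intercept},
    )


def _one_way_between(table: pd.DataFrame) -> StatResult:
    groups = [g["value"].to_numpy() for _, g in table.groupby("group")]
    if len(groups) != 2:
        raise ValueError("expected exactly 2 groups")
    f, p = sps.f_oneway(*groups)
    n = tuple(len(g) for g in groups)
    return StatResult(
        statistic_name="F",
        statistic=float(f),
        df=(1.0, float(sum(n) - 2)),
        p_two_tailed=float(p),
        estimate=float(groups[0].mean() - groups[1].mean()),
        n=n,
    )


def mixed_anova(table: pd.DataFrame, alpha: float = 0.05) -> tuple[StatResult, pd.DataFrame]:
    """Mixed two-way ANOVA (group between x band within) with Bonferroni
    post hoc group contrasts per band.

    ``table`` is tidy with columns ``animal_id, group, band, value`` and must
    be balanced: every animal measured in every band.  Returns the group
    main-effect F and a per-band contrast table whose ``p_bonferroni`` is the
    unpaired-t p multiplied by the number of bands (capped at 1) and
    ``significant`` compares it to ``alpha``.

    With a single band the design degenerates to a one-way between-groups
    ANOVA, so F equals the squared unpaired t.
    """
    required = {"animal_id", "group", "band", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby(["animal_id", "band"]).size()
    bands = list(table["band"].unique())
    animals = table["animal_id"].unique()
    for a in animals:
        for b in bands:
            if (a, b) not in counts.index:
                raise ValueError(f"missing cell: animal {a!r}, band {b!r}")
    if table["value"].isna().any():
        bad = table[table["value"].isna()].iloc[0]
        raise ValueError(f"missing value in cell: animal {bad['animal_id']!r}, band {bad['band']!r}")

    sizes = table.groupby("group")["animal_id"].nunique()
    if len(bands) == 1:
        main = _one_way_between(table)
    elif table["value"].nunique() == 1:
        # degenerate zero-variance table: no effect by definition
        main = StatResult(
            statistic_name="F",
            statistic=0.0,
            df=(1.0, float(sizes.sum() - 2)),
            p_two_tailed=1.0,
            estimate=0.0,
            n=tuple(int(v) for v in sizes),
        )
    else:
        import pingouin as pg

        aov = pg.mixed_anova(
            data=table, dv="value", within="band", subject="animal_id", between="group"
        )
        row = aov[aov["Source"] == "group"].iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        main = StatResult(
            statistic_name="F",
            statistic=float(row["F"]),
            df=(float(row["DF1"]), float(row["DF2"])),
            p_two_tailed=float(row[p_col]),
            estimate=float(
                table.groupby("group")["value"].mean().diff().iloc[-1] * -1
            ),
            n=tuple(int(v) for v in sizes),
            extra={"anova_table": aov.drop(columns=["eps"], errors="ignore")},
        )

    post_rows = []
    group_names = sorted(table["group"].unique())
    for b in bands:
        sub = table[table["band"] == b]
        va = sub[sub["group"] == group_names[0]]["value"].to_numpy()
        vb = sub[sub["group"] == group_names[1]]["value"].to_numpy()
        res = unpaired_t(va, vb)
        p_adj = min(1.0, res.p_two_tailed * len(bands))
        post_rows.append(
            dict(
                band=b,
                t=res.statistic,
                df=res.df[0],
                p_uncorrected=res.p_two_tailed,
                p_bonferroni=p_adj,
                significant=p_adj < alpha,
                estimate=res.estimate,
            )
        )
    return main, pd.DataFrame(post_rows)


def null_pearson_type1_rate(
    n_sims: int = 10_000, n: int = 20, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of the t-transform Pearson p under a true null
    (independent Gaussians), vectorized across simulations."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n))
    y = rng.standard_normal((n_sims, n))
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    r = (x * y).sum(axis=1) / np.sqrt((x**2).sum(axis=1) * (y**2).sum(axis=1))
    t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * sps.t.sf(t, n - 2)
    return float((p < alpha).mean())
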