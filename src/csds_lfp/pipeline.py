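"""End-to-end orchestration: simulate -> behavior -> spectra -> stats ->
decode, with a reproducibility manifest.

Every stage reads and writes flat files under one output directory, so the
stages are independently runnable and the whole run is reproducible from
(config, seed) alone.  The manifest records the config hash, the master
seed, package/library versions and a checksum for every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import PHASE_WITH_CD1, ZONE_CORNER, ZONE_INTERACTION, summaries_to_frame, summarize_behavior
from .cohort import CohortConfig, GROUP_CONTROL, GROUP_DEFEAT, simulate_cohort
from .decoder import cohort_dataset, decode_with_null
from .io import write_assays_csv, write_json, write_lfp_csv, write_tracking_csv
from .spectral import CANONICAL_BANDS, band_power_summary
from .stats import mixed_anova, pearson_with_p, unpaired_t

logger = logging.getLogger(__name__)

#: RunConfig keys accepted at the top level of a config file.
RUN_CONFIG_KEYS = {
    "cohort",
    "epoch_length_s",
    "n_repeats",
    "n_shifts",
    "zscore_mode",
    "write_lfp",
}

_COHORT_SIMPLE_KEYS = {
    "n_control",
    "n_defeat",
    "seed",
    "session_phase_duration",
    "sampling_rate",
    "n_channels",
    "tracking_rate",
    "occupancy_jitter_sd",
    "background_exponent",
    "background_rms_uv",
    "envelope_smoothing_s",
}


@dataclasses.dataclass
class RunConfig:
    """Pipeline-level configuration wrapping a :class:`CohortConfig`."""

    cohort: CohortConfig
    epoch_length_s: float = 5.0
    n_repeats: int = 20
    n_shifts: int = 200
    zscore_mode: str = "session"
    write_lfp: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - RUN_CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort_raw = dict(raw.get("cohort", {}))
        unknown = set(cohort_raw) - _COHORT_SIMPLE_KEYS
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        cohort = CohortConfig(**cohort_raw)
        kwargs = {k: v for k, v in raw.items() if k != "cohort"}
        return cls(cohort=cohort, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = {
            k: v for k, v in dataclasses.asdict(self.cohort).items() if k in _COHORT_SIMPLE_KEYS
        }
        return d


def load_config(path: str | Path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in order and write a manifest.

    Stages: cohort simulation, behavior metrics, band-power summary, group
    statistics (t-tests, mixed ANOVA + Bonferroni, change-vs-SI-ratio
    correlations), and state decoding with the circular-shift null.
    Re-running with the same config reproduces byte-identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.cohort.seed,
        "versions": {"csds_lfp": __version__, "numpy": np.__version__},
        "stages": {},
    }
    written: list[Path] = []

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0, files):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": [f.name for f in files],
        }
        written.extend(files)
        logger.info("stage %s done (%.1fs)", name, time.perf_counter() - t0)

    # 1. simulate
    t0 = stage("simulate")
    try:
        animals = simulate_cohort(config.cohort, include_lfp=True)
    except Exception as exc:  # re-raise with the stage name, per contract
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    files = []
    for a in animals:
        p = outdir / f"tracking_{a.animal_id}.csv"
        write_tracking_csv(a.behavior, p)
        files.append(p)
        if config.write_lfp and a.lfp is not None:
            p = outdir / f"lfp_{a.animal_id}.csv"
            write_lfp_csv(a.lfp, p)
            files.append(p)
    p = outdir / "assays.csv"
    write_assays_csv({a.animal_id: (a.group, a.assays) for a in animals}, p)
    files.append(p)
    done("simulate", t0, files)

    # 2. behavior metrics
    t0 = stage("behavior")
    summaries = [
        summarize_behavior(a.animal_id, a.group, a.behavior, a.assays) for a in animals
    ]
    beh = summaries_to_frame(summaries)
    p = outdir / "behavior_summary.csv"
    beh.to_csv(p, index=False, float_format="%.6f")
    done("behavior", t0, [p])

    # 3. spectral band power
    t0 = stage("spectra")
    bps = band_power_summary(
        [(a.animal_id, a.group, a.lfp, a.behavior) for a in animals],
        bands=CANONICAL_BANDS,
        mode=config.zscore_mode,
    )
    p1 = outdir / "band_power_summary.csv"
    bps.table.to_csv(p1, index=False, float_format="%.6f")
    p2 = outdir / "total_power_change.csv"
    bps.total_change.to_csv(p2, index=False, float_format="%.6f")
    done("spectra", t0, [p1, p2])

    # 4. group statistics
    t0 = stage("stats")
    results = group_statistics(beh, bps.table)
    p = outdir / "group_stats.json"
    write_json(results, p)
    done("stats", t0, [p])

    # 5. decode
    t0 = stage("decode")
    dataset = cohort_dataset(
        animals, epoch_length=config.epoch_length_s, mode=config.zscore_mode
    )
    res = decode_with_null(
        dataset,
        n_repeats=config.n_repeats,
        n_shifts=config.n_shifts,
        seed=config.cohort.seed,
    )
    p = outdir / "decoder_result.json"
    write_json(
        {
            "real_accuracy_mean_pct": res.real_mean,
            "real_accuracy_sem_pct": res.real_sem,
            "null_accuracy_mean_pct": res.null_mean,
            "null_accuracy_sem_pct": res.null_sem,
            "null_percentiles_pct": {
                str(q): float(np.percentile(res.null_accuracies, q)) for q in (1, 50, 95, 99)
            },
            "empirical_p": res.empirical_p,
            "base_rate_pct": res.base_rate_pct,
            "per_class_recall": res.per_class_recall,
            "n_epochs": dataset.n_epochs,
            "svc_params": res.svc_params,
            "seed": config.cohort.seed,
        },
        p,
    )
    done("decode", t0, [p])

    manifest["checksums"] = {f.name: _sha256(f) for f in written}
    write_json(manifest, outdir / "manifest.json")
    return manifest


def group_statistics(behavior: pd.DataFrame, band_table: pd.DataFrame) -> dict:
    """The statistical battery over a cohort's tidy tables.

    Unpaired t-tests on the behavioral measures, a mixed group x band ANOVA
    with Bonferroni post hoc per zone on change-in-power, and Pearson
    correlations between per-animal change-in-power and the interaction-zone
    SI ratio.
    """
    out: dict = {}
    ctrl = behavior[behavior["group"] == GROUP_CONTROL]
    dft = behavior[behavior["group"] == GROUP_DEFEAT]

    def t_entry(col):
        r = unpaired_t(ctrl[col].to_numpy(), dft[col].to_numpy())
        return {
            "t": r.statistic,
            "df": r.df[0],
            "p": r.p_two_tailed,
            "mean_control": float(ctrl[col].mean()),
            "mean_defeated": float(dft[col].mean()),
            "n": list(r.n),
        }

    for col in (
        "sucrose_pct",
        "immobility_s",
        "si_ratio_interaction",
        "time_interaction_with_cd1",
        "time_corner_with_cd1",
    ):
        if behavior[col].notna().all():
            out[f"t_test_{col}"] = t_entry(col)

    si = behavior.set_index("animal_id")["si_ratio_interaction"]
    for zone in (ZONE_INTERACTION, ZONE_CORNER):
        sub = band_table[band_table["zone"] == zone].dropna(subset=["change"])
        tbl = sub.rename(columns={"change": "value"})[
            ["animal_id", "group", "band", "value"]
        ]
        counts = tbl.groupby("animal_id").size()
        tbl = tbl[tbl["animal_id"].isin(counts[counts == counts.max()].index)]
        try:
            main, post = mixed_anova(tbl)
            out[f"anova_{zone}"] = {
                "F": main.statistic,
                "df": list(main.df),
                "p": main.p_two_tailed,
                "posthoc": post.drop(columns=["estimate"]).to_dict(orient="records"),
            }
        except ValueError as exc:
            out[f"anova_{zone}"] = {"error": str(exc)}
        for band in sub["band"].unique():
            bsub = sub[sub["band"] == band]
            x = bsub.set_index("animal_id")["change"]
            common = x.index.intersection(si.index)
            if len(common) >= 3 and x.loc[common].std() > 0:
                r = pearson_with_p(x.loc[common].to_numpy(), si.loc[common].to_numpy())
                out[f"correlation_{zone}_{band}"] = {
                    "r": r.statistic,
                    "p": r.p_two_tailed,
                    "slope": r.extra["slope"],
                    "intercept": r.extra["intercept"],
                    "n": len(common),
                }
    return out


def validate_inputs(paths: dict[str, str | Path], bands=CANONICAL_BANDS) -> list[dict]:
    """Schema/sanity checks on on-disk inputs; returns a machine-readable
    issue list (empty when everything is well-formed).

    ``paths`` may contain ``tracking`` (list of files or one file), ``lfp``
    (list or one) and ``assays``.
    """
    issues: list[dict] = []

    def listify(v):
        if v is None:
            return []
        return list(v) if isinstance(v, (list, tuple)) else [v]

    for p in listify(paths.get("tracking")):
        p = Path(p)
        try:
            df = pd.read_csv(p)
        except Exception as exc:
            issues.append({"file": p.name, "issue": f"unreadable: {exc}"})
            continue
        for col in ("time_s", "x_cm", "y_cm", "phase"):
            if col not in df.columns:
                issues.append({"file": p.name, "issue": f"missing column {col!r}"})
        if "time_s" in df.columns and len(df) > 1:
            if np.any(np.diff(df["time_s"].to_numpy()) <= 0):
                issues.append({"file": p.name, "issue": "time_s not strictly increasing"})
        if "phase" in df.columns:
            found = set(df["phase"].astype(str).unique())
            if not {"no_cd1", "with_cd1"} <= found:
                issues.append(
                    {"file": p.name, "issue": f"phases {sorted(found)} do not cover no_cd1/with_cd1"}
                )

    top = max(b.high for b in bands)
    for p in listify(paths.get("lfp")):
        p = Path(p)
        try:
            df = pd.read_csv(p, nrows=1000)
        except Exception as exc:
            issues.append({"file": p.name, "issue": f"unreadable: {exc}"})
            continue
        ch_cols = [c for c in df.columns if c.startswith("ch")]
        if "time_s" not in df.columns or not ch_cols:
            issues.append({"file": p.name, "issue": "expected columns time_s, ch00, ..."})
            continue
        t = df["time_s"].to_numpy()
        if len(t) > 1:
            fs = 1.0 / float(np.median(np.diff(t)))
            if fs <= 2 * top:
                issues.append(
                    {
                        "file": p.name,
                        "issue": f"sampling rate {fs:.1f} Hz violates Nyquist for the "
                        f"{top:.0f} Hz band edge",
                    }
                )

    for p in listify(paths.get("assays")):
        p = Path(p)
        try:
            df = pd.read_csv(p)
        except Exception as exc:
            issues.append({"file": p.name, "issue": f"unreadable: {exc}"})
            continue
        for col in ("animal_id", "group", "sucrose_g", "water_g", "immobility_s"):
            if col not in df.columns:
                issues.append({"file": p.name, "issue": f"missing column {col!r}"})
    return issues
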