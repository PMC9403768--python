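"""Plain-text readers/writers for the pipeline's on-disk formats.

LFP traces travel as CSV (``time_s, ch00, ch01, ...``; microvolts),
tracking as CSV (``time_s, x_cm, y_cm, phase``), assays as a one-row-per-
animal CSV, and results as JSON.  Formats are deliberately flat so every
stage is inspectable and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import AssayRecord, BehaviorSession
from .spectral import LfpRecording


def write_lfp_csv(lfp: LfpRecording, path: str | Path, fmt: str = "%.3f") -> None:
    n_ch, n = lfp.samples.shape
    cols = ["time_s"] + [f"ch{c:02d}" for c in range(n_ch)]
    data = np.column_stack([np.arange(n) / lfp.sampling_rate, lfp.samples.T])
    header = ",".join(cols)
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt=fmt)


def read_lfp_csv(path: str | Path, animal_id: str = "") -> LfpRecording:
    df = pd.read_csv(path)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if "time_s" not in df.columns or not ch_cols:
        raise ValueError(f"{path}: expected columns time_s, ch00, ch01, ...")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time_s is not uniformly sampled")
    return LfpRecording(
        samples=df[ch_cols].to_numpy().T,
        sampling_rate=1.0 / float(dt[0]),
        animal_id=animal_id,
    )


def write_tracking_csv(session: BehaviorSession, path: str | Path) -> None:
    df = session.track.copy()
    df["phase"] = session.phase_of(df["time_s"].to_numpy())
    df.to_csv(path, index=False, float_format="%.4f")


def read_tracking_csv(path: str | Path) -> BehaviorSession:
    df = pd.read_csv(path)
    required = {"time_s", "x_cm", "y_cm", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tracking file missing columns {sorted(missing)}")
    phases = {}
    t = df["time_s"].to_numpy()
    med_dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    for name, sub in df.groupby("phase"):
        ts = sub["time_s"].to_numpy()
        phases[str(name)] = (float(ts.min()), float(ts.max()) + med_dt)
    return BehaviorSession(track=df[["time_s", "x_cm", "y_cm"]], phases=phases)


def write_assays_csv(records: dict[str, tuple[str, AssayRecord]], path: str | Path) -> None:
    """``records`` maps animal_id -> (group, AssayRecord)."""
    rows = [
        dict(
            animal_id=aid,
            group=group,
            sucrose_g=rec.sucrose_consumption_g,
            water_g=rec.water_consumption_g,
            immobility_s=rec.immobility_s,
        )
        for aid, (group, rec) in records.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")


def read_assays_csv(path: str | Path) -> dict[str, tuple[str, AssayRecord]]:
    df = pd.read_csv(path)
    required = {"animal_id", "group", "sucrose_g", "water_g", "immobility_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: assay file missing columns {sorted(missing)}")
    return {
        row["animal_id"]: (
            row["group"],
            AssayRecord(row["sucrose_g"], row["water_g"], row["immobility_s"]),
        )
        for _, row in df.iterrows()
    }


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
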