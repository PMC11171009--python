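"""Plain-text I/O for traces, NN series and case tables.

Traces travel as a two-column CSV (time_s, value) plus a JSON sidecar
holding the sampling rate, phase marks, invalid spans and any
synthetic ground truth.  The same reader accepts real sensor exports
with (time, value) columns and no sidecar — the sampling rate is then
inferred from the median time step.  Case tables are flat CSV, one row
per patient-day.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import SignalTrace, NNSeries

__all__ = [
    "write_trace",
    "read_trace",
    "write_nn",
    "read_nn",
    "write_case_table",
    "read_case_table",
]


def _spans_from_mask(mask: np.ndarray, fs: float) -> list[list[float]]:
    """Invalid (False) spans of a boolean mask as [start_s, stop_s)."""
    spans = []
    bad = ~mask
    idx = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    for start, stop in zip(idx[0::2], idx[1::2]):
        spans.append([start / fs, stop / fs])
    return spans


def write_trace(trace: SignalTrace, basepath: str | Path) -> None:
    """Write ``<base>.csv`` (time_s,value) and ``<base>.json`` sidecar."""
    base = Path(basepath)
    df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
    df.to_csv(base.with_suffix(".csv"), index=False)
    meta = {k: v for k, v in trace.meta.items() if not k.startswith("_")}
    sidecar = {
        "fs": trace.fs,
        "phase_marks": trace.phase_marks,
        "invalid_spans": _spans_from_mask(trace.valid_mask, trace.fs),
        "meta": _jsonable(meta),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_trace(basepath: str | Path) -> SignalTrace:
    """Read a trace CSV, honouring a JSON sidecar when present."""
    base = Path(basepath)
    csv_path = base if base.suffix == ".csv" else base.with_suffix(".csv")
    df = pd.read_csv(csv_path)
    tcol, vcol = df.columns[:2]
    t = df[tcol].to_numpy(dtype=float)
    x = df[vcol].to_numpy(dtype=float)
    sidecar_path = csv_path.with_suffix(".json")
    fs = None
    phase_marks: dict = {}
    meta: dict = {}
    mask = np.ones(x.size, dtype=bool)
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        fs = side.get("fs")
        phase_marks = side.get("phase_marks", {})
        meta = side.get("meta", {})
        for start, stop in side.get("invalid_spans", []):
            i0, i1 = int(round(start * fs)), int(round(stop * fs))
            mask[i0:i1] = False
    if fs is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ValueError("cannot infer sampling rate from time column")
        fs = 1.0 / dt
    for key in ("true_beats", "true_peak_times", "true_peak_values",
                "true_valley_times", "true_valley_values"):
        if key in meta:
            meta[key] = np.asarray(meta[key], dtype=float)
    return SignalTrace(
        samples=x, fs=float(fs), valid_mask=mask,
        phase_marks=phase_marks, meta=meta,
    )


def write_nn(nn: NNSeries, path: str | Path) -> None:
    """NN series as CSV (beat_time_s, nn_ms); nn_ms empty-padded when
    cleaning removed intervals."""
    n = nn.beat_times.size
    nn_col = np.full(n, np.nan)
    nn_col[1:1 + nn.nn_ms.size] = nn.nn_ms
    pd.DataFrame(
        {"beat_time_s": nn.beat_times, "nn_ms": nn_col}
    ).to_csv(path, index=False)


def read_nn(path: str | Path) -> NNSeries:
    df = pd.read_csv(path)
    nn = df["nn_ms"].dropna().to_numpy(dtype=float)
    return NNSeries(
        beat_times=df["beat_time_s"].to_numpy(dtype=float), nn_ms=nn
    )


def write_case_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_case_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
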