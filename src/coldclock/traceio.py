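"""CSV persistence for multi-channel traces.

Layout: one file per slice, header row mandatory, columns ``time_h``,
``temp_C`` and one column per reporter channel; UTF-8, '.' decimal.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MultiChannelTrace

REQUIRED_COLUMNS = ("time_h", "temp_C")
#: relative tolerance for the uniform-grid check, in hours
GRID_TOL_H = 1e-6


class TraceFormatError(ValueError):
    """A trace CSV violated the format contract."""


def write_trace_csv(trace: MultiChannelTrace, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_h": trace.time_h, "temp_C": trace.temp_C})
    for name, vals in trace.channels.items():
        df[name] = vals
    df.to_csv(path, index=False)


def read_trace_csv(path) -> MultiChannelTrace:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}")
    channels = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if not channels:
        raise TraceFormatError(f"{path}: no channel columns")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise TraceFormatError(f"{path}: NaN value at data row {row}")
    t = df["time_h"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TraceFormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt == 0):
        row = int(np.argmax(dt == 0)) + 1
        raise TraceFormatError(f"{path}: duplicate time stamp at data row {row}")
    if np.any(dt < 0):
        row = int(np.argmax(dt < 0)) + 1
        raise TraceFormatError(f"{path}: non-monotone time at data row {row}")
    step = dt[0]
    bad = np.abs(dt - step) > GRID_TOL_H
    if np.any(bad):
        row = int(np.argmax(bad)) + 1
        raise TraceFormatError(
            f"{path}: non-uniform sampling at data row {row} "
            f"(step {dt[np.argmax(bad)]:.6g} h, expected {step:.6g} h)"
        )
    return MultiChannelTrace(
        time_h=t,
        temp_C=df["temp_C"].to_numpy(dtype=float),
        channels={c: df[c].to_numpy(dtype=float) for c in channels},
        meta={"source": str(path), "slice_id": path.stem},
    )
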