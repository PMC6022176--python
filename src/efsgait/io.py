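"""CSV interchange formats.

Two dialects, both plain headed CSV with times in seconds written at
full precision:

* signal CSV: ``time_s,value_v`` — one uniformly sampled voltage
  channel; the sample rate is inferred from the median time step on
  read and sampling must be uniform to within 1e-6 relative jitter;
* events CSV: ``time_s,kind`` with ``kind`` in {IC, SE} — a
  time-ordered event sequence.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .events import GaitEvents
from .sensors import SignalTrace

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_events_csv",
    "write_events_csv",
    "write_params_csv",
    "read_params_csv",
]

_FLOAT_FMT = "%.17g"  # lossless round trip for float64
_REL_JITTER = 1e-6


def write_signal_csv(trace: SignalTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value_v": trace.samples})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_signal_csv(path, channel: str = "efs") -> SignalTrace:
    """Read a signal CSV; infer the sample rate from the median Δt."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "value_v"]:
        raise FormatError(f"{path}: expected header 'time_s,value_v', got {list(df.columns)}")
    if len(df) == 0:
        raise FormatError(f"{path}: signal file contains no samples")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer the sample rate")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        bad = int(np.argmax(dt <= 0))
        raise FormatError(f"{path}: time must be strictly increasing (row {bad + 3})")
    bad = np.abs(dt - med) > _REL_JITTER * med
    if bad.any():
        row = int(np.argmax(bad)) + 3  # 1-based, after header and first sample
        raise FormatError(f"{path}: non-uniform sampling beyond tolerance at row {row}")
    return SignalTrace(
        channel=channel,
        fs=1.0 / med,
        t0=float(t[0]),
        samples=df["value_v"].to_numpy(dtype=float),
    )


def write_events_csv(events: GaitEvents, path) -> None:
    df = pd.DataFrame({"time_s": events.times, "kind": events.kinds})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path, source: str = "truth") -> GaitEvents:
    """Read an events CSV; ordering and alternation are validated."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "kind"]:
        raise FormatError(f"{path}: expected header 'time_s,kind', got {list(df.columns)}")
    if len(df) == 0:
        return GaitEvents(np.empty(0), np.empty(0, dtype=object), source=source)
    try:
        return GaitEvents(
            df["time_s"].to_numpy(dtype=float),
            df["kind"].to_numpy(dtype=object),
            source=source,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_params_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_params_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
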