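"""Per-cycle temporal gait parameters.

From an alternating IC/SE event sequence, each consecutive triple
``(IC_m, SE_n, IC_{m+1})`` yields one gait cycle:

* ``Tg = IC_{m+1} - IC_m`` — gait-cycle duration,
* ``Ts = SE_n - IC_m`` — stance-phase duration,
* ``Tw = IC_{m+1} - SE_n = Tg - Ts`` — swing-phase duration,
* ``C = (60 / Tg[s]) * 2`` — cadence in steps/min (two steps per cycle),
* ``RS = Ts/Tg``, ``RW = Tw/Tg`` — phase ratios (~60 %/40 % in
  healthy gait).

Durations are stored in milliseconds; cadence is computed as
``120000 / Tg[ms]``.  Partial cycles at either end of the sequence
(a leading SE, trailing events after the last IC) are dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InconsistentEventsError
from .events import GaitEvents, IC

__all__ = ["CYCLE_COLUMNS", "compute_cycle_params", "summarize_params"]

#: Column order of the per-cycle parameter table.
CYCLE_COLUMNS = ["cycle_index", "ic_time_s", "tg_ms", "ts_ms", "tw_ms", "cadence_spm", "rs", "rw"]

_PARAM_COLUMNS = CYCLE_COLUMNS[2:]


def compute_cycle_params(events: GaitEvents) -> pd.DataFrame:
    """Build the per-cycle parameter table from an event sequence.

    Returns a DataFrame with one row per complete cycle and the columns
    in :data:`CYCLE_COLUMNS` (``ic_time_s`` is the cycle's starting IC,
    kept so cycles from different detectors can be paired).  Fewer than
    two IC events yield an empty table with a warning.
    """
    ic = events.ic_times
    se = events.se_times
    if ic.size < 2:
        warnings.warn("fewer than 2 IC events; no complete gait cycle")
        return pd.DataFrame(columns=CYCLE_COLUMNS)

    rows = []
    for m in range(ic.size - 1):
        in_cycle = se[(se > ic[m]) & (se < ic[m + 1])]
        if in_cycle.size != 1:
            # Alternation guarantees exactly one SE per IC pair; anything
            # else means the sequence was built outside GaitEvents.
            raise InconsistentEventsError(f"cycle {m}: expected exactly 1 SE between ICs, found {in_cycle.size}")
        ts_ms = (in_cycle[0] - ic[m]) * 1000.0
        tw_ms = (ic[m + 1] - in_cycle[0]) * 1000.0
        tg_ms = ts_ms + tw_ms  # the Tg = Ts + Tw identity holds exactly
        if tg_ms <= 0 or ts_ms <= 0:
            raise InconsistentEventsError(f"cycle {m}: non-positive phase duration")
        rows.append(
            {
                "cycle_index": m,
                "ic_time_s": ic[m],
                "tg_ms": tg_ms,
                "ts_ms": ts_ms,
                "tw_ms": tw_ms,
                "cadence_spm": 120000.0 / tg_ms,
                "rs": ts_ms / tg_ms,
                "rw": tw_ms / tg_ms,
            }
        )
    df = pd.DataFrame(rows, columns=CYCLE_COLUMNS)
    df["cycle_index"] = df["cycle_index"].astype(int)
    return df


def summarize_params(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample sd, min and max per parameter column.

    The sample standard deviation uses ``n - 1``; a single-cycle table
    gets ``sd = 0`` and is flagged via ``result.attrs["degenerate_n"]``.
    ``result.attrs["n"]`` records the number of cycles.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty parameter table")
    n = len(table)
    cols = [c for c in _PARAM_COLUMNS if c in table.columns]
    vals = table[cols]
    out = pd.DataFrame(
        {
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if n > 1 else pd.Series(0.0, index=cols),
            "min": vals.min(),
            "max": vals.max(),
        }
    )
    out.attrs["n"] = n
    out.attrs["degenerate_n"] = n == 1
    return out
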