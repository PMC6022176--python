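"""Foot-event detection on the pressure and electrostatic channels.

Pressure channel (three-step procedure)
---------------------------------------
1. Locate the stance time zones from the rising and falling edges of
   the insole voltage: a monotone run crossing a fixed threshold
   (default 1 V — far above the no-load output, far below the loaded
   plateau) upward is a rising edge, downward a falling edge.
2. Because the no-load output drifts, the signal minimum bounding each
   edge — not a fixed level — anchors the event.  The minimum is found
   from the smoothed derivative: walk from the derivative's peak on the
   edge back (rising) or forward (falling) to its zero crossing.
3. Correct the anchor by an offset of 3 % of the cycle's local
   max-minus-min swing: IC is the first time after the pre-rise minimum
   at which the raw signal exceeds ``min + offset`` (on the loading
   ramp), SE the last time before the post-fall minimum at which it
   still does.

EFS channel (peak extraction)
-----------------------------
The induced current is maximal as the foot accelerates off the ground
and minimal (most negative) as it decelerates into contact, so the
positive peaks of the trace mark foot-off (SE) and the negative troughs
mark initial contact (IC).  Peaks are taken on a lightly smoothed trace
with a prominence floor (a fraction of the trace's peak-to-peak swing)
and a minimum mutual separation; SE/IC alternation is enforced by
dropping the less prominent member of any same-kind adjacent pair
(ties keep the earlier event).  If the electrode polarity is unknown,
``auto_polarity`` flips the labels when the trough→peak spacing pattern
indicates an inverted channel (stance, trough→peak, should be the
longer of the two inter-event gaps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientSignalError, MalformedSignalError
from .events import GaitEvents, IC, SE
from .sensors import SignalTrace

__all__ = ["DetectorConfig", "detect_pressure_events", "detect_efs_events"]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of both detectors."""

    pressure_threshold: float = 1.0      # stance-zone threshold, V
    offset_frac: float = 0.03            # step-3 offset as a fraction of the cycle swing
    min_event_gap: float = 0.3           # minimum spacing of same-kind events, s
    efs_smooth_window: float = 0.05      # moving-average width, s (both channels)
    efs_min_prominence_frac: float = 0.2 # prominence floor, fraction of peak-to-peak
    auto_polarity: bool = False          # flip SE/IC labels on an inverted electrode
    crossing_sustain: float = 0.005      # offset crossing must hold this long, s

    def __post_init__(self):
        if not 0.0 < self.offset_frac < 1.0:
            raise ValueError("offset_frac must lie in (0, 1)")
        if self.min_event_gap <= 0:
            raise ValueError("min_event_gap must be positive")
        if self.efs_smooth_window < 0:
            raise ValueError("efs_smooth_window must be non-negative")
        if not 0.0 < self.efs_min_prominence_frac < 1.0:
            raise ValueError("efs_min_prominence_frac must lie in (0, 1)")


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with edge-shortened windows (no phase shift)."""
    w = int(width)
    if w <= 1:
        return np.asarray(x, dtype=float).copy()
    w += 1 - w % 2  # force odd so the window is symmetric
    n = x.size
    c = np.concatenate([[0.0], np.cumsum(np.asarray(x, dtype=float))])
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _first_above(x: np.ndarray, start: int, stop: int, level: float, sustain: int = 1) -> int | None:
    """First index in [start, stop) from which x > level holds for ``sustain`` samples.

    The sustain requirement rejects isolated noise excursions above the
    level without moving the crossing on a clean monotone ramp.
    """
    seg = x[start:stop] > level
    if seg.size < sustain:
        return None
    if sustain > 1:
        runs = np.convolve(seg.astype(float), np.ones(sustain), mode="valid") == sustain
    else:
        runs = seg
    if not runs.any():
        return None
    return start + int(np.argmax(runs))


def _last_above(x: np.ndarray, start: int, stop: int, level: float, sustain: int = 1) -> int | None:
    """Last index in [start, stop) up to which x > level held for ``sustain`` samples."""
    seg = x[start:stop] > level
    rev = _first_above(seg[::-1].astype(float), 0, seg.size, 0.5, sustain)
    if rev is None:
        return None
    return start + int(seg.size - 1 - rev)


def detect_pressure_events(trace: SignalTrace, cfg: DetectorConfig | None = None) -> GaitEvents:
    """Run the three-step stance segmentation on a pressure trace.

    Returns strictly alternating IC/SE events; partial stances at the
    trace boundaries (an unloading without a loading edge, or vice
    versa) are dropped.  A trace that never crosses the threshold
    yields an empty result with a warning.
    """
    cfg = cfg or DetectorConfig()
    if trace.channel != "pressure":
        raise ValueError("detect_pressure_events expects a pressure trace")
    x = trace.samples
    fs = trace.fs
    win = max(1, int(round(cfg.efs_smooth_window * fs)))
    xs = _moving_average(x, win)
    thr = cfg.pressure_threshold

    above = xs >= thr
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1     # first sample at/above thr
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1   # first sample below thr
    if up.size == 0 and down.size == 0:
        warnings.warn("pressure trace never crosses the threshold; no events detected")
        return GaitEvents(np.empty(0), np.empty(0, dtype=object), source="pressure")

    # Pair each rising edge with the next falling edge; drop boundary partials.
    down = down[down > (up[0] if up.size else -1)]
    pairs = []
    for k, u in enumerate(up):
        nxt = down[down > u]
        if nxt.size == 0:
            break  # trailing stance runs past the end of the trace
        d = int(nxt[0])
        if k + 1 < up.size and up[k + 1] < d:
            raise MalformedSignalError("two rising edges without a falling edge", index=int(up[k + 1]))
        pairs.append((int(u), d))
    if not pairs:
        warnings.warn("no complete stance zone inside the trace; no events detected")
        return GaitEvents(np.empty(0), np.empty(0, dtype=object), source="pressure")

    dxs = _moving_average(np.gradient(xs), win)
    half = max(win, int(round(cfg.min_event_gap * fs / 2)))
    n = x.size
    times, kinds = [], []
    for u, d in pairs:
        # Step 2, rising side: derivative peak on the edge, walk left to its zero point.
        a = max(0, u - half)
        p = a + int(np.argmax(dxs[a:min(n, u + half)]))
        j = p
        while j > 0 and dxs[j - 1] > 0:
            j -= 1
        min_rise = xs[j]
        # Step 2, falling side: derivative trough, walk right to its zero point.
        a = max(0, d - half)
        q = a + int(np.argmin(dxs[a:min(n, d + half)]))
        k = q
        while k < n - 1 and dxs[k + 1] < 0:
            k += 1
        min_fall = xs[k]

        vmax = float(xs[u:d].max()) if d > u else float(xs[u])
        sustain = max(1, int(round(cfg.crossing_sustain * fs)))
        ic_idx = _first_above(x, j, d, min_rise + cfg.offset_frac * (vmax - min_rise), sustain)
        se_idx = _last_above(x, u, k + 1, min_fall + cfg.offset_frac * (vmax - min_fall), sustain)
        if ic_idx is None or se_idx is None or se_idx <= ic_idx:
            raise MalformedSignalError("could not place IC/SE inside a stance zone", index=u)
        times.extend([trace.t0 + ic_idx / fs, trace.t0 + se_idx / fs])
        kinds.extend([IC, SE])

    return GaitEvents(np.array(times), np.array(kinds, dtype=object), source="pressure")


def detect_efs_events(trace: SignalTrace, cfg: DetectorConfig | None = None) -> GaitEvents:
    """Extract SE (positive peaks) and IC (negative troughs) from an EFS trace."""
    cfg = cfg or DetectorConfig()
    if trace.channel != "efs":
        raise ValueError("detect_efs_events expects an efs trace")
    x = trace.samples
    fs = trace.fs
    win = max(1, int(round(cfg.efs_smooth_window * fs)))
    xs = _moving_average(x, win)
    ptp = float(xs.max() - xs.min()) if xs.size else 0.0
    if ptp <= 0:
        raise InsufficientSignalError("trace has no peak-to-peak swing")
    prom = cfg.efs_min_prominence_frac * ptp
    dist = max(1, int(round(cfg.min_event_gap * fs)))

    pk, pk_props = find_peaks(xs, prominence=prom, distance=dist)
    tr, tr_props = find_peaks(-xs, prominence=prom, distance=dist)
    cand = sorted(
        [(int(i), SE, float(p)) for i, p in zip(pk, pk_props["prominences"])]
        + [(int(i), IC, float(p)) for i, p in zip(tr, tr_props["prominences"])]
    )

    # Enforce alternation: of adjacent same-kind events keep the more
    # prominent one; on a tie keep the earlier.
    kept: list[tuple[int, str, float]] = []
    for ev in cand:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    if len(kept) < 2:
        raise InsufficientSignalError("fewer than 2 alternating peaks retained")

    kinds = np.array([k for _, k, _ in kept], dtype=object)
    if cfg.auto_polarity and _polarity_flipped(np.array([i for i, _, _ in kept]), kinds):
        kinds = np.where(kinds == SE, IC, SE).astype(object)
    times = trace.t0 + np.array([i for i, _, _ in kept]) / fs
    return GaitEvents(times, kinds, source="efs")


def _polarity_flipped(idx: np.ndarray, kinds: np.ndarray) -> bool:
    """Heuristic polarity check.

    With correct polarity the trough(IC)→peak(SE) gap is the stance
    (~60 % of the cycle) and peak→trough the swing (~40 %).  If the
    median trough→peak gap is the shorter one, the electrode polarity
    is inverted and the labels should swap.
    """
    gaps = np.diff(idx)
    ic_to_se = gaps[kinds[:-1] == IC]
    se_to_ic = gaps[kinds[:-1] == SE]
    if ic_to_se.size == 0 or se_to_ic.size == 0:
        return False
    return bool(np.median(ic_to_se) < np.median(se_to_ic))
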