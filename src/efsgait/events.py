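"""Ordered gait-event sequences.

A gait cycle is delimited by initial contacts (IC, heel strike) of one
foot; the separate event (SE, foot-off) splits it into a stance and a
swing phase.  :class:`GaitEvents` is the common currency between the
detectors, the parameter computation and the agreement statistics: a
time-ordered sequence of labelled events that strictly alternates
between IC and SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IC = "IC"
SE = "SE"
_KINDS = (IC, SE)


@dataclass(frozen=True)
class GaitEvents:
    """Time-ordered, strictly alternating IC/SE events of one foot.

    Parameters
    ----------
    times
        Event timestamps in seconds, strictly increasing.
    kinds
        Event labels, one of ``"IC"`` or ``"SE"`` per event; adjacent
        labels must differ (stance and swing alternate).
    source
        Which channel produced the events: ``"pressure"``, ``"efs"`` or
        ``"truth"``.
    """

    times: np.ndarray
    kinds: np.ndarray
    source: str = "truth"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        kinds = np.asarray(self.kinds, dtype=object)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "kinds", kinds)
        if times.ndim != 1 or kinds.shape != times.shape:
            raise ValueError("times and kinds must be 1-D arrays of equal length")
        if not set(kinds) <= set(_KINDS):
            bad = sorted(set(kinds) - set(_KINDS))
            raise ValueError(f"unknown event kind(s): {bad}")
        if times.size > 1:
            if np.any(np.diff(times) <= 0):
                i = int(np.argmax(np.diff(times) <= 0))
                raise ValueError(f"event times must be strictly increasing (at position {i + 1})")
            if np.any(kinds[1:] == kinds[:-1]):
                i = int(np.argmax(kinds[1:] == kinds[:-1]))
                raise ValueError(f"event kinds must alternate (position {i + 1} repeats {kinds[i + 1]})")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def ic_times(self) -> np.ndarray:
        return self.times[self.kinds == IC]

    @property
    def se_times(self) -> np.ndarray:
        return self.times[self.kinds == SE]

    def shifted(self, dt: float) -> "GaitEvents":
        """Translate every event time by ``dt`` seconds."""
        return GaitEvents(self.times + dt, self.kinds.copy(), self.source)

    def within(self, t_start: float, t_end: float) -> "GaitEvents":
        """Keep only events with ``t_start <= t <= t_end``."""
        m = (self.times >= t_start) & (self.times <= t_end)
        return GaitEvents(self.times[m], self.kinds[m], self.source)


def events_from_arrays(ic_times, se_times, source: str = "truth") -> GaitEvents:
    """Merge separate IC and SE time arrays into one alternating sequence."""
    ic_times = np.asarray(ic_times, dtype=float)
    se_times = np.asarray(se_times, dtype=float)
    times = np.concatenate([ic_times, se_times])
    kinds = np.array([IC] * ic_times.size + [SE] * se_times.size, dtype=object)
    order = np.argsort(times, kind="stable")
    return GaitEvents(times[order], kinds[order], source)
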