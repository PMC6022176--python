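"""Ground-truth gait timing and foot kinematics.

This module is the hidden truth of the simulator.  It draws per-cycle
gait timing from a pace class (slow / normal / fast walking), producing
an :class:`EventSchedule` of initial-contact (IC) and foot-off (SE)
instants, and turns a schedule into a :class:`FootTrajectory`: the foot
height above ground ``h(t)`` and the equivalent sole–ground plate area
``s_s(t)`` that drive the electrostatic and pressure forward models.

Pace classes
------------
Cycle durations are drawn from a truncated normal distribution.  The
three built-in profiles reproduce the timing statistics of healthy
adults stepping to a metronome at three speeds:

========  ============  ==============
profile   Tg mean ± sd  Tg range (ms)
========  ============  ==============
fast       990 ± 120     870–1153
normal    1198 ± 110    1088–1398
slow      1498 ±  75    1358–1697
========  ============  ==============

The stance phase occupies ~60 % of the cycle in healthy gait; per-cycle
stance fractions are drawn from a truncated normal around that value.

Swing trajectory
----------------
During swing the foot lifts quickly at foot-off, travels at roughly
constant clearance height, and drops quickly into heel strike.  ``h(t)``
is therefore a smoothed trapezoid: cosine S-ramps of duration ``lift_s``
at each end of the swing and a flat plateau at ``h_max`` in between.
This concentrates ``dh/dt`` — and hence the induced current — in short
bursts just after foot-off and just before initial contact, which is
the physical basis of peak-based event detection on the electrostatic
channel.  The area ``s_s(t)`` stays at ``s_max`` while the foot is flat
on the ground, rolls off to ``s_min`` over the last ``roll_fraction``
of stance (heel rise / toe roll) and loads back up over the first
``roll_fraction`` after contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .events import GaitEvents, events_from_arrays

__all__ = [
    "PaceProfile",
    "PACE_PROFILES",
    "EventSchedule",
    "FootTrajectory",
    "sample_event_schedule",
    "synthesize_trajectory",
    "contralateral_schedule",
]

#: Hard clip bounds on the per-cycle stance fraction.
STANCE_FRACTION_BOUNDS = (0.4, 0.8)


@dataclass(frozen=True)
class PaceProfile:
    """Timing statistics of one walking-pace class.

    Durations are in milliseconds; ``stance_fraction_*`` are
    dimensionless fractions of the cycle duration.
    """

    name: str
    tg_mean: float
    tg_sd: float
    tg_min: float
    tg_max: float
    stance_fraction_mean: float = 0.60
    stance_fraction_sd: float = 0.02

    def __post_init__(self):
        if not (self.tg_min <= self.tg_mean <= self.tg_max):
            raise ValueError("require tg_min <= tg_mean <= tg_max")
        if self.tg_sd < 0 or self.stance_fraction_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 < self.stance_fraction_mean < 1.0:
            raise ValueError("stance_fraction_mean must lie in (0, 1)")


PACE_PROFILES: dict[str, PaceProfile] = {
    "fast": PaceProfile("fast", 990.0, 120.0, 870.0, 1153.0),
    "normal": PaceProfile("normal", 1198.0, 110.0, 1088.0, 1398.0),
    "slow": PaceProfile("slow", 1498.0, 75.0, 1358.0, 1697.0),
}


@dataclass(frozen=True)
class EventSchedule:
    """Ground-truth IC and SE timestamps (seconds) of one foot.

    A schedule of ``n`` cycles holds ``n + 1`` IC times and ``n`` SE
    times, strictly alternating ``IC_m < SE_m < IC_{m+1}`` (stance then
    swing).  A degenerate schedule with a single IC and no SE describes
    a foot standing on the ground.
    """

    foot_id: str
    ic_times: np.ndarray
    se_times: np.ndarray

    def __post_init__(self):
        ic = np.asarray(self.ic_times, dtype=float)
        se = np.asarray(self.se_times, dtype=float)
        object.__setattr__(self, "ic_times", ic)
        object.__setattr__(self, "se_times", se)
        if self.foot_id not in ("left", "right"):
            raise ValueError("foot_id must be 'left' or 'right'")
        if ic.size != se.size + 1:
            raise ValueError("a schedule needs exactly one more IC than SE")
        if ic.size > 1 and np.any(np.diff(ic) <= 0):
            raise ValueError("ic_times must be strictly increasing")
        if se.size > 1 and np.any(np.diff(se) <= 0):
            raise ValueError("se_times must be strictly increasing")
        if se.size and not (np.all(ic[:-1] < se) and np.all(se < ic[1:])):
            raise ValueError("events must alternate: IC_m < SE_m < IC_{m+1}")

    @property
    def n_cycles(self) -> int:
        return int(self.se_times.size)

    @property
    def cycle_durations(self) -> np.ndarray:
        """Tg per cycle, seconds."""
        return np.diff(self.ic_times)

    @property
    def stance_durations(self) -> np.ndarray:
        """Ts per cycle, seconds."""
        return self.se_times - self.ic_times[:-1]

    @property
    def swing_durations(self) -> np.ndarray:
        """Tw per cycle, seconds."""
        return self.ic_times[1:] - self.se_times

    def to_events(self, source: str = "truth") -> GaitEvents:
        return events_from_arrays(self.ic_times, self.se_times, source=source)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sample a normal(mean, sd) truncated to [lo, hi]."""
    if not lo <= hi:
        raise ValueError("require lo <= hi")
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ValueError("zero-variance draw with mean outside [lo, hi]")
        return np.full(size, float(mean))
    out = np.empty(size)
    pending = np.arange(size)
    while pending.size:
        draw = rng.normal(mean, sd, size=pending.size)
        ok = (draw >= lo) & (draw <= hi)
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return out


def sample_event_schedule(
    profile: PaceProfile,
    n_cycles: int,
    seed: int,
    foot_id: str = "right",
    t_start: float = 0.0,
) -> EventSchedule:
    """Draw a ground-truth event schedule for one foot.

    Cycle durations come from the profile's truncated normal; each
    stance duration is the cycle duration times a stance fraction drawn
    from a truncated normal clipped to ``STANCE_FRACTION_BOUNDS``.
    Identical ``(profile, n_cycles, seed)`` reproduce the schedule
    bit-for-bit.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    tg_s = _truncated_normal(
        rng, profile.tg_mean, profile.tg_sd, profile.tg_min, profile.tg_max, n_cycles
    ) / 1000.0
    lo, hi = STANCE_FRACTION_BOUNDS
    frac = _truncated_normal(
        rng, profile.stance_fraction_mean, profile.stance_fraction_sd, lo, hi, n_cycles
    )
    ic = t_start + np.concatenate([[0.0], np.cumsum(tg_s)])
    se = ic[:-1] + tg_s * frac
    return EventSchedule(foot_id=foot_id, ic_times=ic, se_times=se)


def contralateral_schedule(schedule: EventSchedule) -> EventSchedule:
    """Derive the opposite foot's schedule, phase-shifted by half a cycle.

    The opposite foot strikes mid-way through each of the reference
    foot's cycles and reuses its per-cycle stance fractions.  One cycle
    is lost at the boundary.  Only used to enrich the simulated
    electrostatic waveform; the reference (instrumented) foot is the
    right one.
    """
    if schedule.n_cycles < 2:
        raise ValueError("need at least 2 cycles to derive the opposite foot")
    tg = schedule.cycle_durations
    ic = schedule.ic_times[:-1] + 0.5 * tg
    frac = schedule.stance_durations / tg
    se = ic[:-1] + frac[:-1] * np.diff(ic)
    other = "left" if schedule.foot_id == "right" else "right"
    return EventSchedule(foot_id=other, ic_times=ic, se_times=se)


@dataclass(frozen=True)
class FootTrajectory:
    """Foot height and sole–ground equivalent area on a uniform grid.

    ``h`` is zero on every stance interval and strictly positive inside
    every swing; ``s_s`` is bounded in ``[s_min, s_max]`` with
    ``s_min > 0`` so the electrostatic forward model never divides by
    zero.
    """

    t: np.ndarray
    h: np.ndarray
    s_s: np.ndarray
    schedule: EventSchedule

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def _cosine_step(u: np.ndarray) -> np.ndarray:
    """Smooth 0→1 S-ramp on u in [0, 1] with zero slope at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def synthesize_trajectory(
    schedule: EventSchedule,
    h_max: float = 0.15,
    s_max: float = 0.025,
    s_min: float = 0.002,
    roll_fraction: float = 0.15,
    fs: float = 4000.0,
    lift_s: float = 0.05,
    pad_s: float = 0.5,
    lead_s: float = 0.5,
) -> FootTrajectory:
    """Generate foot height and contact-area series from a schedule.

    Parameters
    ----------
    h_max
        Peak swing clearance in metres.
    s_max, s_min
        Sole–ground equivalent plate area (m²) when flat on the ground
        and when airborne (residual toe/heel proximity); ``s_min > 0``.
    roll_fraction
        Fraction of each stance spent in the loading ramp after IC and
        in the roll-off ramp before SE (each), ``0 < roll_fraction < 0.5``.
    fs
        Sample rate of the generated grid, Hz.
    lift_s
        Duration of the lift/landing S-ramps bounding each swing,
        seconds; capped at 30 % of the swing so short swings stay smooth.
    pad_s
        Trailing padding after the final IC, seconds.
    lead_s
        Lead-in before the first IC, seconds; the foot rests on the
        ground (``h = 0``) during the lead-in, as a recording that
        starts before the first analysed step would show.
    """
    if s_min <= 0:
        raise ValueError("s_min must be positive")
    if s_min >= s_max:
        raise ValueError("require s_min < s_max")
    if not 0.0 < roll_fraction < 0.5:
        raise ValueError("roll_fraction must lie in (0, 0.5)")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if lift_s <= 0:
        raise ValueError("lift_s must be positive")
    if lead_s < 0 or pad_s < 0:
        raise ValueError("lead_s and pad_s must be non-negative")

    t0 = float(schedule.ic_times[0]) - lead_s
    t_end = float(schedule.ic_times[-1]) + pad_s
    n = int(round((t_end - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    h = np.zeros(n)
    s_s = np.full(n, s_max)

    # Swing intervals: (SE_m, IC_{m+1}).
    for se, ic_next in zip(schedule.se_times, schedule.ic_times[1:]):
        tw = ic_next - se
        tr = min(lift_s, 0.3 * tw)
        i0 = int(np.searchsorted(t, se, side="right"))
        i1 = int(np.searchsorted(t, ic_next, side="left"))
        u = t[i0:i1] - se
        seg = np.where(
            u <= tr,
            h_max * _cosine_step(u / tr),
            np.where(u >= tw - tr, h_max * _cosine_step((tw - u) / tr), h_max),
        )
        h[i0:i1] = seg
        s_s[i0:i1] = s_min

    # Stance loading / roll-off ramps of the contact area.
    stance_bounds = list(zip(schedule.ic_times[:-1], schedule.se_times))
    stance_bounds.append((schedule.ic_times[-1], t_end))  # final open stance
    for k, (ic, se) in enumerate(stance_bounds):
        d = se - ic
        r = roll_fraction * d
        if k > 0:  # first stance follows the lead-in rest: foot already flat
            i0 = int(np.searchsorted(t, ic, side="left"))
            i1 = int(np.searchsorted(t, min(ic + r, t_end), side="left"))
            u = (t[i0:i1] - ic) / r if r > 0 else np.empty(0)
            s_s[i0:i1] = s_min + (s_max - s_min) * _cosine_step(u)
        if k < len(stance_bounds) - 1:  # no roll-off in the final open stance
            j0 = int(np.searchsorted(t, se - r, side="right"))
            j1 = int(np.searchsorted(t, se, side="right"))
            u = (se - t[j0:j1]) / r
            s_s[j0:j1] = s_min + (s_max - s_min) * _cosine_step(u)

    return FootTrajectory(t=t, h=h, s_s=s_s, schedule=schedule)
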