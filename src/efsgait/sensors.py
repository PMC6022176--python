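"""Forward models of the two measurement channels.

Electrostatic field sensing (EFS)
---------------------------------
A walking body carries a static charge ``Q_B`` (triboelectric charging
against clothing and the floor).  Together with the feet-to-ground
capacitance ``C_f = 2 eps_s S_s / d_e`` (sole permittivity ``eps_s``,
equivalent sole–ground area ``S_s``, sole thickness ``d_e``) and the
residual body–environment capacitances, this sets a body potential that
varies as the foot height ``h(t)`` and contact area ``s_s(t)`` change::

    U_B(t) = Q_B * (eps_a * s_s(t) + h(t) * C_f) / (C_f * eps_a * s_s(t))
           = Q_B * (1 / C_f + h(t) / (eps_a * s_s(t)))

A nearby sensing electrode couples to the body through a capacitance
``C`` and carries the displacement current ``I = C * dU_B/dt``, which is
proportional to ``(1/S_s) dh/dt - (h/S_s^2) dS_s/dt``: the current
spikes positive as the foot lifts off and negative as it lands.  The
electrode's own potential is neglected — the electrode sits at virtual
ground behind the sampling resistor, so its potential is tiny compared
with ``U_B``.

Analog front end
----------------
The pA-scale electrode current is converted to a voltage across a
10 GΩ sampling resistor (10 mV/pA), low-pass filtered at 20 Hz to
reject mains interference and high-frequency fields (foot motion lives
at 1–2 Hz), and digitised at 1 kHz.  The filter is realised as a
zero-phase (forward–backward) Butterworth so filtering never shifts
event times.  Simulation runs on a finer internal grid (default 4 kHz)
to keep the numerical derivative clean, then decimates.

Foot-pressure reference channel
-------------------------------
Force-sensitive resistors under heel and toe, in a divider driven from
a 5 V battery, give a 0–2.5 V output: near zero when airborne, a
plateau when loaded, with linear loading/unloading ramps plus slow
baseline drift and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ConfigurationError
from .kinematics import EventSchedule, FootTrajectory

__all__ = [
    "BodyElectrostaticConfig",
    "FrontEndConfig",
    "SignalTrace",
    "PRESSURE_RANGE_V",
    "body_potential",
    "induced_current",
    "front_end",
    "simulate_pressure",
    "trim_trace",
]

#: FSR divider output swings between these voltages.
PRESSURE_RANGE_V = (0.0, 2.5)

_EPS0 = 8.854e-12  # vacuum permittivity, F/m


@dataclass(frozen=True)
class BodyElectrostaticConfig:
    """Electrostatic constants of the body–environment capacitance model.

    ``c_f`` (total feet-to-ground capacitance when standing) defaults to
    ``2 * eps_s * s_ref / d_e``.  ``c_r_total`` is the summed residual
    body–environment capacitance; it completes the total body
    capacitance ``c_h = c_f + c_r_total`` but does not enter the
    potential waveform.  ``c_couple`` is the body-to-electrode coupling
    capacitance; at a few metres' sensing distance it is a fraction of
    a femtofarad, which keeps the induced current at pA scale.  The
    absolute amplitudes are uncalibrated — only the timing structure of
    the waveform is meaningful — and every constant is configurable.
    """

    q_b: float = 1e-8            # body charge, C
    eps_a: float = _EPS0         # air permittivity, F/m
    eps_s: float = 2.5 * _EPS0   # sole dielectric permittivity, F/m
    d_e: float = 0.01            # sole thickness, m
    s_ref: float = 0.025         # reference sole area used to derive c_f, m^2
    c_f: float | None = None     # feet-ground capacitance, F (derived if None)
    c_r_total: float = 1e-10     # residual body-environment capacitance, F
    c_couple: float = 1e-16      # body-electrode coupling capacitance, F

    def __post_init__(self):
        if self.c_f is None:
            object.__setattr__(self, "c_f", 2.0 * self.eps_s * self.s_ref / self.d_e)
        if not np.isfinite([self.q_b, self.c_f, self.c_r_total, self.c_couple]).all():
            raise ConfigurationError("all charges and capacitances must be finite")
        if self.c_f <= 0 or self.c_couple <= 0:
            raise ConfigurationError("c_f and c_couple must be positive")

    @property
    def c_h(self) -> float:
        """Total body capacitance: feet plus residual couplings."""
        return self.c_f + self.c_r_total


@dataclass(frozen=True)
class FrontEndConfig:
    """I–V conversion, anti-mains filtering and sampling of the EFS channel."""

    r_s: float = 1e10          # sampling resistor, ohm (10 GOhm -> 10 mV/pA)
    cutoff: float = 20.0       # low-pass corner, Hz
    filter_order: int = 4
    fs: float = 1000.0         # output (ADC) sample rate, Hz
    noise_sd: float = 20.0     # input-referred white current noise, pA
    mains_freq: float = 50.0   # grid frequency, Hz
    mains_amp: float = 50.0    # mains-interference current amplitude, pA

    def __post_init__(self):
        if self.r_s <= 0:
            raise ConfigurationError("r_s must be positive")
        if not 0.0 < self.cutoff < self.fs / 2.0:
            raise ConfigurationError("cutoff must lie in (0, fs/2)")

    @property
    def gain_mV_per_pA(self) -> float:
        """I–V conversion rate: 10 GΩ gives 10 mV per pA."""
        return self.r_s / 1e9


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled voltage channel."""

    channel: str           # "efs" or "pressure"
    fs: float              # sample rate, Hz
    t0: float              # time of the first sample, s
    samples: np.ndarray    # volts

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.channel not in ("efs", "pressure"):
            raise ValueError("channel must be 'efs' or 'pressure'")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if samples.size and not np.isfinite(samples).all():
            raise ValueError("samples must be finite")
        if self.channel == "pressure" and samples.size:
            lo, hi = PRESSURE_RANGE_V
            if samples.min() < lo - 1e-9 or samples.max() > hi + 1e-9:
                raise ValueError(f"pressure samples must lie within [{lo}, {hi}] V")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.fs if self.samples.size else 0.0


def body_potential(traj: FootTrajectory, cfg: BodyElectrostaticConfig) -> np.ndarray:
    """Body potential ``U_B(t)`` (volts) on the trajectory's grid.

    ``U_B = q_b * (1/c_f + h/(eps_a * s_s))``: a constant baseline from
    the feet-to-ground capacitance, plus a term that grows as the foot
    rises and as the contact area shrinks.
    """
    if np.any(traj.s_s <= 0):
        raise ValueError("equivalent area s_s must be strictly positive everywhere")
    return cfg.q_b * (1.0 / cfg.c_f + traj.h / (cfg.eps_a * traj.s_s))


def induced_current(u_b: np.ndarray, cfg: BodyElectrostaticConfig, fs: float) -> np.ndarray:
    """Displacement current ``I = c_couple * dU_B/dt`` (amps).

    The derivative is taken by central differences on the uniform grid
    (one-sided at the ends).
    """
    u_b = np.asarray(u_b, dtype=float)
    if u_b.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return cfg.c_couple * np.gradient(u_b, 1.0 / fs)


def front_end(
    i: np.ndarray,
    cfg: FrontEndConfig,
    seed: int,
    fs_in: float = 4000.0,
    t0: float = 0.0,
) -> SignalTrace:
    """Pass an electrode current through the analog front end.

    Adds white current noise (``noise_sd`` pA) and a mains sinusoid
    (``mains_amp`` pA at ``mains_freq``), converts to volts across
    ``r_s``, applies the zero-phase Butterworth low-pass, and decimates
    from the simulation grid ``fs_in`` to the ADC rate ``cfg.fs``.
    Identical seeds give identical traces.
    """
    i = np.asarray(i, dtype=float)
    if i.size < 2:
        raise ValueError("need at least 2 samples")
    if fs_in < cfg.fs:
        raise ConfigurationError("simulation grid must be at least as fine as the ADC rate")
    step = fs_in / cfg.fs
    if abs(step - round(step)) > 1e-9:
        raise ConfigurationError("fs_in must be an integer multiple of the ADC rate")
    if cfg.cutoff >= cfg.fs / 2.0:
        raise ConfigurationError("cutoff must be below the ADC Nyquist frequency")

    rng = np.random.default_rng(seed)
    t = t0 + np.arange(i.size) / fs_in
    i_noisy = i.copy()
    if cfg.noise_sd > 0:
        i_noisy = i_noisy + cfg.noise_sd * 1e-12 * rng.standard_normal(i.size)
    if cfg.mains_amp > 0:
        i_noisy = i_noisy + cfg.mains_amp * 1e-12 * np.sin(2.0 * np.pi * cfg.mains_freq * t)
    v = i_noisy * cfg.r_s
    sos = butter(cfg.filter_order, cfg.cutoff, btype="low", fs=fs_in, output="sos")
    v = sosfiltfilt(sos, v)
    return SignalTrace(channel="efs", fs=cfg.fs, t0=t0, samples=v[:: int(round(step))])


def simulate_pressure(
    schedule: EventSchedule,
    v_full: float = 2.5,
    ramp_s: float = 0.08,
    drift_amp: float = 0.1,
    noise_sd: float = 0.02,
    fs: float = 1000.0,
    seed: int = 0,
    drift_period_s: float = 20.0,
    pad_s: float = 0.5,
    lead_s: float = 0.5,
) -> SignalTrace:
    """Simulate the FSR insole voltage for one foot.

    Each stance is a trapezoid: a linear rise from the baseline to the
    plateau over ``ramp_s`` starting at IC, and a linear fall ending at
    SE.  The baseline is a slow sinusoid in ``[0, drift_amp]`` (sensor
    drift under no load, period ``drift_period_s`` much longer than a
    cycle); the plateau amplitude is ``v_full - drift_amp`` above the
    baseline so that the output never exceeds ``v_full``.  Gaussian
    noise is added and the result clipped to the 0–2.5 V output range.
    """
    lo, hi = PRESSURE_RANGE_V
    if not lo < v_full <= hi:
        raise ValueError(f"v_full must lie in ({lo}, {hi}]")
    stances = schedule.stance_durations
    if stances.size and ramp_s >= stances.min() / 2.0:
        raise ValueError("ramp_s must be shorter than half the shortest stance")
    if not 0.0 <= drift_amp < v_full:
        raise ValueError("drift_amp must lie in [0, v_full)")

    if lead_s < 0 or pad_s < 0:
        raise ValueError("lead_s and pad_s must be non-negative")
    rng = np.random.default_rng(seed)
    t0 = float(schedule.ic_times[0]) - lead_s
    t_end = float(schedule.ic_times[-1]) + pad_s
    n = int(round((t_end - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs

    amplitude = v_full - drift_amp
    trap = np.zeros(n)
    bounds = list(zip(schedule.ic_times[:-1], schedule.se_times))
    bounds.append((schedule.ic_times[-1], None))  # final stance: no unloading
    for ic, se in bounds:
        rise = np.clip((t - ic) / ramp_s, 0.0, 1.0)
        fall = 1.0 if se is None else np.clip((se - t) / ramp_s, 0.0, 1.0)
        seg = amplitude * np.minimum(rise, fall)
        trap = np.maximum(trap, seg)

    baseline = 0.0
    if drift_amp > 0:
        baseline = drift_amp * 0.5 * (1.0 + np.sin(2.0 * np.pi * t / drift_period_s))
    v = trap + baseline
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(n)
    v = np.clip(v, lo, hi)
    return SignalTrace(channel="pressure", fs=fs, t0=t0, samples=v)


def trim_trace(trace: SignalTrace, head_s: float, tail_s: float) -> SignalTrace:
    """Drop ``head_s`` seconds at the start and ``tail_s`` at the end.

    Walkers need an adjustment period before settling into a steady
    rhythm, so the edges of a recording are discarded before analysis.
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim durations must be non-negative")
    n = len(trace)
    i0 = int(round(head_s * trace.fs))
    i1 = n - int(round(tail_s * trace.fs))
    if i1 - i0 < 2:
        raise ValueError("trimming would leave fewer than 2 samples")
    return SignalTrace(
        channel=trace.channel,
        fs=trace.fs,
        t0=trace.t0 + i0 / trace.fs,
        samples=trace.samples[i0:i1],
    )
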