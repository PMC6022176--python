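"""End-to-end simulation → detection → parameters → validation pipeline.

One run simulates both channels from a single ground-truth schedule,
trims the unsteady head and tail of the recording, detects events on
both channels, computes per-cycle parameter tables, and measures the
agreement of the electrostatic channel against ground truth and
against the pressure reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as efio
from .agreement import (
    agreement_report,
    cycle_accuracy,
    error_stats,
    match_events,
    pair_gait_cycles,
)
from .detection import DetectorConfig, detect_efs_events, detect_pressure_events
from .events import GaitEvents, IC, SE
from .parameters import compute_cycle_params
from .kinematics import (
    PACE_PROFILES,
    EventSchedule,
    FootTrajectory,
    contralateral_schedule,
    sample_event_schedule,
    synthesize_trajectory,
)
from .sensors import (
    BodyElectrostaticConfig,
    FrontEndConfig,
    SignalTrace,
    body_potential,
    front_end,
    induced_current,
    simulate_pressure,
    trim_trace,
)

__all__ = [
    "TrajectoryConfig",
    "PressureConfig",
    "PipelineConfig",
    "SimulatedSession",
    "simulate_session",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("efsgait")

#: Internal simulation grid rate (Hz); an integer multiple of the ADC rate.
SIM_FS = 4000.0


@dataclass(frozen=True)
class TrajectoryConfig:
    """Kinematic constants of the simulated foot trajectory."""

    h_max: float = 0.15
    s_max: float = 0.025
    s_min: float = 0.002
    roll_fraction: float = 0.15
    lift_s: float = 0.05


@dataclass(frozen=True)
class PressureConfig:
    """Shape and noise of the simulated FSR insole channel."""

    v_full: float = 2.5
    ramp_s: float = 0.08
    drift_amp: float = 0.1
    noise_sd: float = 0.02
    drift_period_s: float = 20.0
    fs: float = 1000.0


@dataclass(frozen=True)
class PipelineConfig:
    pace: str = "normal"
    n_cycles: int = 100
    seed: int = 0
    trim_head: float = 2.0
    trim_tail: float = 2.0
    both_feet: bool = False
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    body: BodyElectrostaticConfig = field(default_factory=BodyElectrostaticConfig)
    front_end: FrontEndConfig = field(default_factory=FrontEndConfig)
    pressure: PressureConfig = field(default_factory=PressureConfig)
    output_dir: Path = Path("efsgait_out")

    def __post_init__(self):
        if self.pace not in PACE_PROFILES:
            raise ValueError(f"unknown pace {self.pace!r}; choose from {sorted(PACE_PROFILES)}")
        object.__setattr__(self, "output_dir", Path(self.output_dir))


@dataclass(frozen=True)
class SimulatedSession:
    """Everything one simulated walking session produced."""

    schedule: EventSchedule
    trajectory: FootTrajectory
    efs: SignalTrace
    pressure: SignalTrace


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n)
    return [int(s % (2**31)) for s in state]


def simulate_session(
    pace: str = "normal",
    n_cycles: int = 100,
    seed: int = 0,
    trajectory: TrajectoryConfig | None = None,
    body: BodyElectrostaticConfig | None = None,
    fe: FrontEndConfig | None = None,
    pressure: PressureConfig | None = None,
    both_feet: bool = False,
) -> SimulatedSession:
    """Simulate one walking session: schedule → both sensor channels.

    With ``both_feet`` the opposite foot's swing pulses are superposed
    onto the electrostatic current (the pressure insole stays on the
    right foot only); this enriches the waveform but breaks
    single-foot event detection, so it is off by default.
    """
    trajectory = trajectory or TrajectoryConfig()
    body = body or BodyElectrostaticConfig()
    fe = fe or FrontEndConfig()
    pressure = pressure or PressureConfig()
    s_sched, s_fe, s_press = _child_seeds(seed, 3)

    schedule = sample_event_schedule(PACE_PROFILES[pace], n_cycles, s_sched)
    traj = synthesize_trajectory(schedule, fs=SIM_FS, **dataclasses.asdict(trajectory))
    i = induced_current(body_potential(traj, body), body, SIM_FS)
    if both_feet:
        other = contralateral_schedule(schedule)
        traj_l = synthesize_trajectory(other, fs=SIM_FS, lead_s=0.0, **dataclasses.asdict(trajectory))
        i_l = induced_current(body_potential(traj_l, body), body, SIM_FS)
        # superpose the opposite foot's current where the grids overlap
        i = i.copy()
        off = int(round((traj_l.t[0] - traj.t[0]) * SIM_FS))
        lo = max(0, off)
        seg = i_l[max(0, -off):]
        n_overlap = min(i.size - lo, seg.size)
        if n_overlap > 0:
            i[lo:lo + n_overlap] += seg[:n_overlap]
    efs = front_end(i, fe, seed=s_fe, fs_in=SIM_FS, t0=float(traj.t[0]))
    press = simulate_pressure(
        schedule,
        v_full=pressure.v_full,
        ramp_s=pressure.ramp_s,
        drift_amp=pressure.drift_amp,
        noise_sd=pressure.noise_sd,
        fs=pressure.fs,
        seed=s_press,
        drift_period_s=pressure.drift_period_s,
    )
    return SimulatedSession(schedule, traj, efs, press)


def _config_hash(cfg: PipelineConfig) -> str:
    d = dataclasses.asdict(cfg)
    d.pop("output_dir", None)  # where results land does not change what they are
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline and write all report files to ``cfg.output_dir``.

    Writes the two signal CSVs, the truth and detected event CSVs, the
    per-cycle parameter CSVs and a validation report (JSON plus a flat
    key=value text file).  Returns the report as a dict.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: pace=%s n_cycles=%d seed=%d config=%s",
             cfg.pace, cfg.n_cycles, cfg.seed, _config_hash(cfg))

    session = simulate_session(
        pace=cfg.pace, n_cycles=cfg.n_cycles, seed=cfg.seed,
        trajectory=cfg.trajectory, body=cfg.body, fe=cfg.front_end,
        pressure=cfg.pressure, both_feet=cfg.both_feet,
    )
    efs_trace = trim_trace(session.efs, cfg.trim_head, cfg.trim_tail)
    press_trace = trim_trace(session.pressure, cfg.trim_head, cfg.trim_tail)
    t_lo = max(efs_trace.t0, press_trace.t0)
    t_hi = min(efs_trace.times[-1], press_trace.times[-1])
    truth = session.schedule.to_events().within(t_lo, t_hi)
    log.info("trimmed to [%.3f, %.3f] s; %d truth events retained", t_lo, t_hi, len(truth))

    efs_events = detect_efs_events(efs_trace, cfg.detector)
    press_events = detect_pressure_events(press_trace, cfg.detector)
    log.info("detected %d efs events, %d pressure events", len(efs_events), len(press_events))

    efs_params = compute_cycle_params(efs_events)
    press_params = compute_cycle_params(press_events)

    ic_match = match_events(efs_events, truth, IC)
    se_match = match_events(efs_events, truth, SE)
    ic_stats = error_stats(ic_match.deltas_ms, n_unmatched=ic_match.n_unmatched_est + ic_match.n_unmatched_ref)
    se_stats = error_stats(se_match.deltas_ms, n_unmatched=se_match.n_unmatched_est + se_match.n_unmatched_ref)

    tg_efs, tg_press = pair_gait_cycles(efs_events, press_events)
    acc = cycle_accuracy(tg_efs, tg_press)
    agr = agreement_report(tg_efs, tg_press)

    efio.write_signal_csv(efs_trace, out / "efs_signal.csv")
    efio.write_signal_csv(press_trace, out / "pressure_signal.csv")
    efio.write_events_csv(truth, out / "truth_events.csv")
    efio.write_events_csv(efs_events, out / "efs_events.csv")
    efio.write_events_csv(press_events, out / "pressure_events.csv")
    efio.write_params_csv(efs_params, out / "efs_params.csv")
    efio.write_params_csv(press_params, out / "pressure_params.csv")

    report = {
        "pace": cfg.pace,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n": int(tg_efs.size),
        "n_truth_events": len(truth),
        "n_efs_cycles": int(len(efs_params)),
        "n_pressure_cycles": int(len(press_params)),
        "ic_error": ic_stats.as_dict(),
        "se_error": se_stats.as_dict(),
        "tg_accuracy_pct": acc.accuracy_pct,
        **agr.as_dict(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        for key, val in report.items():
            if not isinstance(val, dict):
                fh.write(f"{key}={val}\n")
        for prefix, st in (("ic_error", ic_stats), ("se_error", se_stats)):
            for key, val in st.as_dict().items():
                if not isinstance(val, list):
                    fh.write(f"{prefix}.{key}={val}\n")
    log.info("pipeline done: n=%d accuracy=%.2f%% r=%.4f icc=%.4f",
             report["n"], report["tg_accuracy_pct"], report["pearson_r"], report["icc"])
    return report


def _update_dataclass(obj, updates: dict):
    valid = {f.name for f in dataclasses.fields(obj)}
    unknown = set(updates) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) for {type(obj).__name__}: {sorted(unknown)}")
    return dataclasses.replace(obj, **updates)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file plus overrides.

    The YAML mirrors the config structure: top-level scalar keys
    (``pace``, ``n_cycles``, ``seed``, ``trim_head``, ``trim_tail``,
    ``both_feet``, ``output_dir``) and nested sections ``detector``,
    ``trajectory``, ``body``, ``front_end``, ``pressure`` whose keys
    mirror the corresponding dataclass fields.  ``overrides`` (e.g.
    command-line flags) take precedence over the file.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **{k: v for k, v in overrides.items() if v is not None}}

    cfg = PipelineConfig()
    nested = {
        "detector": cfg.detector,
        "trajectory": cfg.trajectory,
        "body": cfg.body,
        "front_end": cfg.front_end,
        "pressure": cfg.pressure,
    }
    updates: dict = {}
    for key, val in data.items():
        if key in nested:
            updates[key] = _update_dataclass(nested[key], dict(val))
        else:
            updates[key] = val
    return _update_dataclass(cfg, updates)
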