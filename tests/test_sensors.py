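import numpy as np
import pytest
from hypothesis import given, strategies as st

from efsgait import (
    BodyElectrostaticConfig,
    ConfigurationError,
    EventSchedule,
    FootTrajectory,
    FrontEndConfig,
    PACE_PROFILES,
    SignalTrace,
    body_potential,
    front_end,
    induced_current,
    sample_event_schedule,
    simulate_pressure,
    synthesize_trajectory,
    trim_trace,
)
from efsgait.kinematics import PaceProfile


def const_trajectory(h, s, n=100, fs=1000.0):
    sched = EventSchedule("right", ic_times=[0.0], se_times=[])
    t = np.arange(n) / fs
    return FootTrajectory(t=t, h=np.full(n, h), s_s=np.full(n, s), schedule=sched)


class TestBodyPotential:
    def test_standing_body_sits_at_qb_over_cf(self):
        cfg = BodyElectrostaticConfig()
        u = body_potential(const_trajectory(0.0, 0.02), cfg)
        np.testing.assert_allclose(u, cfg.q_b / cfg.c_f, rtol=1e-12)

    def test_closed_form_with_constant_height(self):
        cfg = BodyElectrostaticConfig()
        h0, s0 = 0.1, 0.01
        u = body_potential(const_trajectory(h0, s0), cfg)
        expected = cfg.q_b * (1.0 / cfg.c_f + h0 / (cfg.eps_a * s0))
        np.testing.assert_allclose(u, expected, rtol=1e-12)

    def test_linear_in_body_charge(self):
        traj = const_trajectory(0.05, 0.01)
        u1 = body_potential(traj, BodyElectrostaticConfig(q_b=1e-8))
        u2 = body_potential(traj, BodyElectrostaticConfig(q_b=2e-8))
        np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-12)

    def test_rejects_nonpositive_area(self):
        traj = const_trajectory(0.05, 0.01)
        bad = FootTrajectory(t=traj.t, h=traj.h, s_s=np.zeros_like(traj.s_s), schedule=traj.schedule)
        with pytest.raises(ValueError):
            body_potential(bad, BodyElectrostaticConfig())


class TestInducedCurrent:
    def test_constant_potential_gives_zero_current(self):
        cfg = BodyElectrostaticConfig()
        i = induced_current(np.full(50, 3.3), cfg, fs=1000.0)
        np.testing.assert_allclose(i, 0.0, atol=1e-30)

    def test_linear_ramp_gives_constant_current(self):
        cfg = BodyElectrostaticConfig()
        fs, a = 1000.0, 2.5
        u = a * np.arange(100) / fs
        i = induced_current(u, cfg, fs)
        np.testing.assert_allclose(i, cfg.c_couple * a, rtol=1e-9)

    def test_current_sign_follows_foot_velocity(self):
        # the current is positive while the foot lifts, negative as it lands
        sched = sample_event_schedule(PACE_PROFILES["normal"], 1, seed=0)
        traj = synthesize_trajectory(sched, fs=4000.0)
        cfg = BodyElectrostaticConfig()
        i = induced_current(body_potential(traj, cfg), cfg, 4000.0)
        se, ic = sched.se_times[0], sched.ic_times[1]
        rising = (traj.t > se + 0.005) & (traj.t < se + 0.045)
        falling = (traj.t > ic - 0.045) & (traj.t < ic - 0.005)
        assert np.all(i[rising] > 0) and np.all(i[falling] < 0)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError):
            induced_current(np.array([1.0]), BodyElectrostaticConfig(), 1000.0)

    def test_current_proportional_to_height_velocity_in_swing(self):
        """With s_s constant over the swing, I = C*q_b/(eps_a*s_min) * dh/dt.

        Checked on a fine grid against the analytic derivative of the
        cosine lift ramps, away from the C2 breakpoints of the profile
        where a central difference cannot converge faster than O(dt).
        """
        fs = 50000.0
        profile = PaceProfile("normal", 1000.0, 0.0, 1000.0, 1000.0,
                              stance_fraction_mean=0.6, stance_fraction_sd=0.0)
        sched = sample_event_schedule(profile, 2, seed=0)
        lift = 0.05
        traj = synthesize_trajectory(sched, fs=fs, lift_s=lift)
        cfg = BodyElectrostaticConfig()
        i = induced_current(body_potential(traj, cfg), cfg, fs)

        h_max, s_min = 0.15, 0.002
        scale = cfg.c_couple * cfg.q_b / (cfg.eps_a * s_min)
        peak = scale * h_max * np.pi / (2 * lift)

        dh = np.zeros_like(traj.t)
        breakpoints = []
        for se, ic in zip(sched.se_times, sched.ic_times[1:]):
            tw = ic - se
            u = traj.t - se
            rise = (u > 0) & (u < lift)
            fall = (u > tw - lift) & (u < tw)
            dh[rise] = h_max * np.pi / (2 * lift) * np.sin(np.pi * u[rise] / lift)
            dh[fall] = -h_max * np.pi / (2 * lift) * np.sin(np.pi * (tw - u[fall]) / lift)
            breakpoints += [se, se + lift, ic - lift, ic]
        keep = np.ones(traj.t.size, dtype=bool)
        keep[:2] = keep[-2:] = False
        for b in breakpoints:
            keep &= np.abs(traj.t - b) > 3.0 / fs
        rel_err = np.abs(i[keep] - scale * dh[keep]) / peak
        assert rel_err.max() < 1e-6


class TestFrontEnd:
    def test_dc_gain_is_10mV_per_pA(self):
        cfg = FrontEndConfig(noise_sd=0.0, mains_amp=0.0)
        i = np.full(4000, 1e-12)  # 1 pA
        trace = front_end(i, cfg, seed=0, fs_in=4000.0)
        np.testing.assert_allclose(trace.samples, 0.010, rtol=1e-9)

    def test_mains_attenuated_at_least_20dB(self):
        cfg = FrontEndConfig(noise_sd=0.0, mains_amp=0.0)
        t = np.arange(40000) / 4000.0
        amp = 100e-12
        out50 = front_end(amp * np.sin(2 * np.pi * 50.0 * t), cfg, 0, fs_in=4000.0).samples
        out2 = front_end(amp * np.sin(2 * np.pi * 2.0 * t), cfg, 0, fs_in=4000.0).samples
        mid = slice(2000, 8000)  # avoid filter edge transients
        ratio = np.std(out50[mid]) / np.std(out2[mid])
        assert 20 * np.log10(1.0 / ratio) >= 20.0

    def test_zero_input_zero_noise_gives_zero_trace(self):
        cfg = FrontEndConfig(noise_sd=0.0, mains_amp=0.0)
        trace = front_end(np.zeros(2000), cfg, seed=0, fs_in=4000.0)
        np.testing.assert_allclose(trace.samples, 0.0, atol=1e-15)

    def test_linearity_without_noise(self):
        cfg = FrontEndConfig(noise_sd=0.0, mains_amp=0.0)
        rng = np.random.default_rng(0)
        i = 1e-12 * rng.standard_normal(4000)
        a = front_end(i, cfg, 0, fs_in=4000.0).samples
        b = front_end(3.0 * i, cfg, 0, fs_in=4000.0).samples
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-9)

    def test_deterministic_under_seed(self):
        cfg = FrontEndConfig()
        i = np.zeros(4000)
        a = front_end(i, cfg, seed=42, fs_in=4000.0).samples
        b = front_end(i, cfg, seed=42, fs_in=4000.0).samples
        assert np.array_equal(a, b)

    def test_rejects_cutoff_at_or_above_adc_nyquist(self):
        with pytest.raises(ConfigurationError):
            FrontEndConfig(cutoff=600.0, fs=1000.0)


class TestSimulatePressure:
    def stance_schedule(self):
        return EventSchedule("right", ic_times=[1.0, 2.5], se_times=[1.7])

    def test_noiseless_trapezoid_levels(self):
        trace = simulate_pressure(self.stance_schedule(), v_full=2.5, ramp_s=0.1,
                                  drift_amp=0.0, noise_sd=0.0, seed=0)
        t, v = trace.times, trace.samples
        assert np.all(v[t < 1.0 - 1e-9] == 0.0)
        np.testing.assert_allclose(v[(t >= 1.1) & (t <= 1.6)], 2.5, atol=1e-12)
        assert np.all(v[(t > 1.7 + 1e-9) & (t < 2.5 - 1e-9)] == 0.0)

    def test_ramp_crossing_matches_linear_algebra(self):
        trace = simulate_pressure(self.stance_schedule(), v_full=2.5, ramp_s=0.1,
                                  drift_amp=0.0, noise_sd=0.0, seed=0)
        # the rising ramp crosses 1 V at IC + ramp_s * (1 V / v_full)
        t_cross = 1.0 + 0.1 * (1.0 / 2.5)
        i = np.argmax(trace.samples >= 1.0)
        assert abs(trace.times[i] - t_cross) <= 1.0 / trace.fs + 1e-12

    @given(noise_sd=st.floats(0.0, 5.0))
    def test_output_always_within_adc_range(self, noise_sd):
        trace = simulate_pressure(self.stance_schedule(), noise_sd=noise_sd, seed=3)
        assert trace.samples.min() >= 0.0 and trace.samples.max() <= 2.5

    def test_rejects_ramp_longer_than_stance(self):
        with pytest.raises(ValueError):
            simulate_pressure(self.stance_schedule(), ramp_s=0.5)

    def test_deterministic_under_seed(self):
        a = simulate_pressure(self.stance_schedule(), seed=9).samples
        b = simulate_pressure(self.stance_schedule(), seed=9).samples
        assert np.array_equal(a, b)


class TestTrimTrace:
    def test_trim_removes_requested_spans(self):
        trace = SignalTrace("efs", 100.0, 0.0, np.arange(1000, dtype=float))
        out = trim_trace(trace, 2.0, 3.0)
        assert out.t0 == pytest.approx(2.0)
        assert len(out) == 1000 - 200 - 300
        np.testing.assert_array_equal(out.samples, trace.samples[200:700])

    def test_rejects_overlong_trim(self):
        trace = SignalTrace("efs", 100.0, 0.0, np.zeros(100))
        with pytest.raises(ValueError):
            trim_trace(trace, 0.6, 0.6)
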