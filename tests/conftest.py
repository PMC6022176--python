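import pytest
from hypothesis import HealthCheck, settings

from efsgait import detect_efs_events, detect_pressure_events, simulate_session

settings.register_profile(
    "efsgait",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("efsgait")


@pytest.fixture(scope="session")
def normal_session():
    """One 100-cycle normal-pace simulated session with default noise."""
    return simulate_session(pace="normal", n_cycles=100, seed=1234)


@pytest.fixture(scope="session")
def normal_detections(normal_session):
    """Detected events on both channels plus the ground truth."""
    return {
        "efs": detect_efs_events(normal_session.efs),
        "pressure": detect_pressure_events(normal_session.pressure),
        "truth": normal_session.schedule.to_events(),
    }
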