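import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pupilcf import build_schedule
from pupilcf.synthetic import SimulationParams, simulate_recording

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def moderate_schedule():
    return build_schedule("moderate")


@pytest.fixture(scope="session")
def simple_schedule():
    return build_schedule("simple")


@pytest.fixture(scope="session")
def responder_recording(moderate_schedule):
    """A clearly responding synthetic subject (0.5 mm dilation, low noise)."""
    rec, truth = simulate_recording(
        moderate_schedule,
        SimulationParams(dilation_amplitude_mm=0.5, noise_sd_mm=0.05, seed=42),
        subject_id="responder",
    )
    assert truth
    return rec


@pytest.fixture(scope="session")
def null_recording(moderate_schedule):
    """A non-responding synthetic subject (no dilation, no drift)."""
    rec, truth = simulate_recording(
        moderate_schedule,
        SimulationParams(
            dilation_amplitude_mm=0.0, drift_amplitude_mm=0.0, noise_sd_mm=0.05, seed=43
        ),
        subject_id="null",
    )
    assert not truth
    return rec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
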