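import pytest
from hypothesis import HealthCheck, settings

import rasim

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def defaults() -> rasim.ParameterBundle:
    return rasim.default_parameters()


@pytest.fixture()
def repro() -> rasim.ParameterBundle:
    return rasim.reproduction_preset()


@pytest.fixture(scope="session")
def calibrated() -> rasim.ParameterBundle:
    return rasim.calibrated_preset()


@pytest.fixture(scope="session")
def calibrated_run(calibrated) -> rasim.Trajectory:
    """A 60-day calibrated grow-out with hourly budgets, shared across
    validation/synthetic tests."""
    return rasim.run_simulation(calibrated, days=60)
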