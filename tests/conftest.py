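"""Shared fixtures: one simulated experiment reused across the suite."""

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from phenosink import SimulationConfig, generate_design, noise_free, simulate_experiment
from phenosink.qc import MeasurementSchedule, run_qc


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def noise_free_config():
    return noise_free(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def design():
    return generate_design(0)


@pytest.fixture(scope="session")
def tables(design, default_config):
    return simulate_experiment(design, default_config)


@pytest.fixture(scope="session")
def noise_free_tables(design, noise_free_config):
    return simulate_experiment(design, noise_free_config)


@pytest.fixture(scope="session")
def schedule(default_config):
    return MeasurementSchedule.from_config(default_config)


@pytest.fixture(scope="session")
def cleaned(tables, schedule):
    return run_qc(tables["photosynthesis"], schedule)
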