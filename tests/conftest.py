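import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erpselect import SimulationConfig, epoch, simulate_session

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# a 12-channel slice of the actiCAP montage with centro-parietal coverage
SMALL_CHANNELS = (
    "Fp1", "Fz", "F3", "FC1", "C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4",
)
SMALL_INFORMATIVE = ("Cz", "CP1", "CP2", "P3", "Pz")


def small_config(seed=0, **overrides):
    """Fast 12-channel oddball simulation used throughout the unit tests."""
    params = dict(
        n_runs=2,
        n_standards_per_run=120,
        n_targets_per_run=30,
        channel_names=SMALL_CHANNELS,
        informative_sensors=SMALL_INFORMATIVE,
        erp_amplitude=2.0,
        noise_sd=1.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_session():
    """Two runs of the default small benchmark (session 0, seed 0)."""
    return simulate_session(small_config(), 0, 0)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    return [epoch(r, (0.0, 1000.0)) for r in small_session]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
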