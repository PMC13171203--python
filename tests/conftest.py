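import numpy as np
import pytest

from chunklock.config import AnalysisConfig, SimConfig
from chunklock.forward import build_forward
from chunklock.geometry import Sphere, toy_sensor_layout, toy_source_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sim():
    """Small, fast study configuration at the analysis rate."""
    return SimConfig(
        n_participants=3,
        n_channels=10,
        n_trials_per_level=6,
        sfreq_raw=100.0,
        epoch_window=(-1.3, 1.3),
        pad=0.45,
        seed=7,
    )


@pytest.fixture
def ana_small():
    return AnalysisConfig(n_perm=200, cov_window=(-0.85, 1.2))


@pytest.fixture(scope="session")
def toy_forward():
    grid = toy_source_grid()
    sensors = toy_sensor_layout(24)
    return build_forward(grid, sensors, Sphere())
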