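import numpy as np
import pytest

from altsense import (
    NoiseModel,
    SimulationConfig,
    generate_dilution_series,
    simulate_reaction,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def states_450():
    """Default-condition reaction trajectory at 450 U/L."""
    return simulate_reaction(450.0)


@pytest.fixture(scope="session")
def optical_series(default_config):
    return generate_dilution_series(modality="optical", config=default_config)


@pytest.fixture(scope="session")
def electrical_series(default_config):
    return generate_dilution_series(modality="electrical", config=default_config)


@pytest.fixture()
def noiseless():
    return NoiseModel.noiseless()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
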