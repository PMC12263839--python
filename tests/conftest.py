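import numpy as np
import pytest

from tumordnds.simulate import SimulationConfig, generate_reference


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1234)


@pytest.fixture(scope="session")
def site_table(sim_config):
    """Site table of a small seeded synthetic exome, shared across tests."""
    _, table = generate_reference(sim_config)
    return table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
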