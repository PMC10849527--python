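import numpy as np
import pytest

from progniche.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_dataset():
    """One fully simulated 9-taxon study system shared across tests."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
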