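import warnings

import numpy as np
import pytest

from epicanal.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced panel used by unit tests: 6 accessions, 400 genes."""
    return SimConfig(n_accessions=6, n_genes=400, n_regions=200, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(small_config, n_progeny=48)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
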