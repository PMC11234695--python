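import numpy as np
import pandas as pd
import pytest

from coregqtl.simulate import SimConfig, simulate_genotypes, simulate_molecular_cascade


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_animals=200, n_variants=400, n_peaks=30, n_genes=60,
                     seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_cascade(small_cfg, small_sim):
    g, truth = small_sim
    return simulate_molecular_cascade(g, truth, small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
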