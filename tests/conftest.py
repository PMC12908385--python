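import numpy as np
import pandas as pd
import pytest

from rngwas import Pedigree, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small population exercised by many integration tests."""
    cfg = SimulationConfig(
        n_founders=40, n_generations=2, n_markers=300, n_chromosomes=3,
        n_cg=10, n_qtl=5, seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def founder_pedigree():
    """Eight unrelated animals (founders only)."""
    n = 8
    return Pedigree(np.arange(1, n + 1), np.full(n, -1), np.full(n, -1))


@pytest.fixture
def trio_pedigree():
    return Pedigree.from_frame(
        pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})
    )
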