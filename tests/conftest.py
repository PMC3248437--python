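import numpy as np
import pytest

import c3mi as m


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_ensemble():
    """A 30-gene ensemble with a known network, reused by slower tests."""
    cfg = m.SimulationConfig(
        n_genes=30, edge_density=0.05, n_samples=200, n_datasets=6, seed=300
    )
    network, datasets = m.generate_ensemble(cfg)
    return cfg, network, datasets
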