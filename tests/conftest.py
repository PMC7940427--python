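import numpy as np
import pytest

from scstage.synthdata import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small 4-sample experiment with composition trends and programs."""
    cfg = SimConfig(n_samples=4, cells_per_sample=300, n_genes=250, seed=101)
    adata, truth = simulate_experiment(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def flat_experiment():
    """Two equal, trend-free cell types; useful for null-structure tests."""
    cfg = SimConfig(n_samples=3, cells_per_sample=400, n_genes=200,
                    n_celltypes=2, celltype_names=("A", "B"),
                    base_proportions=(0.5, 0.5),
                    composition_trends=(0.0, 0.0), program_genes=0,
                    seed=202)
    adata, truth = simulate_experiment(cfg)
    return cfg, adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
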