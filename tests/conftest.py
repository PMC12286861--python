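import numpy as np
import pandas as pd
import pytest

from mimetect import scoring, synthetic


@pytest.fixture(scope="session")
def small_sim():
    """A small planted single-cell dataset shared across tests."""
    cfg = synthetic.SimConfig(n_cells=800, n_genes=800, seed=11)
    adata, truth = synthetic.simulate_single_cell(cfg)
    sigs = synthetic.population_signatures(synthetic.default_populations(800))
    return adata, truth, sigs


@pytest.fixture(scope="session")
def small_scores(small_sim):
    adata, truth, sigs = small_sim
    ranks = scoring.rank_genes_per_cell(adata, tie_seed=11)
    return scoring.score_signatures(ranks, sigs), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def de_table():
    """Toy differential-expression table with hand-checkable filter outcomes."""
    return pd.DataFrame({
        "gene": [f"G{i}" for i in range(1, 7)],
        "adj_p": [0.005, 0.005, 0.02, 0.001, 0.0, 0.009],
        "log2fc": [1.2, 0.9, 2.0, 1.5, 3.0, 1.01],
        "pct_expressed": [0.2, 0.2, 0.5, 0.05, 0.10, 0.11],
        "population": ["muscle"] * 6,
    })
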