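import numpy as np
import pytest

from renge import core, synthetic
from renge.dataio import CONTROL, ExpressionDataset
from renge.perturbation import build_knockdown_table


@pytest.fixture(scope="session")
def small_config():
    """A 6-gene screen small enough for repeated fitting in unit tests."""
    return synthetic.SyntheticConfig(
        G=6, n_ko=4, T=3, cells_per_stratum=8, noise_sd=0.05,
        edge_density=0.3, seed=3,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    A, truth = synthetic.generate_network(small_config)
    ds, kd, model = synthetic.simulate_dataset(A, small_config)
    return {"A": A, "truth": truth, "dataset": ds, "kd": kd, "model": model,
            "config": small_config}


@pytest.fixture(scope="session")
def standard_screen():
    """The standard 20-gene benchmark configuration."""
    cfg = synthetic.SyntheticConfig(seed=1)
    A, truth = synthetic.generate_network(cfg)
    ds, kd, model = synthetic.simulate_dataset(A, cfg)
    return {"A": A, "truth": truth, "dataset": ds, "kd": kd, "model": model,
            "config": cfg}


def make_dataset(expr, gene_names, time_index, ko_gene, perturb_prob=None):
    expr = np.asarray(expr, dtype=float)
    n = expr.shape[0]
    return ExpressionDataset(
        expr=expr,
        gene_names=gene_names,
        cell_ids=[f"cell{i}" for i in range(n)],
        time_index=np.asarray(time_index),
        ko_gene=np.asarray(ko_gene, dtype=object),
        perturb_prob=perturb_prob,
    )


@pytest.fixture
def two_gene_chain():
    """Hand-checkable 2-gene system: gene1 -> gene2 with coefficient 0.5,
    KO of gene1 in half the cells, exact (noise-free) expression."""
    A = np.array([[0.0, 0.0], [0.5, 0.0]])
    b = np.array([[2.0, 3.0]])
    model = core.GRNModel(
        A=A, b=b, alpha={"g1": 0.0}, beta_w=0.0, gamma_w=0.0, K=1,
        lambda1=0.0, lambda2=0.0, gene_names=["g1", "g2"], fixed_weight=1.0,
    )
    return model
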