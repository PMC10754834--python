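"""Bootstrap significance for network coefficients.

Cells are resampled with replacement within every (KO gene, time) stratum —
stratum sizes are preserved exactly — and the model is refitted on each
replicate. Each off-diagonal coefficient is then tested against a normal
null N(0, Var) built from the replicate spread: z = A_hat / sd,
p = 2 (1 - Phi(|z|)), followed by Benjamini-Hochberg correction across all
off-diagonal tests. The diagonal (self-regulation) is never tested or
exported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from . import core
from .dataio import ExpressionDataset, sort_edges
from .perturbation import KnockdownTable

__all__ = [
    "BootstrapEnsemble",
    "bootstrap_resample",
    "run_bootstrap",
    "edge_pvalues",
]


@dataclass
class BootstrapEnsemble:
    """Replicate coefficient matrices from stratified resample-and-refit."""

    A_samples: np.ndarray  # (N, G, G)
    gene_names: list[str]
    seed: int
    n_nonconverged: int = 0

    @property
    def N(self) -> int:
        return self.A_samples.shape[0]


def bootstrap_resample(
    dataset: ExpressionDataset,
    kd: KnockdownTable | None = None,
    seed: int = 0,
):
    """Resample cells with replacement within each (KO gene, time) stratum.

    Stratum sizes are preserved exactly; returns (dataset, kd) with the same
    structure (kd is None if not supplied). Cell ids get a replicate suffix
    so the no-duplicates invariant holds.
    """
    rng = np.random.default_rng(seed)
    picked = []
    for (_, _), idx in dataset.strata():
        picked.append(rng.choice(idx, size=len(idx), replace=True))
    order = np.concatenate(picked)
    ds = dataset.subset(order, suffix="__b")
    kd_out = kd.subset(order) if kd is not None else None
    return ds, kd_out


def run_bootstrap(
    dataset: ExpressionDataset,
    kd: KnockdownTable,
    K: int,
    lambda1: float,
    lambda2: float,
    N: int = 30,
    seed: int = 0,
    freeze_weights_from: "core.GRNModel | None" = None,
    **fit_kwargs,
) -> BootstrapEnsemble:
    """N resample-and-refit cycles with replicate seeds derived from ``seed``.

    Hyperparameters are supplied once (selected on the full data) and reused
    for every replicate. By default all parameters are re-estimated per
    replicate; passing ``freeze_weights_from`` pins the time-order weights
    to an already-fitted model's values instead.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    G = dataset.n_genes
    A_samples = np.zeros((N, G, G))
    n_bad = 0
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(N)]
    for l, s in enumerate(child_seeds):
        ds_l, kd_l = bootstrap_resample(dataset, kd, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if freeze_weights_from is not None:
                model = core.fit(
                    ds_l, kd_l, K, lambda1, lambda2, seed=s,
                    fixed_weight=None, fit_weights=False,
                    init=freeze_weights_from, **fit_kwargs,
                )
            else:
                model = core.fit(ds_l, kd_l, K, lambda1, lambda2, seed=s, **fit_kwargs)
        A_samples[l] = model.A
        n_bad += int(not model.converged)
    if n_bad:
        warnings.warn(
            f"{n_bad}/{N} bootstrap replicates did not report convergence",
            UserWarning, stacklevel=2,
        )
    return BootstrapEnsemble(
        A_samples=A_samples, gene_names=dataset.gene_names, seed=seed,
        n_nonconverged=n_bad,
    )


def edge_pvalues(ensemble: BootstrapEnsemble, A_hat: np.ndarray) -> pd.DataFrame:
    """Two-sided normal p-values and BH q-values for every off-diagonal edge.

    z = A_hat / sd(replicates) with sd using denominator N-1; degenerate
    sd = 0 gives p = 0 (with a warning) for a nonzero coefficient and p = 1
    for a zero one.
    """
    if ensemble.N < 2:
        raise ValueError("need >= 2 bootstrap replicates")
    A_hat = np.asarray(A_hat, dtype=float)
    G = A_hat.shape[0]
    sd = ensemble.A_samples.std(axis=0, ddof=1)
    off = ~np.eye(G, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, A_hat / np.where(sd > 0, sd, 1.0), np.inf)
    p = 2.0 * norm.sf(np.abs(z))
    degenerate = (sd == 0) & off
    if degenerate.any():
        p = np.where(degenerate & (A_hat != 0), 0.0, p)
        p = np.where(degenerate & (A_hat == 0), 1.0, p)
        if (degenerate & (A_hat != 0)).any():
            warnings.warn(
                "zero bootstrap variance at a nonzero coefficient; p set to 0",
                UserWarning, stacklevel=2,
            )
    pvals = p[off]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    tgt, reg = np.nonzero(off)
    genes = ensemble.gene_names
    edges = pd.DataFrame(
        {
            "regulator": [genes[j] for j in reg],
            "target": [genes[i] for i in tgt],
            "coefficient": A_hat[off],
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    return sort_edges(edges)
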