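"""Knockdown vectors, perturbation probabilities, and KO-indicator regression.

The knockdown vector X_c of a cell encodes the expression *decrease* of its
KO target: a single nonpositive entry at the KO gene equal to
-p_c * (mean control expression of that gene at the cell's time point),
where p_c is the probability that the detected gRNA actually perturbed the
transcriptome. Control cells have all-zero rows.

The module also provides the linear-regression artifacts used for screening
and gene selection: a per-gene least-squares fit of expression on KO
indicators (beta matrix), the mean-total-|beta| screening score, and the
per-gene expression-variation ranking used to pick non-KO genes into a
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .dataio import CONTROL, ExpressionDataset

__all__ = [
    "KnockdownTable",
    "PerturbRegression",
    "control_baseline",
    "build_knockdown_table",
    "estimate_perturb_prob",
    "fit_perturb_regression",
    "mimosca_score",
    "expression_variation_scores",
]


@dataclass
class KnockdownTable:
    """Per-cell knockdown vectors X (cells x genes) and perturbation probabilities."""

    X: np.ndarray
    perturb_prob: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.perturb_prob = np.asarray(self.perturb_prob, dtype=float)

    def subset(self, indices: np.ndarray) -> "KnockdownTable":
        indices = np.asarray(indices, dtype=int)
        return KnockdownTable(self.X[indices], self.perturb_prob[indices])


@dataclass
class PerturbRegression:
    """Least-squares expression change per KO: beta is genes x KO-genes."""

    beta: np.ndarray
    intercepts: np.ndarray
    ko_genes: list[str]
    gene_names: list[str]


def control_baseline(dataset: ExpressionDataset, t: int) -> np.ndarray:
    """Per-gene mean expression over control cells at time ``t``."""
    mask = dataset.is_control & (dataset.time_index == t)
    if not mask.any():
        raise ValueError(f"no control cells at time index {t}")
    return dataset.expr[mask].mean(axis=0)


def build_knockdown_table(dataset: ExpressionDataset) -> KnockdownTable:
    """X[c, i] = -p_c * baseline_t[i] at i = KO gene of cell c, else 0."""
    X = np.zeros_like(dataset.expr)
    baselines = {int(t): control_baseline(dataset, int(t)) for t in dataset.times}
    for c in range(dataset.n_cells):
        g = dataset.ko_gene[c]
        if g == CONTROL:
            continue
        gi = dataset.gene_index(g)
        t = int(dataset.time_index[c])
        X[c, gi] = -dataset.perturb_prob[c] * baselines[t][gi]
    return KnockdownTable(X=X, perturb_prob=dataset.perturb_prob.copy())


def estimate_perturb_prob(dataset: ExpressionDataset, seed: int = 0) -> np.ndarray:
    """Posterior probability that each KO cell's transcriptome was perturbed.

    For each KO gene, every cell is scored by the projection of its deviation
    from the time-matched control baseline onto the (unit-norm) mean
    deviation of its stratum — a 1-D KO-signature score. Scores of the KO
    cells are pooled with control-cell scores and a two-component Gaussian
    mixture is fitted; p_c is the posterior of the component whose mean is
    further from the control bulk. Cells in singleton strata get p_c = 1
    with a warning. Control cells keep p_c = 1 (ignored downstream).
    """
    baselines = {int(t): control_baseline(dataset, int(t)) for t in dataset.times}
    dev = dataset.expr - np.stack([baselines[int(t)] for t in dataset.time_index])
    p = np.ones(dataset.n_cells)
    ctrl_idx = np.flatnonzero(dataset.is_control)
    for g in dataset.ko_genes:
        cells_g = np.flatnonzero(dataset.ko_gene == g)
        if cells_g.size == 1:
            warnings.warn(
                f"KO stratum for {g} has a single cell; perturb_prob set to 1",
                UserWarning, stacklevel=2,
            )
            continue
        # unit-norm stratum signature per time point
        sig = {}
        for t in dataset.times:
            sel = cells_g[dataset.time_index[cells_g] == t]
            if sel.size == 0:
                continue
            s = dev[sel].mean(axis=0)
            nrm = np.linalg.norm(s)
            sig[int(t)] = s / nrm if nrm > 0 else s
        scores_ko = np.array(
            [dev[c] @ sig[int(dataset.time_index[c])] for c in cells_g]
        )
        scores_ctrl = np.array(
            [
                dev[c] @ sig[int(dataset.time_index[c])]
                for c in ctrl_idx
                if int(dataset.time_index[c]) in sig
            ]
        )
        pooled = np.concatenate([scores_ko, scores_ctrl])[:, None]
        if np.ptp(pooled) < 1e-12:
            p[cells_g] = 0.5
            continue
        gm = GaussianMixture(
            n_components=2, random_state=seed, n_init=5, max_iter=200
        ).fit(pooled)
        means = gm.means_.ravel()
        ctrl_center = scores_ctrl.mean() if scores_ctrl.size else 0.0
        affected = int(np.argmax(np.abs(means - ctrl_center)))
        p[cells_g] = gm.predict_proba(scores_ko[:, None])[:, affected]
    return p


def fit_perturb_regression(
    dataset: ExpressionDataset, t: int | None = None
) -> PerturbRegression:
    """Per-gene least squares of expression on KO indicator covariates.

    ``beta[i, j]`` is the fitted expression change of gene i under KO of
    gene j relative to control cells; a two-group design reduces to the
    difference of group means.  ``t`` restricts to one time point (None =
    all cells).  A vanishing ridge (1e-8) stabilizes near-singular designs;
    true rank deficiency (e.g. duplicated KO columns) raises.
    """
    if t is not None:
        keep = np.flatnonzero(dataset.time_index == t)
    else:
        keep = np.arange(dataset.n_cells)
    ko = dataset.ko_gene[keep]
    ko_genes = sorted({g for g in ko if g != CONTROL})
    if not ko_genes:
        raise ValueError("no KO cells in the selected subset")
    n = keep.size
    D = np.zeros((n, 1 + len(ko_genes)))
    D[:, 0] = 1.0
    for j, g in enumerate(ko_genes):
        D[:, 1 + j] = ko == g
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # identify offending strata for the error message
        bad = [
            g for j, g in enumerate(ko_genes)
            if np.linalg.matrix_rank(np.delete(D, 1 + j, axis=1)) == np.linalg.matrix_rank(D)
        ]
        raise ValueError(f"rank-deficient KO design; collinear strata: {bad or ko_genes}")
    Y = dataset.expr[keep]
    G_ = D.T @ D + 1e-8 * np.eye(D.shape[1])
    coef = np.linalg.solve(G_, D.T @ Y)  # (1 + n_ko, G)
    return PerturbRegression(
        beta=coef[1:].T,
        intercepts=coef[0],
        ko_genes=ko_genes,
        gene_names=dataset.gene_names,
    )


def mimosca_score(reg: PerturbRegression) -> float:
    """Mean over KO genes of the total absolute fitted expression change,
    sum_{i,j} |beta_{ij}| / G_ko — a screen for whether single-gene KOs move
    the transcriptome enough for network inference."""
    n_ko = reg.beta.shape[1]
    if n_ko == 0:
        raise ValueError("no KO genes in regression")
    return float(np.abs(reg.beta).sum() / n_ko)


def expression_variation_scores(reg: PerturbRegression) -> pd.Series:
    """Per-gene total |beta| across KOs, sorted descending.

    Used to rank non-KO genes by how much the knockouts move them, when
    selecting genes into the network.
    """
    v = np.abs(reg.beta).sum(axis=1)
    s = pd.Series(v, index=reg.gene_names, name="expression_variation")
    return s.sort_values(ascending=False, kind="mergesort")
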