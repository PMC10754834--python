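"""Synthetic ground-truth networks and simulated time-series KO screens.

The generator emulates the statistical structure the inference model
assumes: a sparse signed network with bounded spectral radius, wild-type
baselines per time point, and per-condition cell populations whose mean
deviation from baseline follows the masked matrix-power propagation with
sigmoid time-order weights. Observed values add i.i.d. Gaussian noise on
the normalized-expression scale. Two optional departures from the model
class are provided for robustness checks: a tanh squashing of each
propagation step, and a negative-binomial count mode with log1p readout.

The KO gene's own coordinate in a KO cell is the knocked-down value
(1 - p) * baseline ~ 0: the generator's mean is the model's forward output
plus the direct knockdown term X at that (masked) coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import core, evaluation
from .dataio import CONTROL, ExpressionDataset, TruthNetwork
from .perturbation import KnockdownTable

__all__ = [
    "SyntheticConfig",
    "generate_network",
    "simulate_dataset",
    "ko_ratio_sweep",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated screen.

    Defaults are the standard desk-scale benchmark: a 20-gene network at
    12% edge density (70% activating edges), spectral radius 0.8, 10 KO
    genes sampled at 4 time points with 30 cells per (KO, time) stratum,
    second-order propagation, and Gaussian noise sd 0.1 on the normalized
    expression scale.
    """

    G: int = 20
    n_ko: int = 10
    T: int = 4
    cells_per_stratum: int = 30
    edge_density: float = 0.12
    sign_mix: float = 0.7
    spectral_cap: float = 0.8
    noise_sd: float = 0.1
    alpha: float = 0.0
    beta_w: float = 1.0
    gamma_w: float = 1.0
    K_true: int = 2
    seed: int = 0
    squash: bool = False  # tanh at each propagation step (model misspecification)
    count_mode: bool = False  # NB counts + log1p readout instead of Gaussian

    def __post_init__(self) -> None:
        if self.n_ko > self.G:
            raise ValueError("n_ko cannot exceed G")
        if not (0 <= self.edge_density <= 1):
            raise ValueError("edge_density must be in [0, 1]")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.G))
        return [f"g{i + 1:0{width}d}" for i in range(self.G)]

    @property
    def ko_genes(self) -> list[str]:
        return self.gene_names[: self.n_ko]


def generate_network(config: SyntheticConfig) -> tuple[np.ndarray, TruthNetwork]:
    """Draw a sparse signed network and rescale it to the spectral cap.

    Off-diagonal support is Bernoulli(edge_density); magnitudes are uniform
    on [0.3, 1]; signs are + with probability sign_mix. When the sampled
    support has a positive spectral radius the matrix is rescaled so the
    radius equals ``spectral_cap`` exactly (an acyclic draw is nilpotent —
    radius 0 — and is left unscaled). Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    G = config.G
    support = rng.random((G, G)) < config.edge_density
    np.fill_diagonal(support, False)
    mag = rng.uniform(0.3, 1.0, size=(G, G))
    sgn = np.where(rng.random((G, G)) < config.sign_mix, 1.0, -1.0)
    A = np.where(support, mag * sgn, 0.0)
    radius = np.max(np.abs(np.linalg.eigvals(A))) if support.any() else 0.0
    if radius > 1e-12:
        A *= config.spectral_cap / radius
    truth = TruthNetwork(
        adjacency=A != 0,
        gene_names=config.gene_names,
        scores=np.abs(A),
        signs=np.sign(A),
    )
    return A, truth


def _true_model(A_true: np.ndarray, b: np.ndarray, config: SyntheticConfig) -> "core.GRNModel":
    return core.GRNModel(
        A=A_true,
        b=b,
        alpha={g: config.alpha for g in config.ko_genes},
        beta_w=config.beta_w,
        gamma_w=config.gamma_w,
        K=config.K_true,
        lambda1=0.0,
        lambda2=0.0,
        gene_names=config.gene_names,
    )


def _mean_deviation(model: "core.GRNModel", g: str, t: int, x: np.ndarray, squash: bool) -> np.ndarray:
    """Propagated deviation from baseline; optionally tanh-squashed per step."""
    gi = model.gene_names.index(g)
    B = model.masked(gi)
    acc = np.zeros(model.G)
    v = x.copy()
    for k in range(1, model.K + 1):
        v = B @ v
        if squash:
            v = np.tanh(v)
        acc += core.weight(model, t, k, g) * v
    return acc


def simulate_dataset(
    A_true: np.ndarray, config: SyntheticConfig
) -> tuple[ExpressionDataset, KnockdownTable, "core.GRNModel"]:
    """Simulate the screen: per-stratum means from the propagation model,
    per-cell Gaussian (or count) observation noise.

    Returns the dataset, the matching knockdown table (p_c = 1,
    X_g = -baseline of g), and the generating model (useful for
    noiseless-consistency checks and closed-loop prediction tests).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    G, T = config.G, config.T
    b_base = rng.uniform(1.0, 5.0, size=G)
    b = np.tile(b_base, (T, 1))  # stationary wild-type baseline
    model = _true_model(A_true, b, config)

    conditions = [CONTROL] + config.ko_genes
    n = len(conditions) * T * config.cells_per_stratum
    expr = np.zeros((n, G))
    X = np.zeros((n, G))
    time_index = np.zeros(n, dtype=int)
    ko = np.empty(n, dtype=object)
    cell_ids = [f"c{i + 1:05d}" for i in range(n)]
    row = 0
    for g in conditions:
        for t in range(1, T + 1):
            if g == CONTROL:
                mean = b[t - 1]
                x = np.zeros(G)
            else:
                gi = config.gene_names.index(g)
                x = np.zeros(G)
                x[gi] = -b[t - 1][gi]
                # forward + direct knockdown: KO coordinate lands near 0
                mean = b[t - 1] + _mean_deviation(model, g, t, x, config.squash) + x
            m = config.cells_per_stratum
            sl = slice(row, row + m)
            if config.count_mode:
                lam = np.maximum(np.exp(mean), 1e-6)
                r_disp = 10.0
                p_nb = r_disp / (r_disp + lam)
                counts = rng.negative_binomial(r_disp, p_nb, size=(m, G))
                expr[sl] = np.log1p(counts)
            else:
                expr[sl] = mean + rng.normal(0.0, config.noise_sd, size=(m, G))
            X[sl] = x
            time_index[sl] = t
            ko[sl] = g
            row += m
    dataset = ExpressionDataset(
        expr=expr,
        gene_names=config.gene_names,
        cell_ids=cell_ids,
        time_index=time_index,
        ko_gene=ko,
        perturb_prob=np.ones(n),
        time_labels={t: t for t in range(1, T + 1)},
    )
    kd = KnockdownTable(X=X, perturb_prob=np.ones(n))
    return dataset, kd, model


def ko_ratio_sweep(
    config: SyntheticConfig,
    ratios: list[float],
    seed: int = 0,
    K_fit: int | None = None,
    lambda1: float = 0.01,
    lambda2: float = 0.01,
) -> pd.DataFrame:
    """Refit on screens where only a fraction of the KO'd genes are observed.

    For each ratio r, a random subset M of the KO genes of size
    round(r * n_ko) (at least 1) is kept; training cells are restricted to
    controls plus cells whose KO target is in M, the network is refitted,
    and AUPRC ratios are reported overall and split by whether the
    regulator of an edge was itself knocked out (in M) or not.
    """
    rng = np.random.default_rng(seed)
    cfg = replace(config, seed=int(rng.integers(2 ** 31)))
    A_true, truth = generate_network(cfg)
    dataset, kd, _ = simulate_dataset(A_true, cfg)
    K_fit = K_fit if K_fit is not None else config.K_true
    gi = {g: i for i, g in enumerate(cfg.gene_names)}
    rows = []
    for r in ratios:
        if not (0 < r <= 1):
            raise ValueError("ratios must lie in (0, 1]")
        n_keep = max(1, round(r * cfg.n_ko))
        M = sorted(rng.choice(cfg.ko_genes, size=n_keep, replace=False).tolist())
        keep = np.flatnonzero(
            (dataset.ko_gene == CONTROL) | np.isin(dataset.ko_gene, M)
        )
        ds_r, kd_r = dataset.subset(keep), kd.subset(keep)
        model = core.fit(ds_r, kd_r, K_fit, lambda1, lambda2, seed=seed)
        in_M = np.zeros(cfg.G, dtype=bool)
        in_M[[gi[g] for g in M]] = True
        by_ko = np.tile(in_M, (cfg.G, 1))  # restrict on the regulator axis
        scores = np.abs(model.A)
        row = {"ratio": r, "n_ko_observed": n_keep}
        row["auprc_ratio_overall"] = evaluation.auprc_ratio(scores, truth)
        for name, restrict in [("ko", by_ko), ("non_ko", ~by_ko)]:
            try:
                row[f"auprc_ratio_{name}"] = evaluation.auprc_ratio(
                    scores, truth, restrict=restrict
                )
            except ValueError:
                row[f"auprc_ratio_{name}"] = np.nan
            for sign in "+-":
                try:
                    row[f"signed_auprc_ratio_{name}_{sign}"] = (
                        evaluation.signed_auprc_ratio(
                            model.A, truth, sign, restrict=restrict
                        )
                    )
                except ValueError:
                    row[f"signed_auprc_ratio_{name}_{sign}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
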