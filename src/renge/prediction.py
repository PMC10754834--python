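"""Predicting genome-wide expression changes after knocking out a network gene,
and the leave-one-KO-out evaluation protocol."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import core
from .dataio import CONTROL, ExpressionDataset
from .perturbation import KnockdownTable, control_baseline

__all__ = ["predict_ko_response", "leave_one_ko_out"]


def predict_ko_response(
    model: "core.GRNModel",
    g: str,
    t: int,
    knockdown_magnitude: float,
) -> np.ndarray:
    """Predicted per-gene expression change (deviation from baseline b_t)
    when gene ``g`` is knocked down by ``knockdown_magnitude`` (<= 0).

    The change is sum_k w(t, k, g) (M_g (.) A)^k x with x the single-entry
    knockdown vector; the component at g itself is always 0 (masked row).
    For a gene never knocked out in training, alpha_g defaults to the mean
    of the fitted alphas. Linear in the knockdown magnitude.
    """
    if g not in model.gene_names:
        raise ValueError(f"unknown gene {g}")
    x = np.zeros(model.G)
    x[model.gene_names.index(g)] = knockdown_magnitude
    return core.forward(model, g, t, x) - model.b[t - 1]


def leave_one_ko_out(
    dataset: ExpressionDataset,
    kd: KnockdownTable,
    K: int,
    lambda1: float,
    lambda2: float,
    j: str,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Hold out all cells targeting KO gene ``j``, refit, and score prediction.

    The model is trained on every remaining cell (controls included) and
    used to predict the expression change under KO of ``j`` at each time
    point; the prediction is compared against the observed change (stratum
    mean minus time-matched control baseline) by Pearson correlation over
    the other G-1 genes. A zero-variance observed change yields a missing
    correlation.

    Returns a frame with columns time, pearson_r, n_cells plus the
    per-time predicted/observed vectors in object columns.
    """
    if j not in dataset.ko_genes:
        raise ValueError(f"{j} is not a KO gene in this dataset")
    if len(dataset.ko_genes) < 2:
        raise ValueError("need at least one other KO gene for training")
    keep = np.flatnonzero(dataset.ko_gene != j)
    ds_tr = dataset.subset(keep)
    kd_tr = kd.subset(keep)
    assert j not in ds_tr.ko_genes
    model = core.fit(ds_tr, kd_tr, K, lambda1, lambda2, seed=seed, **fit_kwargs)

    gi = dataset.gene_index(j)
    held = np.flatnonzero(dataset.ko_gene == j)
    rows = []
    others = np.array([i for i in range(dataset.n_genes) if i != gi])
    for t in dataset.times:
        t = int(t)
        sel = held[dataset.time_index[held] == t]
        if sel.size == 0:
            continue
        base = control_baseline(dataset, t)
        observed = dataset.expr[sel].mean(axis=0) - base
        magnitude = float(kd.X[sel, gi].mean())
        predicted = predict_ko_response(model, j, t, magnitude)
        o, p = observed[others], predicted[others]
        if np.std(o) == 0 or np.std(p) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(o, p)[0, 1])
        rows.append(
            {
                "time": t,
                "pearson_r": r,
                "n_cells": int(sel.size),
                "observed": observed,
                "predicted": predicted,
            }
        )
    return pd.DataFrame(rows)
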