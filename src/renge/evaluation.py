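"""Benchmark statistics for inferred networks.

AUPRC construction: scores are swept over their distinct values from high to
low; equal scores enter as a single threshold step and the area is the sum
of precision x (recall increment) over steps. Under this convention a
constant-score predictor attains exactly the positive prevalence, so the
AUPRC *ratio* (AUPRC divided by prevalence, the exact random-predictor
expectation for exchangeable scores) equals 1 at chance level.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.stats import spearmanr

from .dataio import TruthNetwork, sort_edges

__all__ = [
    "auprc",
    "auprc_ratio",
    "signed_auprc_ratio",
    "classify_edges",
    "top_edges",
    "confidence_rank_correlation",
    "regulatory_correlation",
    "degree_summary",
    "threshold_truth",
]


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve with tie-grouped thresholds."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    P = int(labels.sum())
    if P == 0:
        raise ValueError("no positive labels")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # cumulative counts at the end of each tie group
    boundaries = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundaries, len(s) - 1)
    tp = np.cumsum(y)[ends]
    n_pred = ends + 1
    precision = tp / n_pred
    recall = tp / P
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(precision * d_recall))


def _offdiag_mask(G: int, restrict: np.ndarray | None = None) -> np.ndarray:
    m = ~np.eye(G, dtype=bool)
    if restrict is not None:
        m &= restrict
    return m


def auprc_ratio(
    pred_scores: np.ndarray,
    truth: TruthNetwork,
    restrict: np.ndarray | None = None,
) -> float:
    """AUPRC of |scores| vs truth edges over off-diagonal pairs, divided by
    the positive prevalence (the random-predictor AUPRC). ``restrict`` is an
    optional boolean G x G mask limiting the evaluated pairs (e.g. edges
    from a given regulator subset)."""
    G = truth.adjacency.shape[0]
    m = _offdiag_mask(G, restrict)
    labels = truth.adjacency[m]
    if labels.sum() == 0:
        raise ValueError("truth has no positive edges in the evaluated pairs")
    if (~labels).sum() == 0:
        raise ValueError("truth has no negative pairs in the evaluated pairs")
    prevalence = labels.mean()
    return auprc(np.abs(np.asarray(pred_scores))[m], labels) / prevalence


def signed_auprc_ratio(
    pred_signed: np.ndarray,
    truth: TruthNetwork,
    sign: str,
    restrict: np.ndarray | None = None,
) -> float:
    """AUPRC ratio for one regulation sign.

    For ``sign='+'`` the confidence of negatively-signed predictions is
    floored at 0 and the positives are the positively-signed true edges
    (symmetric for ``'-'``).
    """
    if truth.signs is None:
        raise ValueError("truth network carries no signs")
    if sign not in {"+", "-"}:
        raise ValueError("sign must be '+' or '-'")
    s = np.asarray(pred_signed, dtype=float)
    scores = np.maximum(s, 0.0) if sign == "+" else np.maximum(-s, 0.0)
    want = 1.0 if sign == "+" else -1.0
    pos = truth.adjacency & (truth.signs == want)
    G = pos.shape[0]
    m = _offdiag_mask(G, restrict)
    labels = pos[m]
    if labels.sum() == 0:
        raise ValueError(f"no true edges of sign {sign}")
    prevalence = labels.mean()
    return auprc(scores[m], labels) / prevalence


def classify_edges(pred_top: pd.DataFrame, truth: TruthNetwork) -> pd.DataFrame:
    """Label each predicted edge by its endpoints' relation in the truth graph.

    ``direct`` if the shortest directed path regulator -> target has length
    1, ``indirect`` if longer, ``no_path`` if the target is unreachable.
    ``pred_top`` is typically the top-n predictions where n equals the number
    of true edges (see :func:`top_edges`).
    """
    g = nx.DiGraph()
    g.add_nodes_from(truth.gene_names)
    tgt, reg = np.nonzero(truth.adjacency)
    g.add_edges_from(
        (truth.gene_names[j], truth.gene_names[i]) for i, j in zip(tgt, reg)
    )
    labels = []
    for _, row in pred_top.iterrows():
        r, t = row["regulator"], row["target"]
        try:
            d = nx.shortest_path_length(g, r, t)
            labels.append("direct" if d == 1 else "indirect")
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            labels.append("no_path")
    out = pred_top.copy()
    out["label"] = labels
    return out


def top_edges(edges: pd.DataFrame, n: int) -> pd.DataFrame:
    """First ``n`` edges in canonical order (|coefficient| desc, lexicographic
    tie-break) — the same-number-as-truth prefix used for classification."""
    return sort_edges(edges).head(n)


def confidence_rank_correlation(
    pred_scores: np.ndarray,
    truth_scores: np.ndarray,
) -> float:
    """Spearman correlation between prediction confidences and external
    scores over shared off-diagonal pairs (ties get average ranks).

    Pairs where the external score is missing (NaN) are dropped; fewer than
    3 shared pairs is an error.
    """
    p = np.asarray(pred_scores, dtype=float)
    s = np.asarray(truth_scores, dtype=float)
    G = p.shape[0]
    m = _offdiag_mask(G) & ~np.isnan(s) & ~np.isnan(p)
    if m.sum() < 3:
        raise ValueError("fewer than 3 shared off-diagonal pairs")
    rho, _ = spearmanr(p[m], s[m])
    return float(rho)


def regulatory_correlation(A: np.ndarray) -> np.ndarray:
    """Spearman correlation between every pair of columns of A (the genes'
    outgoing-regulation profiles); genes with a high value tend to share
    targets, a signature of complex co-membership. Constant columns give
    missing entries."""
    A = np.asarray(A, dtype=float)
    G = A.shape[1]
    if A.shape[0] < 3:
        raise ValueError("need at least 3 rows for rank correlation")
    R = np.full((G, G), np.nan)
    const = np.array([np.ptp(A[:, i]) == 0 for i in range(G)])
    for i in range(G):
        if const[i]:
            continue
        R[i, i] = 1.0
        for j in range(i + 1, G):
            if const[j]:
                continue
            rho, _ = spearmanr(A[:, i], A[:, j])
            R[i, j] = R[j, i] = rho
    return R


def degree_summary(
    edges: pd.DataFrame, fdr: float = 0.01, weight: str = "count"
) -> pd.DataFrame:
    """Per-regulator out-degree among edges significant at q < ``fdr``.

    ``weight='count'`` returns positive/negative edge counts per regulator;
    ``weight='abs_sum'`` returns the summed |coefficient|.
    """
    sig = edges[edges["q_value"] < fdr]
    regs = sorted(edges["regulator"].unique())
    rows = []
    for r in regs:
        sub = sig[sig["regulator"] == r]
        if weight == "count":
            rows.append(
                {
                    "regulator": r,
                    "n_positive": int((sub["coefficient"] > 0).sum()),
                    "n_negative": int((sub["coefficient"] < 0).sum()),
                }
            )
        elif weight == "abs_sum":
            rows.append(
                {"regulator": r, "weighted_out_degree": float(sub["coefficient"].abs().sum())}
            )
        else:
            raise ValueError("weight must be 'count' or 'abs_sum'")
    return pd.DataFrame(rows)


def threshold_truth(
    scores: np.ndarray, gene_names: list[str], cutoff: float
) -> TruthNetwork:
    """Build a truth network keeping pairs with score strictly above
    ``cutoff``; higher cutoffs yield nested subsets of edges."""
    s = np.asarray(scores, dtype=float)
    adj = np.where(np.isnan(s), False, s > cutoff)
    return TruthNetwork(
        adjacency=adj, gene_names=gene_names, scores=s, threshold=cutoff
    )
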