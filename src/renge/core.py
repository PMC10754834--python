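"""The regulatory-network model: masked matrix-power propagation of knockout
effects with sigmoid time-order weights, and its regularized fitting.

Model
-----
For a cell sampled at time t whose KO target is gene g, the expected
expression vector is

    E[c] = sum_{k=1..K} w(t, k, g) (M_g (.) A)^k X_c + b_t

where A is the G x G signed coefficient matrix ({A}_{ij} = effect of gene j
on gene i), M_g the mask matrix zeroing row g (a knocked-out gene is no
longer regulated), X_c the per-cell knockdown vector (single nonpositive
entry at g), b_t the wild-type baseline at time t, and

    w(t, k, g) = logistic(alpha_g + beta * t - gamma * k)

an order-k, time-t weight that is increasing in t and decreasing in k
(beta, gamma >= 0): later sampling times expose higher-order regulation.

The loss is the mask-weighted squared error (the KO gene's own coordinate is
ignored — its mRNA may persist after a CRISPR knockout) plus an L1 penalty
on A and an L2 penalty on every power A^k up to K.  The L1 term is made
smooth by splitting A = A+ - A- with A+, A- >= 0, so the whole objective is
differentiable and can be minimized by the bound-constrained quasi-Newton
method L-BFGS-B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .dataio import CONTROL, ExpressionDataset
from .perturbation import KnockdownTable

__all__ = [
    "GRNModel",
    "weight",
    "forward",
    "loss",
    "fit",
    "cv_loss",
    "select_hyperparameters",
]

ALPHA_BOUNDS = (-10.0, 10.0)
BETAGAMMA_BOUNDS = (0.0, 20.0)


@dataclass
class GRNModel:
    """Fitted parameter set of the propagation model.

    ``A[i, j]`` is the signed strength of regulation j -> i; ``b`` stacks the
    T per-time wild-type baselines; ``alpha`` maps each KO gene to its onset
    offset; ``fixed_weight`` (when set) pins w(t, k, g) to a constant instead
    of the logistic form (used for reduced variants and tests).
    """

    A: np.ndarray
    b: np.ndarray  # (T, G)
    alpha: dict[str, float]
    beta_w: float
    gamma_w: float
    K: int
    lambda1: float
    lambda2: float
    gene_names: list[str]
    fixed_weight: float | None = None
    converged: bool = True
    seed: int | None = None
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        if self.fixed_weight is None and not (self.beta_w >= 0 and self.gamma_w >= 0):
            raise ValueError("beta_w and gamma_w must be nonnegative")

    @property
    def G(self) -> int:
        return self.A.shape[0]

    @property
    def T(self) -> int:
        return self.b.shape[0]

    def alpha_for(self, gene: str) -> float:
        """alpha_g for ``gene``; for a gene never knocked out during training,
        fall back to the mean of the fitted alphas (least-informative onset)."""
        if gene in self.alpha:
            return self.alpha[gene]
        if self.alpha:
            return float(np.mean(list(self.alpha.values())))
        return 0.0

    def masked(self, gene_idx: int) -> np.ndarray:
        B = self.A.copy()
        B[gene_idx, :] = 0.0
        return B


def weight(model: GRNModel, t: int, k: int, g: str) -> float:
    """Sigmoid time-order weight w(t, k, g); overflow-safe."""
    if model.fixed_weight is not None:
        return float(model.fixed_weight)
    return float(expit(model.alpha_for(g) + model.beta_w * t - model.gamma_w * k))


def forward(model: GRNModel, g: str, t: int, x: np.ndarray) -> np.ndarray:
    """Expected expression for KO gene ``g`` (or CONTROL) at time ``t``.

    ``x`` is the knockdown vector (all zeros for CONTROL). The component at
    g itself always equals the baseline: the mask zeroes row g of A.
    """
    bt = model.b[t - 1]
    if g == CONTROL:
        return bt.copy()
    gi = model.gene_names.index(g)
    B = model.masked(gi)
    acc = np.zeros(model.G)
    v = np.asarray(x, dtype=float)
    for k in range(1, model.K + 1):
        v = B @ v
        acc += weight(model, t, k, g) * v
    return acc + bt


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


@dataclass
class _Stratum:
    """Sufficient statistics of one (KO gene, time) cell stratum.

    The masked squared error is linear-quadratic in (b_t, mu_dev), so the
    per-cell sum collapses exactly onto the moments below (the KO gene's own
    coordinate is zeroed out of SE/SxE/SEE; mu_dev's coordinate there is
    structurally zero).
    """

    g_idx: int | None  # None = control
    ko_pos: int | None  # position in the KO-gene list
    t: int
    n: int
    Sx: float  # sum of knockdown magnitudes
    Sxx: float  # sum of squared knockdown magnitudes
    SE: np.ndarray  # (G,) masked sum of expression
    SxE: np.ndarray  # (G,) masked sum of x_c * E_c
    SEE: float  # masked sum of squared expression


def _make_stratum(g_idx, ko_pos, t, E, x) -> _Stratum:
    E = np.asarray(E, dtype=float)
    if g_idx is not None:
        E = E.copy()
        E[:, g_idx] = 0.0
    return _Stratum(
        g_idx=g_idx,
        ko_pos=ko_pos,
        t=t,
        n=E.shape[0],
        Sx=float(x.sum()),
        Sxx=float((x ** 2).sum()),
        SE=E.sum(axis=0),
        SxE=(x[:, None] * E).sum(axis=0) if x.size else np.zeros(E.shape[1]),
        SEE=float((E ** 2).sum()),
    )


def _build_strata(dataset: ExpressionDataset, kd: KnockdownTable) -> tuple[list[_Stratum], list[str]]:
    ko_genes = dataset.ko_genes
    ko_pos = {g: i for i, g in enumerate(ko_genes)}
    strata = []
    for (g, t), idx in dataset.strata():
        if g == CONTROL:
            strata.append(_make_stratum(None, None, t, dataset.expr[idx], np.zeros(0)))
        else:
            gi = dataset.gene_index(g)
            strata.append(
                _make_stratum(gi, ko_pos[g], t, dataset.expr[idx], kd.X[idx, gi])
            )
    return strata, ko_genes


class _Objective:
    """Packed loss + analytic gradient over (A+, A-, b, alpha, beta, gamma)."""

    def __init__(
        self,
        strata: list[_Stratum],
        ko_genes: list[str],
        G: int,
        T: int,
        K: int,
        lambda1: float,
        lambda2: float,
        fixed_weight: float | None,
        fit_weights: bool,
    ):
        self.strata = strata
        self.ko_genes = ko_genes
        self.G, self.T, self.K = G, T, K
        self.l1, self.l2 = lambda1, lambda2
        self.fixed_weight = fixed_weight
        self.fit_weights = fit_weights and fixed_weight is None
        self.n_ko = len(ko_genes)
        G2 = G * G
        self._slices = {
            "P": slice(0, G2),
            "N": slice(G2, 2 * G2),
            "b": slice(2 * G2, 2 * G2 + T * G),
        }
        off = 2 * G2 + T * G
        if self.fit_weights:
            self._slices["alpha"] = slice(off, off + self.n_ko)
            self._slices["bg"] = slice(off + self.n_ko, off + self.n_ko + 2)
            off += self.n_ko + 2
        self.n_params = off
        # KO-gene groups: strata sharing a masked matrix
        self.groups: dict[int, list[_Stratum]] = {}
        self.ctrl: list[_Stratum] = []
        for s in strata:
            if s.g_idx is None:
                self.ctrl.append(s)
            else:
                self.groups.setdefault(s.g_idx, []).append(s)

    # -- packing --------------------------------------------------------
    def pack(self, A, b, alpha, beta, gamma) -> np.ndarray:
        theta = np.zeros(self.n_params)
        theta[self._slices["P"]] = np.maximum(A, 0).ravel()
        theta[self._slices["N"]] = np.maximum(-A, 0).ravel()
        theta[self._slices["b"]] = np.asarray(b).ravel()
        if self.fit_weights:
            theta[self._slices["alpha"]] = alpha
            theta[self._slices["bg"]] = [beta, gamma]
        return theta

    def unpack(self, theta):
        G, T = self.G, self.T
        P = theta[self._slices["P"]].reshape(G, G)
        N = theta[self._slices["N"]].reshape(G, G)
        b = theta[self._slices["b"]].reshape(T, G)
        if self.fit_weights:
            alpha = theta[self._slices["alpha"]]
            beta, gamma = theta[self._slices["bg"]]
        else:
            alpha = np.zeros(self.n_ko)
            beta, gamma = 1.0, 1.0
        return P, N, b, alpha, beta, gamma

    def bounds(self):
        bnds = [(0.0, None)] * (2 * self.G * self.G)
        bnds += [(None, None)] * (self.T * self.G)
        if self.fit_weights:
            bnds += [ALPHA_BOUNDS] * self.n_ko
            bnds += [BETAGAMMA_BOUNDS] * 2
        return bnds

    def _weights(self, alpha_g: float, beta: float, gamma: float, t: int):
        """w_k and dw_k/d(logit) for k = 1..K."""
        if self.fixed_weight is not None:
            w = np.full(self.K, self.fixed_weight)
            return w, np.zeros(self.K)
        ks = np.arange(1, self.K + 1)
        w = expit(alpha_g + beta * t - gamma * ks)
        return w, w * (1.0 - w)

    # -- value + gradient -----------------------------------------------
    def __call__(self, theta: np.ndarray):
        G, T, K = self.G, self.T, self.K
        P, N, b, alpha, beta, gamma = self.unpack(theta)
        A = P - N

        val = self.l1 * (P.sum() + N.sum())
        gA = np.zeros((G, G))
        # L2 on matrix powers
        if self.l2 > 0:
            pows = [np.eye(G), A]
            for _ in range(2, K + 1):
                pows.append(pows[-1] @ A)
            for k in range(1, K + 1):
                val += self.l2 * float((pows[k] ** 2).sum())
                for j in range(k):
                    gA += 2 * self.l2 * pows[j].T @ pows[k] @ pows[k - 1 - j].T

        gb = np.zeros((T, G))
        galpha = np.zeros(self.n_ko)
        gbeta = 0.0
        ggamma = 0.0

        for s in self.ctrl:
            bt = b[s.t - 1]
            val += s.SEE - 2 * float(bt @ s.SE) + s.n * float(bt @ bt)
            gb[s.t - 1] += -2 * s.SE + 2 * s.n * bt

        for gi, group in self.groups.items():
            B = A.copy()
            B[gi, :] = 0.0
            # column vectors B^k e_g for k = 0..K
            e = np.zeros(G)
            e[gi] = 1.0
            s_vecs = [e]
            for _ in range(K):
                s_vecs.append(B @ s_vecs[-1])
            u_by_k = np.zeros((K, G))  # accumulated dL/d(w_k * B^k e_g) factors
            for st in group:
                kp = st.ko_pos
                w, dw = self._weights(alpha[kp], beta, gamma, st.t)
                mu_dev = np.zeros(G)
                for k in range(1, K + 1):
                    mu_dev += w[k - 1] * s_vecs[k]
                bm = b[st.t - 1].copy()
                bm[gi] = 0.0  # the KO gene's own squared error is ignored
                val += (
                    st.SEE - 2 * float(bm @ st.SE) + st.n * float(bm @ bm)
                    - 2 * float(mu_dev @ st.SxE) + 2 * st.Sx * float(bm @ mu_dev)
                    + st.Sxx * float(mu_dev @ mu_dev)
                )
                gbt = -2 * st.SE + 2 * st.n * bm + 2 * st.Sx * mu_dev
                gbt[gi] = 0.0
                gb[st.t - 1] += gbt
                xr = -2 * st.SxE + 2 * st.Sx * bm + 2 * st.Sxx * mu_dev
                for k in range(1, K + 1):
                    proj = float(xr @ s_vecs[k])
                    u_by_k[k - 1] += w[k - 1] * xr
                    if self.fit_weights:
                        galpha[kp] += proj * dw[k - 1]
                        gbeta += proj * dw[k - 1] * st.t
                        ggamma += proj * dw[k - 1] * (-k)
            # dL/dB = sum_k sum_{j=0}^{k-1} (B^T)^j u_k (B^{k-1-j} e)^T
            dB = np.zeros((G, G))
            for k in range(1, K + 1):
                u = u_by_k[k - 1]
                Btju = u.copy()
                for j in range(k):
                    dB += np.outer(Btju, s_vecs[k - 1 - j])
                    if j < k - 1:
                        Btju = B.T @ Btju
            dB[gi, :] = 0.0  # masked row never flows into A
            gA += dB

        grad = np.zeros(self.n_params)
        grad[self._slices["P"]] = (gA + self.l1).ravel()
        grad[self._slices["N"]] = (-gA + self.l1).ravel()
        grad[self._slices["b"]] = gb.ravel()
        if self.fit_weights:
            grad[self._slices["alpha"]] = galpha
            grad[self._slices["bg"]] = [gbeta, ggamma]
        return val, grad


def loss(model: GRNModel, dataset: ExpressionDataset, kd: KnockdownTable) -> float:
    """Value of the regularized objective at the model's parameters."""
    strata, ko_genes = _build_strata(dataset, kd)
    obj = _Objective(
        strata, ko_genes, dataset.n_genes, dataset.n_times, model.K,
        model.lambda1, model.lambda2, model.fixed_weight,
        fit_weights=model.fixed_weight is None,
    )
    alpha = np.array([model.alpha.get(g, 0.0) for g in ko_genes])
    theta = obj.pack(model.A, model.b, alpha, model.beta_w, model.gamma_w)
    val, _ = obj(theta)
    return float(val)


def _control_means(dataset: ExpressionDataset) -> np.ndarray:
    T = dataset.n_times
    b = np.zeros((T, dataset.n_genes))
    for t in range(1, T + 1):
        mask = dataset.is_control & (dataset.time_index == t)
        if not mask.any():
            raise ValueError(f"no control cells at time {t}")
        b[t - 1] = dataset.expr[mask].mean(axis=0)
    return b


def fit(
    dataset: ExpressionDataset,
    kd: KnockdownTable,
    K: int,
    lambda1: float,
    lambda2: float,
    seed: int = 0,
    fixed_weight: float | None = None,
    fit_weights: bool = True,
    maxiter: int = 8000,
    ftol: float = 1e-9,
    gtol: float = 1e-6,
    init: GRNModel | None = None,
) -> GRNModel:
    """Fit all parameters jointly by L-BFGS-B.

    Starts from the zero network (the L1-preferred origin) with baselines at
    their zero-network optimum (per-time control means), alpha = 0,
    beta = gamma = 1.  ``fixed_weight`` pins w to a constant and removes the
    weight parameters from the problem.  Deterministic given inputs.
    """
    strata, ko_genes = _build_strata(dataset, kd)
    obj = _Objective(
        strata, ko_genes, dataset.n_genes, dataset.n_times, K,
        lambda1, lambda2, fixed_weight, fit_weights,
    )
    if init is not None:
        alpha0 = np.array([init.alpha.get(g, 0.0) for g in ko_genes])
        theta0 = obj.pack(init.A, init.b, alpha0, init.beta_w, init.gamma_w)
    else:
        b0 = _control_means(dataset)
        theta0 = obj.pack(np.zeros((dataset.n_genes,) * 2), b0,
                          np.zeros(len(ko_genes)), 1.0, 1.0)
    res = minimize(
        obj, theta0, jac=True, method="L-BFGS-B", bounds=obj.bounds(),
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
    )
    if not res.success:
        warnings.warn(
            f"L-BFGS-B did not converge: {res.message}", UserWarning, stacklevel=2
        )
    P, N, b, alpha, beta, gamma = obj.unpack(res.x)
    return GRNModel(
        A=P - N,
        b=b,
        alpha={g: float(a) for g, a in zip(ko_genes, alpha)},
        beta_w=float(beta),
        gamma_w=float(gamma),
        K=K,
        lambda1=lambda1,
        lambda2=lambda2,
        gene_names=dataset.gene_names,
        fixed_weight=fixed_weight,
        converged=bool(res.success),
        seed=seed,
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# cross-validation and hyperparameter search
# ---------------------------------------------------------------------------


def _heldout_error(model: GRNModel, dataset: ExpressionDataset, kd: KnockdownTable) -> tuple[float, int]:
    """Total masked squared error and cell count on a held-out set."""
    total = 0.0
    n = 0
    for (g, t), idx in dataset.strata():
        E = dataset.expr[idx]
        if g == CONTROL:
            R = E - model.b[t - 1]
        else:
            gi = dataset.gene_index(g)
            preds = np.stack([
                forward(model, g, t, kd.X[i] ) for i in idx
            ])
            R = E - preds
            R[:, gi] = 0.0
        total += float((R ** 2).sum())
        n += len(idx)
    return total, n


def cv_loss(
    dataset: ExpressionDataset,
    kd: KnockdownTable,
    K: int,
    lambda1: float,
    lambda2: float,
    folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> float:
    """Mean held-out masked squared error per cell, stratified by (KO gene, time).

    Cells are partitioned fold-wise within each stratum; a stratum smaller
    than ``folds`` stays entirely in training (with a warning).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assign = np.full(dataset.n_cells, -1, dtype=int)
    for (g, t), idx in dataset.strata():
        if len(idx) < folds:
            warnings.warn(
                f"stratum ({g}, t={t}) has {len(idx)} < {folds} cells; kept in training",
                UserWarning, stacklevel=2,
            )
            continue
        perm = rng.permutation(np.sort(idx))
        assign[perm] = np.arange(len(perm)) % folds
    errs = []
    for f in range(folds):
        train_idx = np.flatnonzero(assign != f)
        test_idx = np.flatnonzero(assign == f)
        if test_idx.size == 0:
            continue
        ds_tr = dataset.subset(train_idx)
        kd_tr = kd.subset(train_idx)
        model = fit(ds_tr, kd_tr, K, lambda1, lambda2, seed=seed, **fit_kwargs)
        ds_te = dataset.subset(test_idx)
        kd_te = kd.subset(test_idx)
        total, n = _heldout_error(model, ds_te, kd_te)
        errs.append(total / n)
    return float(np.mean(errs))


def select_hyperparameters(
    dataset: ExpressionDataset,
    kd: KnockdownTable,
    budget: int = 50,
    seed: int = 0,
    folds: int = 5,
    K_max: int = 4,
    **fit_kwargs,
) -> tuple[int, float, float]:
    """Search (K, lambda1, lambda2) minimizing cross-validation loss.

    Seeded random search: K uniform on {1..K_max}, penalties log-uniform on
    [1e-3, 1e2]. Every candidate is scored with the same fold assignment so
    cv losses are comparable; the argmin over evaluated candidates is
    returned and a larger budget can only improve (or tie) the best loss.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(budget):
        K = int(rng.integers(1, K_max + 1))
        l1 = float(10 ** rng.uniform(-3, 2))
        l2 = float(10 ** rng.uniform(-3, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = cv_loss(dataset, kd, K, l1, l2, folds=folds, seed=seed, **fit_kwargs)
        if best is None or score < best[0]:
            best = (score, K, l1, l2)
    return best[1], best[2], best[3]
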