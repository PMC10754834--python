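import numpy as np
import pytest
from scipy.special import expit

from renge import core, synthetic
from renge.core import GRNModel, cv_loss, fit, forward, loss, select_hyperparameters, weight
from renge.dataio import CONTROL
from renge.perturbation import KnockdownTable, build_knockdown_table

from conftest import make_dataset


def _bare_model(A, b, K=1, fixed_weight=None, **kw):
    genes = [f"g{i+1}" for i in range(A.shape[0])]
    defaults = dict(alpha={g: 0.0 for g in genes}, beta_w=0.0, gamma_w=0.0,
                    lambda1=0.0, lambda2=0.0)
    defaults.update(kw)
    return GRNModel(A=A, b=b, K=K, gene_names=genes,
                    fixed_weight=fixed_weight, **defaults)


class TestWeight:
    def test_all_zero_parameters_give_half(self):
        m = _bare_model(np.zeros((2, 2)), np.zeros((1, 2)))
        assert weight(m, t=3, k=2, g="g1") == pytest.approx(0.5)

    def test_logistic_evaluation(self):
        m = _bare_model(np.zeros((2, 2)), np.zeros((1, 2)), beta_w=1.0, gamma_w=1.0)
        # alpha=0, beta=1, gamma=1, t=2, k=1 -> logistic(1)
        assert weight(m, t=2, k=1, g="g1") == pytest.approx(expit(1.0))

    def test_monotone_in_t_and_k(self):
        m = _bare_model(np.zeros((2, 2)), np.zeros((3, 2)), beta_w=0.7, gamma_w=1.3)
        ws_t = [weight(m, t, 1, "g1") for t in (1, 2, 3)]
        ws_k = [weight(m, 2, k, "g1") for k in (1, 2, 3)]
        assert ws_t == sorted(ws_t) and len(set(ws_t)) == 3
        assert ws_k == sorted(ws_k, reverse=True) and len(set(ws_k)) == 3
        assert all(0 < w < 1 for w in ws_t + ws_k)

    def test_large_gamma_kills_weight_without_overflow(self):
        m = _bare_model(np.zeros((2, 2)), np.zeros((1, 2)), beta_w=0.0, gamma_w=1e4)
        assert weight(m, t=1, k=1, g="g1") == pytest.approx(0.0, abs=1e-12)


class TestForward:
    def test_hand_matrix_vector_product(self):
        A = np.array([[0.0, 0.0], [0.5, 0.0]])
        m = _bare_model(A, np.zeros((1, 2)), K=1, fixed_weight=1.0)
        out = forward(m, "g1", 1, np.array([-1.0, 0.0]))
        np.testing.assert_allclose(out, [0.0, -0.5])

    def test_nilpotent_chain_unchanged_by_higher_K(self):
        A = np.array([[0.0, 0.0], [0.5, 0.0]])  # strictly lower-triangular
        x = np.array([-1.0, 0.0])
        m1 = _bare_model(A, np.zeros((1, 2)), K=1, fixed_weight=1.0)
        m2 = _bare_model(A, np.zeros((1, 2)), K=2, fixed_weight=1.0)
        np.testing.assert_allclose(forward(m1, "g1", 1, x), forward(m2, "g1", 1, x))

    def test_control_returns_baseline_exactly(self):
        A = np.full((3, 3), 0.4)
        b = np.array([[1.0, 2.0, 3.0]])
        m = _bare_model(A, b, K=2, fixed_weight=1.0)
        np.testing.assert_array_equal(forward(m, CONTROL, 1, np.zeros(3)), b[0])

    def test_ko_gene_component_equals_baseline_for_any_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            G = 4
            A = rng.normal(size=(G, G))
            b = rng.normal(size=(2, G))
            K = int(rng.integers(1, 4))
            m = _bare_model(A, b, K=K, beta_w=rng.uniform(0, 2),
                            gamma_w=rng.uniform(0, 2))
            g = f"g{rng.integers(1, G+1)}"
            gi = m.gene_names.index(g)
            x = np.zeros(G)
            x[gi] = -rng.uniform(0.5, 3)
            out = forward(m, g, 2, x)
            assert out[gi] == pytest.approx(b[1][gi])


class TestLoss:
    def test_zero_at_exact_control_fit(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]], ["g1", "g2"], [1, 2],
                          [CONTROL, CONTROL])
        kd = build_knockdown_table(ds)
        m = _bare_model(np.zeros((2, 2)), np.array([[1.0, 2.0], [3.0, 4.0]]), K=1)
        assert loss(m, ds, kd) == pytest.approx(0.0)

    def test_penalty_of_symmetric_swap_matrix(self):
        # A = [[0,1],[1,0]], K=2, l2=1: ||A||_F^2 + ||A^2||_F^2 = 2 + 2 = 4
        ds = make_dataset(np.zeros((1, 2)), ["g1", "g2"], [1], [CONTROL])
        kd = build_knockdown_table(ds)
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = _bare_model(A, np.zeros((1, 2)), K=2, lambda2=1.0)
        assert loss(m, ds, kd) == pytest.approx(4.0)

    def test_masked_coordinate_contributes_nothing(self):
        # the KO gene's own squared error is ignored however wrong the value
        ds1 = make_dataset([[5.0, 1.0], [99.0, 1.0]], ["g1", "g2"], [1, 1],
                           [CONTROL, "g1"])
        ds2 = make_dataset([[5.0, 1.0], [-99.0, 1.0]], ["g1", "g2"], [1, 1],
                           [CONTROL, "g1"])
        kd1, kd2 = build_knockdown_table(ds1), build_knockdown_table(ds2)
        m = _bare_model(np.zeros((2, 2)), np.array([[5.0, 1.0]]), K=1)
        assert loss(m, ds1, kd1) == pytest.approx(loss(m, ds2, kd2))


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self, small_screen):
        ds, kd = small_screen["dataset"], small_screen["kd"]
        strata, kos = core._build_strata(ds, kd)
        obj = core._Objective(strata, kos, ds.n_genes, ds.n_times, K=3,
                              lambda1=0.3, lambda2=0.2, fixed_weight=None,
                              fit_weights=True)
        rng = np.random.default_rng(42)
        h = 1e-6
        for trial in range(10):
            theta = rng.uniform(0.05, 0.6, obj.n_params)
            _, grad = obj(theta)
            probe = rng.choice(obj.n_params, size=25, replace=False)
            for i in probe:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h
                tm[i] -= h
                fd = (obj(tp)[0] - obj(tm)[0]) / (2 * h)
                denom = max(abs(fd), abs(grad[i]), 1e-3)
                assert abs(grad[i] - fd) / denom < 1e-5


class TestFit:
    def test_noiseless_recovery_with_frozen_weights(self):
        cfg = synthetic.SyntheticConfig(
            G=4, n_ko=4, T=3, cells_per_stratum=4, noise_sd=0.0,
            edge_density=0.5, K_true=2, seed=5,
        )
        A, _ = synthetic.generate_network(cfg)
        ds, kd, gen = synthetic.simulate_dataset(A, cfg)
        # weight parameters frozen at the generator's values via init + fit_weights=False
        m = fit(ds, kd, K=2, lambda1=1e-6, lambda2=1e-6, fit_weights=False,
                init=gen, ftol=1e-14, gtol=1e-10, maxiter=20000)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(m.A[off], A[off], atol=0.05)

    def test_zero_signal_with_l1_gives_exactly_zero_network(self):
        # KO cells identical to the control baseline: no data force on A,
        # and the L1 penalty keeps the split-sign parts at the origin
        expr = np.tile([5.0, 3.0], (6, 1))
        ds = make_dataset(expr, ["g1", "g2"], [1] * 6,
                          [CONTROL] * 3 + ["g1"] * 3)
        kd = build_knockdown_table(ds)
        m = fit(ds, kd, K=1, lambda1=0.5, lambda2=0.0, fixed_weight=1.0)
        off = ~np.eye(2, dtype=bool)
        np.testing.assert_array_equal(m.A[off], 0.0)

    def test_stronger_l1_never_increases_total_magnitude(self, small_screen):
        ds, kd = small_screen["dataset"], small_screen["kd"]
        m_lo = fit(ds, kd, K=2, lambda1=0.05, lambda2=0.01)
        m_hi = fit(ds, kd, K=2, lambda1=5.0, lambda2=0.01)
        assert np.abs(m_hi.A).sum() <= np.abs(m_lo.A).sum() + 1e-8

    def test_lasso_oracle_equivalence_reduced_model(self):
        """With T=1, K=1, w==1, l2=0 the joint fit separates into per-target
        lasso regressions; compare against scikit-learn coordinate descent."""
        from sklearn.linear_model import Lasso

        cfg = synthetic.SyntheticConfig(
            G=5, n_ko=5, T=1, cells_per_stratum=15, noise_sd=0.1,
            edge_density=0.4, K_true=1, seed=7,
        )
        A, _ = synthetic.generate_network(cfg)
        ds, kd, _ = synthetic.simulate_dataset(A, cfg)
        lam1 = 0.5
        m = fit(ds, kd, K=1, lambda1=lam1, lambda2=0.0, fixed_weight=1.0,
                ftol=1e-14, gtol=1e-9, maxiter=20000)
        for i, gene in enumerate(ds.gene_names):
            keep = np.flatnonzero(ds.ko_gene != gene)
            n = keep.size
            oracle = Lasso(alpha=lam1 / (2 * n), fit_intercept=True,
                           tol=1e-12, max_iter=100000)
            oracle.fit(kd.X[keep], ds.expr[keep, i])
            np.testing.assert_allclose(m.A[i], oracle.coef_, atol=1e-3)

    def test_fit_deterministic(self, small_screen):
        ds, kd = small_screen["dataset"], small_screen["kd"]
        m1 = fit(ds, kd, K=2, lambda1=0.1, lambda2=0.1, seed=0)
        m2 = fit(ds, kd, K=2, lambda1=0.1, lambda2=0.1, seed=0)
        np.testing.assert_array_equal(m1.A, m2.A)


class TestCrossValidation:
    def test_duplicated_cells_make_heldout_equal_training_error(self):
        # every stratum holds exactly two identical cells, so a 2-fold split
        # necessarily puts one copy in each fold: each fold trains on the
        # same empirical distribution as the full data and is scored on it
        rng = np.random.default_rng(0)
        cells = rng.normal(3.0, 1.0, size=(3, 3))
        expr = np.repeat(cells, 2, axis=0)
        ko = np.repeat([CONTROL, "g1", "g2"], 2)
        ds = make_dataset(expr, ["g1", "g2", "g3"], [1] * 6, ko)
        kd = build_knockdown_table(ds)
        cv = cv_loss(ds, kd, K=1, lambda1=0.0, lambda2=0.0, folds=2, seed=0,
                     fixed_weight=1.0, ftol=1e-14, gtol=1e-10)
        m = fit(ds, kd, K=1, lambda1=0.0, lambda2=0.0, fixed_weight=1.0,
                ftol=1e-14, gtol=1e-10)
        train_err, n = core._heldout_error(m, ds, kd)
        assert cv == pytest.approx(train_err / n, rel=1e-3)

    def test_cv_deterministic_given_seed(self, small_screen):
        ds, kd = small_screen["dataset"], small_screen["kd"]
        a = cv_loss(ds, kd, K=1, lambda1=0.1, lambda2=0.1, folds=3, seed=4)
        b = cv_loss(ds, kd, K=1, lambda1=0.1, lambda2=0.1, folds=3, seed=4)
        assert a == b

    def test_small_stratum_stays_in_training_with_warning(self):
        expr = np.tile([3.0, 1.0], (5, 1))
        ds = make_dataset(expr, ["g1", "g2"], [1] * 5, [CONTROL] * 4 + ["g1"])
        kd = build_knockdown_table(ds)
        with pytest.warns(UserWarning, match="kept in training"):
            cv_loss(ds, kd, K=1, lambda1=0.1, lambda2=0.0, folds=2, seed=0,
                    fixed_weight=1.0)


class TestHyperparameterSearch:
    def test_budget_one_returns_single_candidate(self, small_screen):
        ds, kd = small_screen["dataset"], small_screen["kd"]
        K, l1, l2 = select_hyperparameters(ds, kd, budget=1, seed=0, folds=2)
        assert K in {1, 2, 3, 4}
        assert 1e-3 <= l1 <= 1e2 and 1e-3 <= l2 <= 1e2

    def test_larger_budget_never_worse(self, small_screen):
        ds, kd = small_screen["dataset"], small_screen["kd"]

        def best_cv(budget):
            K, l1, l2 = select_hyperparameters(ds, kd, budget=budget, seed=0, folds=2)
            return cv_loss(ds, kd, K, l1, l2, folds=2, seed=0)

        assert best_cv(4) <= best_cv(1) + 1e-12
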