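import numpy as np
import pytest
from sklearn.linear_model import Lasso, LogisticRegression

from precision_lasso import (
    DesignMatrix,
    PenaltyConfig,
    SolverConfig,
    fit,
    fit_logistic,
    select_lambda_for_k,
    surrogate_objective,
    sym_sqrt,
    smoothed_inv_sqrt,
    trace_norm,
)
from tests.conftest import make_duplicated_design

TIGHT = SolverConfig(max_iter=3000, tol=1e-12, fit_intercept=False)


class TestSurrogateObjective:
    def test_ones_beta_orthonormal_gamma_one(self, orthonormal_design, rng):
        y = rng.standard_normal(64)
        beta = np.ones(8)
        val = surrogate_objective(orthonormal_design, y, beta, PenaltyConfig(gamma=1.0, mu=1.0))
        resid = y - orthonormal_design.values @ beta
        assert val == pytest.approx(resid @ resid + 8.0, rel=1e-10)

    def test_zero_beta_gamma_one(self, orthonormal_design, rng):
        y = rng.standard_normal(64)
        val = surrogate_objective(orthonormal_design, y, np.zeros(8), PenaltyConfig(gamma=1.0, mu=1.0))
        assert val == pytest.approx(y @ y, rel=1e-8)

    def test_matches_bruteforce_assembly(self, random_design, rng):
        y = rng.standard_normal(20)
        beta = rng.standard_normal(6)
        gamma, mu = 0.35, 1.2
        val = surrogate_objective(random_design, y, beta, PenaltyConfig(gamma=gamma, mu=mu))
        Xv = random_design.values
        t1 = float(np.sum((y - Xv @ beta) ** 2))
        XB = Xv @ np.diag(beta)
        t2 = np.linalg.svd(sym_sqrt(XB.T @ XB))[1].sum()
        XBi = Xv @ np.diag(1.0 / beta)  # all |beta| above the floor here
        t3 = np.linalg.svd(smoothed_inv_sqrt(XBi.T @ XBi, mu))[1].sum()
        assert val == pytest.approx(t1 + gamma * t2 + (1 - gamma) * t3, rel=1e-8)


class TestFitSquared:
    def test_identity_design_unregularized(self, rng):
        n = 12
        y = rng.standard_normal(n)
        X = DesignMatrix(np.eye(n))
        res = fit(X, y, PenaltyConfig(gamma=1.0, mu=1.0, lam=0.0), TIGHT)
        np.testing.assert_allclose(res.beta, y, atol=1e-8)

    def test_matches_lasso_on_orthonormal_design(self, orthonormal_design, rng):
        Q = orthonormal_design.values
        y = Q @ np.array([2.0, -1.5, 1.0, 0, 0, 0, 0, 0]) + 0.3 * rng.standard_normal(64)
        for lam in (0.1, 0.5):
            res = fit(orthonormal_design, y, PenaltyConfig(gamma=1.0, mu=1.0, lam=lam), TIGHT)
            ref = Lasso(alpha=lam / 64, fit_intercept=False, tol=1e-12, max_iter=200000).fit(Q, y)
            np.testing.assert_allclose(res.beta, ref.coef_, atol=1e-4)

    def test_duplicated_active_columns_share_weight(self, rng):
        X = make_duplicated_design(rng, n=100, p=8)
        beta_true = np.zeros(8)
        beta_true[[0, 1, 3]] = [1.0, 1.0, -1.5]
        y = X.values @ beta_true + 0.2 * rng.standard_normal(100)
        lam = 0.1 * np.max(np.abs(X.values.T @ y))
        res = fit(X, y, PenaltyConfig(gamma=1.0, mu=1.0, lam=lam),
                  SolverConfig(max_iter=2000, tol=1e-10, fit_intercept=False))
        b0, b1 = res.beta[0], res.beta[1]
        assert abs(b0) > 0.1  # the pair is genuinely active
        assert abs(b0 - b1) < 1e-3 * max(abs(b0), abs(b1))

    def test_ols_limit(self, rng):
        n, p = 200, 20
        Xv = rng.standard_normal((n, p))
        y = Xv @ rng.standard_normal(p) + rng.standard_normal(n)
        X = DesignMatrix(Xv)
        res = fit(X, y, PenaltyConfig(gamma=0.5, mu=1.0, lam=0.0), SolverConfig())
        Xc = Xv - Xv.mean(0)
        ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(res.beta, ols, atol=1e-6)
        assert res.intercept == pytest.approx(
            y.mean() - Xv.mean(0) @ ols, abs=1e-6
        )

    def test_objective_trace_non_increasing(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = DesignMatrix(r.standard_normal((40, 15)))
            y = r.standard_normal(40)
            res = fit(X, y, PenaltyConfig(gamma=0.5, mu="auto", lam=3.0),
                      SolverConfig(max_iter=300, tol=1e-8))
            diffs = np.diff(res.objective_trace)
            assert diffs.max(initial=-np.inf) <= 1e-9

    def test_permutation_equivariance(self, rng):
        X = DesignMatrix(rng.standard_normal((30, 6)))
        y = rng.standard_normal(30)
        perm = rng.permutation(6)
        cfg = PenaltyConfig(gamma=0.5, mu=1.0, lam=2.0)
        res = fit(X, y, cfg, TIGHT)
        res_p = fit(DesignMatrix(X.values[:, perm]), y, cfg, TIGHT)
        np.testing.assert_allclose(res_p.beta, res.beta[perm], atol=1e-6)

    def test_monotone_sparsity_in_lambda(self, rng):
        X = DesignMatrix(rng.standard_normal((50, 12)))
        beta_true = np.zeros(12)
        beta_true[:3] = [2.0, -1.0, 1.5]
        y = X.values @ beta_true + 0.5 * rng.standard_normal(50)
        counts = []
        for lam in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0):
            res = fit(X, y, PenaltyConfig(gamma=1.0, mu=1.0, lam=lam),
                      SolverConfig(max_iter=1000, tol=1e-9, fit_intercept=False))
            counts.append(len(res.selected))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_selected_sorted_by_magnitude(self, rng):
        X = DesignMatrix(rng.standard_normal((50, 8)))
        y = X.values[:, 0] * 3 + X.values[:, 4] * 1.5 + 0.1 * rng.standard_normal(50)
        res = fit(X, y, PenaltyConfig(gamma=1.0, mu=1.0, lam=5.0), TIGHT)
        mags = [abs(res.beta[i]) for i in res.selected]
        assert mags == sorted(mags, reverse=True)
        assert len(set(res.selected)) == len(res.selected)


class TestFitLogistic:
    def test_large_lambda_shrinks_to_class_balance(self, rng):
        n, p = 300, 6
        Xv = rng.standard_normal((n, p))
        y = (rng.random(n) < 0.3).astype(float)
        X = DesignMatrix(Xv)
        res = fit_logistic(X, y, PenaltyConfig(gamma=1.0, mu=1.0, lam=1e6),
                           SolverConfig(max_iter=500, tol=1e-10))
        assert np.all(res.beta == 0.0)
        logodds = np.log(y.mean() / (1 - y.mean()))
        assert res.intercept == pytest.approx(logodds, abs=1e-2)

    def test_matches_l1_logistic_oracle(self, rng):
        n, p = 400, 6
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        Xv = Q  # orthonormal columns: penalty is exactly l1 at gamma=1
        beta_true = np.array([8.0, -6.0, 4.0, 0, 0, 0])
        probs = 1 / (1 + np.exp(-(Xv @ beta_true)))
        y = (rng.random(n) < probs).astype(float)
        lam = 2.0
        res = fit_logistic(DesignMatrix(Xv), y,
                           PenaltyConfig(gamma=1.0, mu=1.0, lam=lam),
                           SolverConfig(max_iter=2000, tol=1e-10,
                                        fit_intercept=False))
        # liblinear regularizes its intercept, so compare intercept-free
        ref = LogisticRegression(l1_ratio=1.0, C=1.0 / lam, solver="liblinear",
                                 fit_intercept=False, tol=1e-10,
                                 max_iter=10000).fit(Xv, y)
        np.testing.assert_allclose(res.beta, ref.coef_.ravel(), atol=5e-3)

    def test_recovers_true_actives(self):
        from precision_lasso import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n=2000, p=40, k=3, ar_coef=0.3, n_dep=3,
                               effect_size=2.0, response="binary", seed=3)
        ds = simulate_dataset(cfg)
        Xs = ds.X.standardize()
        res = fit_logistic(Xs, ds.y, PenaltyConfig(gamma=1.0, mu="auto", lam=5.0),
                           SolverConfig(max_iter=300, tol=1e-6))
        top3 = np.argsort(-np.abs(res.beta))[:3]
        assert set(int(i) for i in top3) == set(ds.true_active)

    def test_single_class_rejected(self, rng):
        X = DesignMatrix(rng.standard_normal((20, 3)))
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(X, np.zeros(20), PenaltyConfig(gamma=1.0, mu=1.0, lam=1.0))

    def test_objective_trace_non_increasing(self, rng):
        X = DesignMatrix(rng.standard_normal((80, 10)))
        y = (rng.random(80) < 0.5).astype(float)
        res = fit_logistic(X, y, PenaltyConfig(gamma=0.5, mu="auto", lam=2.0),
                           SolverConfig(max_iter=300, tol=1e-8))
        assert np.diff(res.objective_trace).max(initial=-np.inf) <= 1e-9


class TestSelectLambdaForK:
    def test_k_equals_p_unregularized(self, rng):
        X = DesignMatrix(rng.standard_normal((40, 5)))
        y = X.values @ np.array([1.0, -2, 0.5, 3, -1]) + 0.1 * rng.standard_normal(40)
        lam, res = select_lambda_for_k(X, y, PenaltyConfig(gamma=1.0, mu=1.0),
                                       SolverConfig(), K=5)
        assert lam == 0.0
        assert len(res.selected) == 5

    def test_orthonormal_brackets_soft_threshold(self, orthonormal_design, rng):
        Q = orthonormal_design.values
        y = Q @ np.array([3.0, -2.5, 2.0, 1.5, 0.1, 0.05, 0.02, 0.01])
        K = 3
        lam, res = select_lambda_for_k(
            orthonormal_design, y, PenaltyConfig(gamma=1.0, mu=1.0),
            SolverConfig(max_iter=2000, tol=1e-10, fit_intercept=False), K=K,
        )
        c = np.sort(np.abs(Q.T @ y))[::-1]
        # exact-K soft-threshold window for the orthonormal-design Lasso,
        # with 2% slack for the smoothed solver's threshold blur
        assert 0.98 * c[K] <= lam <= 1.02 * c[K - 1]
        assert len(res.selected) == K

    def test_exact_count_on_simulated_ar_design(self):
        from precision_lasso import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n=120, p=60, k=5, ar_coef=0.5, n_dep=5, seed=11)
        ds = simulate_dataset(cfg)
        Xs = ds.X.standardize()
        lam, res = select_lambda_for_k(
            Xs, ds.y, PenaltyConfig(gamma=0.8, mu="auto"),
            SolverConfig(max_iter=300, tol=1e-6), K=5,
        )
        assert len(res.selected) == 5
        assert lam > 0

    def test_k_out_of_range(self, rng):
        X = DesignMatrix(rng.standard_normal((20, 4)))
        with pytest.raises(ValueError):
            select_lambda_for_k(X, rng.standard_normal(20), K=5)
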