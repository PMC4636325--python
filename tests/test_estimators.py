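"""OLS and penalized least-squares solvers."""

import numpy as np
import pytest

from penregsim import (
    PenalizedRegression,
    PenaltySpec,
    fit_ols,
    fit_penalized,
    generate_dataset,
    regularization_path,
    scenario,
)
from penregsim.estimators import penalized_objective, _solve_std
from penregsim.exceptions import (
    DegreesOfFreedomError,
    InvalidPenaltyError,
    SingularDesignError,
)


def _random_instance(seed, n=80, k=6, snr=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    beta = rng.standard_normal(k) * snr
    y = 0.7 + X @ beta + rng.standard_normal(n)
    return X, y


class TestOLS:
    def test_exact_interpolation(self):
        X = np.column_stack([np.linspace(-1, 1, 10), np.zeros(10) + np.arange(10) % 2])
        y = 2.0 * X[:, 0] + 1.0
        fr = fit_ols((X, y))
        assert fr.intercept == pytest.approx(1.0, abs=1e-10)
        assert fr.coefficients == pytest.approx([2.0, 0.0], abs=1e-10)
        assert fr.rss == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        import statsmodels.api as sm

        ds = generate_dataset(scenario("B", n=110), seed=21)
        fr = fit_ols(ds)
        res = sm.OLS(ds.y, sm.add_constant(ds.X)).fit()
        assert fr.intercept == pytest.approx(res.params[0], abs=1e-10)
        assert np.allclose(fr.coefficients, res.params[1:], atol=1e-10)
        assert fr.rss == pytest.approx(res.ssr, rel=1e-10)

    def test_null_coefficients_within_sampling_bound(self):
        n = 10_000
        rng = np.random.default_rng(3)
        X = rng.standard_normal((n, 5))
        y = rng.standard_normal(n)
        fr = fit_ols((X, y))
        assert np.all(np.abs(fr.coefficients) < 4 / np.sqrt(n))

    def test_rank_deficiency_raises(self):
        X = np.ones((30, 2))
        X[:, 1] = 2.0  # both columns constant -> collinear with intercept
        with pytest.raises(SingularDesignError):
            fit_ols((X, np.arange(30.0)))

    def test_degrees_of_freedom_guard(self):
        X = np.random.default_rng(0).standard_normal((5, 5))
        with pytest.raises(DegreesOfFreedomError):
            fit_ols((X, np.arange(5.0)))


class TestPenalized:
    def test_zero_penalty_equals_ols(self, dataset_b50):
        fr = fit_penalized(dataset_b50, PenaltySpec(0.0, 0.0))
        fo = fit_ols(dataset_b50)
        assert np.allclose(fr.coefficients, fo.coefficients, atol=1e-8)
        assert fr.intercept == pytest.approx(fo.intercept, abs=1e-8)

    def test_orthonormal_design_soft_threshold(self):
        """On an orthonormal centered design the lasso is the soft-thresholded OLS fit."""
        rng = np.random.default_rng(4)
        M = rng.standard_normal((60, 5))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))  # centered orthonormal columns
        y = rng.standard_normal(60)
        b_ols = Q.T @ (y - y.mean())
        lam1 = 0.8
        est = PenalizedRegression(lambda1=lam1, standardize=False).fit(Q, y)
        expect = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam1 / 2, 0.0)
        assert np.allclose(est.coef_, expect, atol=1e-8)

    def test_huge_l1_gives_empty_model(self, dataset_b50):
        fr = fit_penalized(dataset_b50, PenaltySpec(1e6, 0.0))
        assert fr.n_nonzero == 0
        assert fr.intercept == pytest.approx(dataset_b50.y.mean(), abs=1e-12)

    def test_coordinate_descent_matches_closed_form_ridge(self):
        """The generic solver run at lambda1 = 0 equals the closed-form ridge solution."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, k = rng.integers(30, 200), rng.integers(2, 10)
            X = rng.standard_normal((n, k))
            y = X @ rng.standard_normal(k) + rng.standard_normal(n)
            Xc = X - X.mean(axis=0)
            yc = y - y.mean()
            G, c = Xc.T @ Xc, Xc.T @ yc
            lam2 = float(rng.uniform(0.1, 50.0))
            closed = np.linalg.solve(G + lam2 * np.eye(k), c)
            beta = np.zeros(k)
            from penregsim.estimators import _cd_gram

            _cd_gram(G, c, beta, 0.0, lam2, 1e-12, 100_000)
            assert np.allclose(beta, closed, atol=1e-8)

    def test_matches_independent_elastic_net_oracle(self):
        """Cross-check against scikit-learn's solver configured to the same objective.

        Our objective ||r||^2 + l1|b| + l2 b^2 equals 2n times sklearn's
        with alpha = l1/(2n) + l2/n and l1_ratio = (l1/(2n)) / alpha.
        """
        from sklearn.linear_model import ElasticNet

        for seed in range(4):
            X, y = _random_instance(seed)
            n = len(y)
            lam1 = float(np.random.default_rng(seed).uniform(0.5, 10))
            lam2 = float(np.random.default_rng(seed + 100).uniform(0.0, 10))
            Xs = (X - X.mean(0)) / X.std(0)
            yc = y - y.mean()
            alpha = lam1 / (2 * n) + lam2 / n
            l1r = (lam1 / (2 * n)) / alpha
            sk = ElasticNet(alpha=alpha, l1_ratio=l1r, fit_intercept=False,
                            tol=1e-12, max_iter=500_000).fit(Xs, yc)
            mine = PenalizedRegression(lam1, lam2).fit(X, y)
            assert np.allclose(mine.coef_ * X.std(0), sk.coef_, atol=1e-6)

    def test_solution_is_local_optimum(self, dataset_b50, rng):
        pen = PenaltySpec(2.0, 1.0)
        fr = fit_penalized(dataset_b50, pen)
        X, y = dataset_b50.X, dataset_b50.y
        f0 = penalized_objective(X, y, fr.intercept, fr.coefficients, pen)
        assert f0 <= penalized_objective(X, y, y.mean(), np.zeros(X.shape[1]), pen) + 1e-10
        for _ in range(200):
            delta = rng.standard_normal(X.shape[1]) * 0.01
            assert f0 <= penalized_objective(X, y, fr.intercept, fr.coefficients + delta, pen) + 1e-10

    def test_invariance_to_column_permutation(self, dataset_b50):
        pen = PenaltySpec(3.0, 2.0)
        fr = fit_penalized(dataset_b50, pen)
        perm = np.array([4, 0, 7, 2, 8, 1, 6, 3, 5])
        fr_p = fit_penalized((dataset_b50.X[:, perm], dataset_b50.y), pen)
        assert np.allclose(fr_p.coefficients, fr.coefficients[perm], atol=1e-8)

    def test_invariance_to_response_rescaling(self, dataset_b50):
        """Mapping y -> a*y + b scales the solution at (a*l1, l2) by a.

        Substituting beta = a*beta~ in the objective multiplies the RSS and
        L2 terms by a^2 while the L1 term picks up a single factor a, so
        only lambda1 needs rescaling.
        """
        a, b = 2.5, -1.0
        lam1, lam2 = 2.0, 3.0
        base = fit_penalized(dataset_b50, PenaltySpec(lam1, lam2))
        scaled = fit_penalized(
            (dataset_b50.X, a * dataset_b50.y + b), PenaltySpec(a * lam1, lam2)
        )
        assert np.allclose(scaled.coefficients, a * base.coefficients, atol=1e-8)
        assert scaled.intercept == pytest.approx(a * base.intercept + b, abs=1e-8)

    def test_monotone_shrinkage(self):
        for seed in range(3):
            X, y = _random_instance(seed, n=60, k=5)
            l1_norms = []
            for lam1 in [0.0, 0.5, 2.0, 8.0, 32.0]:
                fr = fit_penalized((X, y), PenaltySpec(lam1, 1.0))
                l1_norms.append(np.abs(fr.coefficients * X.std(0)).sum())
            assert np.all(np.diff(l1_norms) <= 1e-8)
            l2_norms = []
            for lam2 in [0.0, 0.5, 2.0, 8.0, 32.0]:
                fr = fit_penalized((X, y), PenaltySpec(1.0, lam2))
                l2_norms.append(float(np.sum((fr.coefficients * X.std(0)) ** 2)))
            assert np.all(np.diff(l2_norms) <= 1e-8)

    def test_negative_penalty_rejected(self):
        with pytest.raises(InvalidPenaltyError):
            PenaltySpec(-1.0, 0.0)
        with pytest.raises(InvalidPenaltyError):
            PenalizedRegression(lambda1=-0.5).fit(np.eye(3), np.ones(3))

    def test_sklearn_get_set_params_round_trip(self):
        est = PenalizedRegression(lambda1=1.0, lambda2=2.0)
        params = est.get_params()
        assert params["lambda1"] == 1.0
        est.set_params(lambda1=5.0)
        assert est.lambda1 == 5.0


class TestRegularizationPath:
    def test_singleton_path_equals_direct_fit(self, dataset_b50):
        pen = PenaltySpec(1.5, 0.5)
        path = regularization_path(dataset_b50, [pen])
        direct = fit_penalized(dataset_b50, pen)
        assert np.allclose(path[0].coefficients, direct.coefficients, atol=1e-8)

    def test_path_matches_cold_starts_and_sparsity_monotone(self, dataset_b50):
        lam1s = [50.0, 20.0, 8.0, 3.0, 1.0, 0.3]
        pens = [PenaltySpec(l, 0.0) for l in lam1s]
        path = regularization_path(dataset_b50, pens)
        nnz = []
        for pen, fr in zip(pens, path):
            cold = fit_penalized(dataset_b50, pen)
            assert np.allclose(fr.coefficients, cold.coefficients, atol=1e-8)
            nnz.append(fr.n_nonzero)
        # decreasing lambda1 -> non-decreasing number of selected variables
        assert np.all(np.diff(nnz) >= 0)

    def test_ridge_path_matches_closed_form(self, dataset_b50):
        lam2s = [0.5, 5.0, 50.0]
        path = regularization_path(dataset_b50, [PenaltySpec(0.0, l) for l in lam2s])
        X, y = dataset_b50.X, dataset_b50.y
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        G, c = Xs.T @ Xs, Xs.T @ yc
        for lam2, fr in zip(lam2s, path):
            closed = np.linalg.solve(G + lam2 * np.eye(X.shape[1]), c) / X.std(0)
            assert np.allclose(fr.coefficients, closed, atol=1e-8)

    def test_empty_path_rejected(self, dataset_b50):
        with pytest.raises(ValueError):
            regularization_path(dataset_b50, [])
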