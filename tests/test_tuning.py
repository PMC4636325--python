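"""Cross-validation error and penalty-tuning strategies."""

import numpy as np
import pytest

from penregsim import (
    CVTunedRegression,
    PenalizedRegression,
    PenaltySpec,
    kfold_cv_error,
    optimize_lambda,
    tune,
)
from penregsim.exceptions import FoldSizeError
from penregsim.tuning import make_folds


class TestKFoldCVError:
    def test_determinism(self, dataset_b50):
        pen = PenaltySpec(2.0, 1.0)
        v1 = kfold_cv_error(dataset_b50, pen, K=10, folds_seed=3)
        v2 = kfold_cv_error(dataset_b50, pen, K=10, folds_seed=3)
        assert v1 == v2

    def test_huge_penalty_approaches_response_variance(self, dataset_b50):
        err = kfold_cv_error(dataset_b50, PenaltySpec(1e8, 0.0), K=10, folds_seed=0)
        assert err == pytest.approx(np.var(dataset_b50.y), rel=0.05)

    def test_leave_one_out_matches_brute_force(self):
        rng = np.random.default_rng(6)
        n, k = 20, 2
        X = rng.standard_normal((n, k))
        y = X @ np.array([1.0, -0.5]) + rng.standard_normal(n)
        pen = PenaltySpec(0.5, 0.2)
        loo = kfold_cv_error((X, y), pen, K=n, folds_seed=0)
        total = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            est = PenalizedRegression(pen.lambda1, pen.lambda2).fit(X[mask], y[mask])
            total += float((y[i] - est.predict(X[i : i + 1])[0]) ** 2)
        assert loo == pytest.approx(total / n, abs=1e-10)

    def test_fold_constraints(self):
        with pytest.raises(ValueError):
            make_folds(10, 1, 0)
        with pytest.raises(FoldSizeError):
            make_folds(3, 4, 0)
        assert len(make_folds(20, 20, 0)) == 20  # LOO allowed


class TestOptimizeLambda:
    def test_pure_noise_prefers_heavy_shrinkage(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        lam2 = optimize_lambda((X, y), "lambda2", K=10, folds_seed=1)
        assert lam2 > 10.0  # substantial shrinkage of every coefficient
        err = kfold_cv_error((X, y), PenaltySpec(0.0, lam2), K=10, folds_seed=1)
        assert err < np.var(y) * 1.05
        # dense-grid oracle: the chosen point is no worse than a 200-point grid
        dense = [
            kfold_cv_error((X, y), PenaltySpec(0.0, l), K=10, folds_seed=1)
            for l in np.geomspace(1e-3, 1e3, 200)
        ]
        assert err <= min(dense) + 1e-3

    def test_strong_signal_prefers_light_l1(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100, 4))
        y = X @ np.array([2.0, -2.0, 1.5, 1.0]) + 0.3 * rng.standard_normal(100)
        lam1 = optimize_lambda((X, y), "lambda1", K=10, folds_seed=2)
        assert lam1 < 5.0
        err = kfold_cv_error((X, y), PenaltySpec(lam1, 0.0), K=10, folds_seed=2)
        assert err < np.var(y) * 0.2  # far better than intercept-only

    def test_degenerate_single_point_grid(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        lam = optimize_lambda((X, y), "lambda2", K=5, folds_seed=0,
                              bounds=(7.0, 7.0 + 1e-12), grid_size=1)
        assert lam in (0.0, 7.0)

    def test_unknown_parameter_name_rejected(self, dataset_b50):
        with pytest.raises(ValueError):
            optimize_lambda(dataset_b50, "lambda3")


class TestTune:
    def test_ridge_keeps_l1_exactly_zero(self, dataset_b50):
        res = tune("Ridge", dataset_b50, K=10, folds_seed=5)
        assert res.penalty.lambda1 == 0.0
        assert res.penalty.lambda2 > 0.0

    def test_lasso_keeps_l2_exactly_zero(self, dataset_b50):
        res = tune("LASSO", dataset_b50, K=10, folds_seed=5)
        assert res.penalty.lambda2 == 0.0

    def test_enet1_first_stage_reproduces_lasso(self, dataset_b50):
        """With shared folds, Enet1's lambda1 equals the LASSO choice."""
        lasso = tune("LASSO", dataset_b50, K=10, folds_seed=5)
        enet1 = tune("Enet1", dataset_b50, K=10, folds_seed=5)
        assert enet1.penalty.lambda1 == pytest.approx(lasso.penalty.lambda1, rel=1e-12)

    def test_joint_search_dominates_sequential(self, dataset_b50):
        """Enet3's evaluated set includes both axes, so its CV optimum can
        only improve on the sequential strategies under the same folds."""
        e1 = tune("Enet1", dataset_b50, K=10, folds_seed=5)
        e2 = tune("Enet2", dataset_b50, K=10, folds_seed=5)
        e3 = tune("Enet3", dataset_b50, K=10, folds_seed=5)
        assert e3.cv_error <= e1.cv_error + 1e-10
        assert e3.cv_error <= e2.cv_error + 1e-10

    @pytest.mark.parametrize("strategy", ["Ridge", "LASSO", "Enet1", "Enet2", "Enet3"])
    def test_reported_error_matches_recomputation(self, dataset_b50, strategy):
        res = tune(strategy, dataset_b50, K=10, folds_seed=7)
        recomputed = kfold_cv_error(dataset_b50, res.penalty, K=10, folds_seed=7)
        assert abs(recomputed - res.cv_error) <= 1e-12

    def test_chosen_point_minimizes_profile(self, dataset_b50):
        res = tune("LASSO", dataset_b50, K=10, folds_seed=9)
        errs = [e for (_, _, e) in res.profile]
        assert res.cv_error <= min(errs) + 1e-8

    def test_doubling_grid_density_does_not_worsen_minimum(self, dataset_b50):
        coarse = tune("LASSO", dataset_b50, K=10, folds_seed=4, grid_size=25)
        fine = tune("LASSO", dataset_b50, K=10, folds_seed=4, grid_size=50)
        assert fine.cv_error <= coarse.cv_error * (1 + 2e-2) + 1e-12

    def test_profile_serialization(self, dataset_b50):
        res = tune("Enet2", dataset_b50, K=10, folds_seed=1)
        df = res.profile_frame()
        assert list(df.columns) == ["lambda1", "lambda2", "cv_error"]
        d = res.to_dict()
        assert d["strategy"] == "Enet2"
        assert d["n_evaluated"] == len(res.profile)

    def test_unknown_strategy_rejected(self, dataset_b50):
        with pytest.raises(ValueError):
            tune("Enet4", dataset_b50)


class TestCVTunedRegression:
    def test_estimator_interface(self, dataset_b50):
        est = CVTunedRegression(strategy="LASSO", cv=10, folds_seed=3)
        est.fit(dataset_b50.X, dataset_b50.y)
        assert est.lambda2_ == 0.0
        assert est.coef_.shape == (9,)
        pred = est.predict(dataset_b50.X)
        assert pred.shape == (50,)
        # final coefficients equal a direct fit at the chosen penalty
        direct = PenalizedRegression(est.lambda1_, est.lambda2_).fit(
            dataset_b50.X, dataset_b50.y
        )
        assert np.allclose(est.coef_, direct.coef_)

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = CVTunedRegression(strategy="Enet3", cv=5)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
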