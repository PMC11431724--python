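"""Weighted lasso path solver: closed forms, oracles, KKT certificates."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression, lasso_path

from sparserank import (
    PathSpec,
    compute_lambda_max,
    fit_path,
    kkt_residuals,
    predict_path,
    soft_threshold,
)

from oracles import weighted_lasso_oracle


def _standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    return (X - X.mean(0)) / X.std(0)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z, t, expected", [(3, 1, 2), (-0.5, 1, 0), (-3, 1, -2), (0, 0, 0), (2, 0, 2)]
    )
    def test_values(self, z, t, expected):
        assert soft_threshold(z, t) == expected


class TestLambdaMax:
    def test_closed_form_single_column(self):
        n = 40
        x = np.tile([1.0, -1.0], n // 2)  # mean 0, x.x/n = 1
        y = 2.0 * x  # x.y/n = 2
        assert compute_lambda_max(x[:, None], y, np.array([2.0])) == pytest.approx(1.0)

    def test_max_over_weighted_gradients(self, rng):
        n = 200
        X = _standardized(rng, n, 2)
        # engineer gradients then check the max of |g_j|/w_j
        y = rng.standard_normal(n)
        g = np.abs((X - X.mean(0)).T @ (y - y.mean()) / n)
        w = np.array([1.0, 3.0])
        assert compute_lambda_max(X, y, w) == pytest.approx(np.max(g / w))

    def test_boundary_property(self, rng):
        """All-null at lambda_max; something active just below it."""
        X = _standardized(rng, 50, 4)
        y = X @ np.array([1.0, 0, -2.0, 0]) + 0.1 * rng.standard_normal(50)
        w = np.array([1.0, 2.0, 1.5, 1.0])
        lam = compute_lambda_max(X, y, w)
        fit = fit_path(X, y, w, PathSpec(lambdas=np.array([lam, 0.99 * lam])))
        assert np.all(fit.coef[:, 0] == 0.0)
        assert np.any(fit.coef[:, 1] != 0.0)

    def test_all_zero_weights_error(self, rng):
        X = _standardized(rng, 20, 2)
        with pytest.raises(ValueError, match="nothing to penalize"):
            compute_lambda_max(X, X[:, 0], np.zeros(2))


class TestGaussianPath:
    def test_orthonormal_closed_form(self):
        """On an orthonormal design the solution is a soft threshold."""
        n = 8
        Q, _ = np.linalg.qr(np.random.default_rng(3).standard_normal((n, 3)))
        X = Q * np.sqrt(n)  # X'X = nI, columns mean not exactly 0 -> center y too
        X = X - X.mean(0)
        # re-orthonormalize after centering
        Q, _ = np.linalg.qr(X)
        X = Q * np.sqrt(n)
        y = X @ np.array([1.5, -0.3, 0.0])
        w = np.array([1.0, 1.0, 2.0])
        lam = 0.5
        fit = fit_path(X, y, w, PathSpec(lambdas=np.array([lam])))
        z = X.T @ (y - y.mean()) / n
        expected = soft_threshold(z, lam * w)
        np.testing.assert_allclose(fit.coef[:, 0], expected, atol=1e-7)

    def test_lambda_zero_matches_ols(self, small_gaussian):
        X, y, _ = small_gaussian
        fit = fit_path(X, y, np.ones(X.shape[1]), PathSpec(lambdas=np.array([1.0, 0.0])))
        ols = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef[:, 1], ols[1:], atol=1e-6)
        np.testing.assert_allclose(fit.intercept[1], ols[0], atol=1e-6)

    def test_matches_qp_oracle_random_instance(self):
        rng = np.random.default_rng(42)
        X = _standardized(rng, 20, 5)
        y = X @ np.array([1.0, 0, -0.5, 0, 0.2]) + rng.standard_normal(20)
        w = rng.uniform(0.5, 2.0, 5)
        lam_max = compute_lambda_max(X, y, w)
        lambdas = lam_max * np.array([0.5, 0.2, 0.05])
        fit = fit_path(X, y, w, PathSpec(lambdas=lambdas))
        for li, lam in enumerate(lambdas):
            beta_star, icpt_star = weighted_lasso_oracle(X, y, w, lam)
            np.testing.assert_allclose(fit.coef[:, li], beta_star, atol=1e-6)
            np.testing.assert_allclose(fit.intercept[li], icpt_star, atol=1e-6)

    def test_matches_sklearn_plain_lasso(self, small_gaussian):
        X, y, _ = small_gaussian
        fit = fit_path(X, y, np.ones(X.shape[1]), PathSpec(n_lambda=30))
        Xc, yc = X - X.mean(0), y - y.mean()
        _, coefs, _ = lasso_path(Xc, yc, alphas=fit.lambdas, tol=1e-14)
        np.testing.assert_allclose(fit.coef, coefs, atol=1e-6)

    def test_weighted_equals_rescaled_plain_lasso(self, rng):
        """w-weighted fit == unit-weight fit on X/w with coefficients rescaled."""
        X = _standardized(rng, 80, 6)
        y = X @ np.array([2.0, 0, 1.0, 0, 0, -1.0]) + rng.standard_normal(80)
        w = rng.uniform(0.3, 3.0, 6)
        fit_w = fit_path(X, y, w, PathSpec(n_lambda=25))
        fit_u = fit_path(X / w, y, np.ones(6), PathSpec(lambdas=fit_w.lambdas))
        np.testing.assert_allclose(fit_w.coef, fit_u.coef / w[:, None], atol=1e-8)

    def test_objective_nonincreasing_along_warm_starts(self, small_gaussian):
        X, y, _ = small_gaussian
        w = np.ones(X.shape[1])
        fit = fit_path(X, y, w, PathSpec(n_lambda=40))
        # at each lambda the fit must beat the previous (warm start) point
        Xc, yc = X - X.mean(0), y - y.mean()

        def obj(beta, lam):
            r = yc - Xc @ beta
            return 0.5 * np.mean(r**2) + lam * np.sum(w * np.abs(beta))

        for li in range(1, fit.n_lambda):
            lam = fit.lambdas[li]
            assert obj(fit.coef[:, li], lam) <= obj(fit.coef[:, li - 1], lam) + 1e-12

    def test_path_continuity(self, small_gaussian):
        X, y, _ = small_gaussian
        fit = fit_path(X, y, np.ones(X.shape[1]), PathSpec(n_lambda=100))
        dlam = -np.diff(fit.lambdas)
        dcoef = np.abs(np.diff(fit.coef, axis=1)).max(axis=0)
        assert np.all(dcoef <= 50 * dlam + 1e-8)

    def test_nonfinite_inputs_rejected(self, small_gaussian):
        X, y, _ = small_gaussian
        X = X.copy()
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_path(X, y, np.ones(X.shape[1]))


class TestBinomialPath:
    def test_matches_sklearn_l1_logistic(self, rng):
        n, p = 200, 4
        X = _standardized(rng, n, p)
        prob = 1 / (1 + np.exp(-(X @ np.array([1.5, 0, -1.0, 0]))))
        y = (rng.random(n) < prob).astype(float)
        lam = 0.02
        fit = fit_path(
            X, y, np.ones(p), PathSpec(family="binomial", lambdas=np.array([0.1, lam]))
        )
        ref = LogisticRegression(
            penalty="l1", C=1.0 / (n * lam), solver="saga", tol=1e-10, max_iter=50_000
        ).fit(X, y)
        np.testing.assert_allclose(fit.coef[:, 1], ref.coef_[0], atol=2e-4)
        np.testing.assert_allclose(fit.intercept[1], ref.intercept_[0], atol=2e-4)

    def test_probabilities_in_unit_interval(self, rng):
        X = _standardized(rng, 60, 3)
        y = (rng.random(60) < 0.4).astype(float)
        fit = fit_path(X, y, np.ones(3), PathSpec(family="binomial", n_lambda=10))
        pred = predict_path(fit, X * 50)  # extreme inputs
        assert np.all((pred > 0) & (pred < 1))

    def test_requires_01_response(self, rng):
        X = _standardized(rng, 30, 2)
        with pytest.raises(ValueError, match="0/1"):
            fit_path(X, np.arange(30.0), np.ones(2), PathSpec(family="binomial"))


class TestKKT:
    def test_converged_fit_certifies(self, small_gaussian):
        X, y, _ = small_gaussian
        w = np.array([1.0, 2.0, 0.5, 1.0, 1.0, 3.0])
        fit = fit_path(X, y, w, PathSpec(n_lambda=50))
        viol = kkt_residuals(fit, X, y, w)
        assert viol.max() < 1e-6

    def test_null_fit_at_lambda_max(self, small_gaussian):
        X, y, _ = small_gaussian
        w = np.ones(X.shape[1])
        lam = compute_lambda_max(X, y, w)
        fit = fit_path(X, y, w, PathSpec(lambdas=np.array([lam])))
        assert kkt_residuals(fit, X, y, w)[0] <= 1e-10

    def test_corrupted_fit_detected(self, small_gaussian):
        X, y, _ = small_gaussian
        w = np.ones(X.shape[1])
        fit = fit_path(X, y, w, PathSpec(n_lambda=10))
        fit.coef[0, -1] += 0.1
        viol = kkt_residuals(fit, X, y, w)
        assert viol[-1] > 1e-4


class TestPredict:
    def test_all_zero_coefficients_constant_prediction(self, small_gaussian):
        X, y, _ = small_gaussian
        w = np.ones(X.shape[1])
        lam = compute_lambda_max(X, y, w)
        fit = fit_path(X, y, w, PathSpec(lambdas=np.array([lam])))
        pred = predict_path(fit, X, index=0)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-10)

    def test_empty_design_intercept_only(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_path(np.empty((4, 0)), y, np.empty(0), PathSpec())
        pred = predict_path(fit, np.empty((4, 0)), index=0)
        np.testing.assert_allclose(pred, 2.5)
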