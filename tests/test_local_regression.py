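import numpy as np
import pytest
from scipy.optimize import minimize

from lmdr.local_regression import (
    RidgeConfig,
    fit_local_model,
    jacobian_series,
    loocv_rmse,
    sequential_fit,
)
from lmdr.state_space import EmbeddingMatrix, LocalityMatrix

from conftest import make_linear_embedding


def _objective(c, A, y, w, lam, n):
    # weighted mean squared error + ridge penalty (intercept unpenalized)
    r = y - A @ c
    return (r * w * r).sum() / n + lam * np.sum(c[:-1] ** 2)


class TestFitLocalModel:
    def test_exact_interpolation_of_linear_target(self, rng):
        X = rng.normal(size=(30, 2))
        y = 2 * X[:, 0] - X[:, 1] + 1.0
        emb = EmbeddingMatrix(X=X, targets=y, column_roles=["a", "b"],
                              target_variable="a", row_times=np.arange(30.0))
        c0, c = fit_local_model(emb, y, np.ones(30), RidgeConfig(lambda_=0.0))
        np.testing.assert_allclose(c, [2, -1], atol=1e-10)
        assert c0 == pytest.approx(1.0, abs=1e-10)

    def test_large_penalty_shrinks_to_weighted_mean(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        w = rng.uniform(0.2, 1.0, size=40)
        c0, c = fit_local_model(X, y, w, RidgeConfig(lambda_=1e9))
        np.testing.assert_allclose(c, 0.0, atol=1e-6)
        assert c0 == pytest.approx(np.sum(w * y) / np.sum(w), rel=1e-6)

    @pytest.mark.parametrize("lam", [0.1, 0.01])
    def test_closed_form_matches_numerical_minimizer(self, lam):
        # independent oracle: generic optimizer on the weighted ridge objective
        rng = np.random.default_rng(3)
        for trial in range(20):
            m, E = rng.integers(15, 50), rng.integers(1, 5)
            X = rng.normal(size=(m, E))
            y = rng.normal(size=m)
            w = rng.uniform(0.05, 1.0, size=m)
            c0, c = fit_local_model(X, y, w, RidgeConfig(lambda_=lam))
            A = np.column_stack([X, np.ones(m)])
            x0 = np.zeros(E + 1)
            res = minimize(_objective, x0, args=(A, y, w, lam, m), method="BFGS",
                           options={"gtol": 1e-12, "maxiter": 2000})
            np.testing.assert_allclose(np.r_[c, c0], res.x, atol=1e-6)

    def test_all_zero_weights_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="positive weight"):
            fit_local_model(X, np.zeros(10), np.zeros(10), RidgeConfig())

    def test_sqrt_weighting_equivalence(self, rng):
        # the ridge closed form equals ridge on the sqrt(w)-scaled system
        m, E, lam = 40, 3, 0.05
        X = rng.normal(size=(m, E))
        y = rng.normal(size=m)
        w = rng.uniform(0.1, 1.0, size=m)
        c0, c = fit_local_model(X, y, w, RidgeConfig(lambda_=lam))
        A = np.column_stack([X, np.ones(m)]) * np.sqrt(w)[:, None]
        z = y * np.sqrt(w)
        pen = np.eye(E + 1)
        pen[E, E] = 0
        ref = np.linalg.solve(A.T @ A + m * lam * pen, A.T @ z)
        np.testing.assert_allclose(np.r_[c, c0], ref, atol=1e-10)


class TestSequentialFit:
    def test_linear_map_recovery_any_theta(self, linear_map):
        emb, _ = make_linear_embedding(linear_map, m=200, seed=0)
        for theta in (LocalityMatrix.identity(3), LocalityMatrix(np.diag([2.0, 0.5, 1.3]))):
            fits = sequential_fit(emb, theta=theta, config=RidgeConfig(lambda_=1e-8))
            np.testing.assert_allclose(
                fits.coefficients, np.tile(linear_map[0], (emb.m, 1)), atol=1e-5
            )
            np.testing.assert_allclose(fits.intercepts, 0.0, atol=1e-5)

    def test_scalar_ar1(self):
        x = np.empty(60)
        x[0] = 1.0
        for t in range(59):
            x[t + 1] = 0.5 * x[t]
        # re-excite across scales so the series is not a single decaying arc
        rng = np.random.default_rng(1)
        segs = []
        for s in range(6):
            x0 = rng.uniform(0.5, 2.0) * (-1) ** s
            seg = [x0]
            for _ in range(9):
                seg.append(0.5 * seg[-1])
            segs.append(seg)
        ts_vals = np.array([v for seg in segs for v in seg])
        emb = EmbeddingMatrix(
            X=ts_vals[:-1, None], targets=0.5 * ts_vals[:-1],
            column_roles=["x"], target_variable="x", row_times=np.arange(59.0),
        )
        fits = sequential_fit(emb, config=RidgeConfig(lambda_=1e-10))
        np.testing.assert_allclose(fits.coefficients[:, 0], 0.5, atol=1e-6)
        np.testing.assert_allclose(fits.intercepts, 0.0, atol=1e-6)

    def test_prediction_reproduces_affine_form(self, small_embedding):
        fits = sequential_fit(small_embedding, config=RidgeConfig(lambda_=1e-4))
        manual = fits.intercepts + np.einsum(
            "ke,ke->k", fits.coefficients, small_embedding.X
        )
        np.testing.assert_allclose(fits.predictions, manual, atol=1e-12)

    def test_self_exclusion_makes_prediction_out_of_sample(self, small_embedding):
        from lmdr.state_space import lmd_distance, lmd_weights

        theta = LocalityMatrix.identity(2)
        w = lmd_weights(lmd_distance(small_embedding, theta))
        fits = sequential_fit(small_embedding, weights=w, config=RidgeConfig(lambda_=1e-6))
        # inflating the self-weight changes nothing because row k is excluded
        w_inflated = w
        w_inflated.w = w.w.copy()
        np.fill_diagonal(w_inflated.w, 1e6)
        fits2 = sequential_fit(small_embedding, weights=w_inflated, config=RidgeConfig(lambda_=1e-6))
        np.testing.assert_allclose(fits.predictions, fits2.predictions, atol=1e-10)

    def test_ridge_shrinkage_monotone(self, small_embedding):
        norms = []
        for lam in (1e-4, 1e-2, 1.0):
            fits = sequential_fit(small_embedding, config=RidgeConfig(lambda_=lam))
            norms.append(np.linalg.norm(fits.coefficients))
        assert norms[0] >= norms[1] >= norms[2]

    def test_svd_solver_matches_weighted_system(self, small_embedding):
        # the SVD route solves b = Ac with b, A scaled by w (not sqrt(w))
        from lmdr.state_space import lmd_distance, lmd_weights

        w = lmd_weights(lmd_distance(small_embedding, LocalityMatrix.identity(2))).w.copy()
        np.fill_diagonal(w, 0.0)
        fits = sequential_fit(small_embedding, config=RidgeConfig(solver="svd"))
        k = 5
        A = np.column_stack([small_embedding.X, np.ones(small_embedding.m)])
        ref = np.linalg.pinv(w[k][:, None] * A, rcond=1e-10) @ (w[k] * small_embedding.targets)
        np.testing.assert_allclose(np.r_[fits.coefficients[k], fits.intercepts[k]], ref, atol=1e-8)


class TestSkillAndJacobians:
    def test_perfect_forecast(self):
        fits = _dummy_fits(preds=np.array([1.0, 2.0, 3.0, 4.0]))
        s = loocv_rmse(fits, np.array([1.0, 2.0, 3.0, 4.0]))
        assert s.rmse == 0 and s.pearson_rho == pytest.approx(1.0)

    def test_constant_shift(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        s = loocv_rmse(_dummy_fits(preds=y + 0.7), y)
        assert s.rmse == pytest.approx(0.7)
        assert s.pearson_rho == pytest.approx(1.0)

    def test_anticorrelated(self):
        s = loocv_rmse(_dummy_fits(preds=np.array([1.0, 2.0, 3.0])), np.array([-1.0, -2.0, -3.0]))
        assert s.pearson_rho == pytest.approx(-1.0)

    def test_too_few_predictions(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            loocv_rmse(_dummy_fits(preds=np.array([1.0, 2.0])), np.array([1.0, 2.0]))

    def test_jacobian_series_stacks_per_variable_rows(self, linear_map):
        emb, Y = make_linear_embedding(linear_map, m=100, seed=2)
        fits = []
        for i in range(3):
            e = EmbeddingMatrix(X=emb.X, targets=Y[:, i], column_roles=emb.column_roles,
                                target_variable=f"x{i + 1}", row_times=emb.row_times)
            fits.append(sequential_fit(e, config=RidgeConfig(lambda_=1e-8)))
        J = jacobian_series(fits)
        assert J.shape == (100, 3, 3)
        np.testing.assert_allclose(J, np.tile(linear_map, (100, 1, 1)), atol=1e-5)

    def test_jacobian_series_alignment_check(self, linear_map):
        emb, Y = make_linear_embedding(linear_map, m=50, seed=3)
        f1 = sequential_fit(emb, config=RidgeConfig(lambda_=1e-8))
        emb2, Y2 = make_linear_embedding(linear_map, m=40, seed=4)
        f2 = sequential_fit(emb2, config=RidgeConfig(lambda_=1e-8))
        with pytest.raises(ValueError, match="aligned"):
            jacobian_series([f1, f2])


def _dummy_fits(preds):
    from lmdr.local_regression import LocalFitSeries

    m = len(preds)
    return LocalFitSeries(
        intercepts=np.zeros(m),
        coefficients=np.zeros((m, 1)),
        predictions=np.asarray(preds, float),
        target_variable="x",
        column_roles=["x"],
        row_times=np.arange(m, dtype=float),
    )
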