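import numpy as np
import pytest

from powdercal import (
    HyperGrid,
    LSSVMModel,
    LSSVMResults,
    fit_lssvm,
    grid_search_lssvm,
    loo_rmsecv,
    loo_rmsecv_naive,
    rbf_kernel,
)
from powdercal.lssvm import kernel_matrix


class TestRBFKernel:
    def test_zero_distance_gives_one(self):
        u = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(u, u, sigma2=5.0) == pytest.approx(1.0)

    def test_unit_scaled_distance(self):
        u, v = np.array([0.0]), np.array([2.0])  # ||u-v||^2 = 4
        assert rbf_kernel(u, v, sigma2=4.0) == pytest.approx(np.exp(-1.0))

    def test_scalar_oracle(self):
        assert rbf_kernel(np.array([0.0, 0.0]), np.array([1.0, 2.0]), 10.0) == \
            pytest.approx(np.exp(-0.5), abs=1e-15)

    def test_invalid_sigma2(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.array([1.0]), np.array([2.0]), 0.0)

    def test_kernel_matrix_psd_and_symmetric(self, rng):
        X = rng.normal(size=(15, 4))
        K = kernel_matrix(X, X, sigma2=3.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-10


class TestFit:
    def test_constant_response_gives_zero_alpha_and_bias_c(self, rng):
        X = rng.normal(size=(8, 3))
        res = fit_lssvm(X, np.full(8, 7.5), gamma=10.0, sigma2=2.0)
        np.testing.assert_allclose(res.alpha, 0.0, atol=1e-10)
        assert res.bias == pytest.approx(7.5)

    def test_kkt_residual_oracle(self, rng):
        """Rebuild the KKT system independently and check A·[b;α] = [0;y]."""
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        res = fit_lssvm(X, y, gamma=5.0, sigma2=3.0)
        n = len(y)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        for i in range(n):
            for j in range(n):
                A[i + 1, j + 1] = rbf_kernel(X[i], X[j], 3.0)
            A[i + 1, i + 1] += 1.0 / 5.0
        sol = np.concatenate([[res.bias], res.alpha])
        rhs = np.concatenate([[0.0], y])
        assert np.linalg.norm(A @ sol - rhs) <= 1e-8 * np.linalg.norm(y)

    def test_alpha_sums_to_zero(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        res = fit_lssvm(X, y, gamma=2.0, sigma2=1.5)
        assert abs(res.alpha.sum()) < 1e-9

    def test_residuals_equal_alpha_over_gamma(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        gamma = 3.0
        res = fit_lssvm(X, y, gamma=gamma, sigma2=2.0)
        resid = y - res.fittedvalues
        np.testing.assert_allclose(resid, res.alpha / gamma, rtol=1e-8, atol=1e-10)

    def test_large_gamma_near_interpolation(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        res = fit_lssvm(X, y, gamma=1e8, sigma2=2.0)
        np.testing.assert_allclose(res.fittedvalues, y, atol=1e-4)

    def test_prediction_invariant_under_sample_permutation(self, rng):
        X = rng.normal(size=(14, 4))
        y = rng.normal(size=14)
        perm = rng.permutation(14)
        m1 = fit_lssvm(X, y, gamma=4.0, sigma2=2.5)
        m2 = fit_lssvm(X[perm], y[perm], gamma=4.0, sigma2=2.5)
        Xnew = rng.normal(size=(6, 4))
        np.testing.assert_allclose(m1.predict(Xnew), m2.predict(Xnew), atol=1e-8)

    def test_invalid_hyperparameters(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        with pytest.raises(ValueError):
            fit_lssvm(X, y, gamma=-1.0, sigma2=1.0)


class TestLeaveOneOut:
    def test_closed_form_matches_naive_refit_loop(self, rng):
        """The leverage shortcut must agree with the normative n-refit
        loop on 20-sample problems."""
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        for gamma, sigma2 in [(0.5, 1.0), (10.0, 5.0), (1e3, 0.3)]:
            fast = loo_rmsecv(X, y, gamma, sigma2)
            slow = loo_rmsecv_naive(X, y, gamma, sigma2)
            assert fast == pytest.approx(slow, abs=1e-8)


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        grid = HyperGrid((2.0,), (3.0,))
        g, s, r = grid_search_lssvm(X, y, grid, refine=False)
        assert (g, s) == (2.0, 3.0)
        assert r == pytest.approx(loo_rmsecv_naive(X, y, 2.0, 3.0), abs=1e-8)

    def test_duplicated_grid_point_idempotent(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        g1 = grid_search_lssvm(X, y, HyperGrid((1.0, 10.0), (1.0, 5.0)), refine=False)
        g2 = grid_search_lssvm(
            X, y, HyperGrid((1.0, 10.0, 10.0), (1.0, 1.0, 5.0)), refine=False
        )
        assert g1 == g2

    def test_returns_grid_minimum(self, rng):
        X = rng.normal(size=(15, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=15)
        grid = HyperGrid((0.1, 1.0, 10.0), (0.5, 2.0, 8.0))
        g, s, r = grid_search_lssvm(X, y, grid, refine=False)
        all_vals = {
            (gg, ss): loo_rmsecv_naive(X, y, gg, ss)
            for gg in grid.gamma_values
            for ss in grid.sigma2_values
        }
        assert r == pytest.approx(min(all_vals.values()), abs=1e-8)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid((), (1.0,))

    def test_model_fit_with_search_records_rmsecv(self, rng):
        X = rng.normal(size=(15, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + 0.05 * rng.normal(size=15)
        res = LSSVMModel(y, X).fit(grid=HyperGrid((1.0, 100.0), (1.0, 10.0)),
                                   refine=False)
        assert res.rmsecv is not None and res.rmsecv > 0
        assert res.gamma in (1.0, 100.0) and res.sigma2 in (1.0, 10.0)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        res = fit_lssvm(X, y, gamma=5.0, sigma2=2.0)
        p = tmp_path / "lssvm.json"
        res.to_json(p)
        again = LSSVMResults.from_json(p)
        Xnew = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(again.predict(Xnew), res.predict(Xnew))
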