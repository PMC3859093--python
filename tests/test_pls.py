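import numpy as np
import pytest

from powdercal import (
    PLSModel,
    PLSResults,
    RankDeficiencyWarning,
    cv_rmsecv_by_lv,
    fit_plsr,
    predict_plsr,
    select_n_lv,
)


def ols_fitted(X, y):
    """Least-squares oracle via the normal equations with intercept."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    return Xc @ beta


class TestFit:
    def test_full_lv_matches_least_squares_oracle(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        res = fit_plsr(X, y, n_lv=3)
        np.testing.assert_allclose(res.predict(X), ols_fitted(X, y), atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        T = fit_plsr(X, y, n_lv=5).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_single_factor_reproduces_collinear_response(self, rng):
        # y lies along one X column; remaining (centered) columns orthogonal
        raw = rng.normal(size=(12, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q
        y = 3.0 * q[:, 0]
        res = fit_plsr(X, y, n_lv=1)
        assert res.rmsec < 1e-10

    def test_coefficient_and_score_paths_agree(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        res = fit_plsr(X, y, n_lv=4)
        Xnew = rng.normal(size=(7, 6))
        np.testing.assert_allclose(
            res.predict(Xnew), res.predict_via_scores(Xnew), rtol=1e-8, atol=1e-10
        )

    def test_rmsec_non_increasing_in_n_lv(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        model = PLSModel(y, X)
        rmsecs = [model.fit(n_lv=k).rmsec for k in range(1, 8)]
        assert all(a >= b - 1e-12 for a, b in zip(rmsecs, rmsecs[1:]))

    def test_sample_permutation_invariance(self, rng):
        X = rng.normal(size=(18, 5))
        y = rng.normal(size=18)
        perm = rng.permutation(18)
        b1 = fit_plsr(X, y, n_lv=3).params
        b2 = fit_plsr(X[perm], y[perm], n_lv=3).params
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_excess_lv_truncates_with_warning(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        with pytest.warns(RankDeficiencyWarning):
            res = fit_plsr(X, y, n_lv=4)
        assert res.n_lv <= 2

    def test_nan_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="NaN"):
            fit_plsr(X, np.array([1.0, 2.0]), 1)

    def test_constant_response_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="constant"):
            PLSModel(np.full(6, 5.0), X)

    def test_matches_sklearn_pls_regression(self, rng):
        """Independent cross-check against scikit-learn's PLS."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30) + X[:, 0]
        ours = fit_plsr(X, y, n_lv=4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.predict(X), ref.predict(X).ravel(), rtol=1e-8, atol=1e-8
        )


class TestPredict:
    def test_training_prediction_reproduces_fitted_values(self, rng):
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        res = fit_plsr(X, y, n_lv=2)
        np.testing.assert_allclose(predict_plsr(res, X), res.fittedvalues)

    def test_mean_input_predicts_mean_response(self, rng):
        X = rng.normal(size=(11, 5))
        y = rng.normal(size=11)
        res = fit_plsr(X, y, n_lv=3)
        assert res.predict(res.x_mean[None, :])[0] == pytest.approx(res.y_mean)

    def test_hand_worked_two_variable_model(self):
        # b = (1, -2), b0 = 3 at x = (1, 1) -> 3 + 1 - 2 = 2
        res = PLSResults(
            model=None,
            x_mean=np.zeros(2),
            y_mean=3.0,
            weights=np.zeros((2, 1)),
            loadings=np.zeros((2, 1)),
            y_loadings=np.zeros(1),
            scores=None,
            coefs_per_lv=np.array([[1.0], [-2.0]]),
            n_lv=1,
        )
        assert res.intercept == pytest.approx(3.0)
        assert res.predict(np.array([[1.0, 1.0]]))[0] == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        res = fit_plsr(X, rng.normal(size=8), 2)
        with pytest.raises(ValueError, match="columns"):
            res.predict(rng.normal(size=(2, 5)))


class TestSelectNLv:
    def test_known_intrinsic_dimension(self):
        # noise-free 2-component mixture: at most 2 LVs needed
        rng = np.random.default_rng(7)
        s1, s2 = rng.normal(size=(2, 40))
        frac = rng.uniform(0, 1, size=25)
        X = np.outer(frac, s1) + np.outer(1 - frac, s2)
        y = 100 * frac
        assert select_n_lv(X, y, max_lv=8, seed=0) <= 2

    def test_minimum_verified_by_exhaustive_recomputation(self, rng):
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=30)
        chosen = select_n_lv(X, y, max_lv=6, folds=5, seed=9)
        curve = cv_rmsecv_by_lv(X, y, max_lv=6, folds=5, seed=9)
        assert curve[chosen - 1] <= curve.min() + 1e-14
        # ties broken toward fewer LVs
        assert chosen == int(np.argmin(curve)) + 1

    def test_single_candidate(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        assert select_n_lv(X, y, max_lv=1, seed=0) == 1

    def test_invalid_max_lv(self, rng):
        with pytest.raises(ValueError):
            select_n_lv(rng.normal(size=(5, 2)), rng.normal(size=5), max_lv=0)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        res = fit_plsr(X, y, n_lv=3)
        p = tmp_path / "model.json"
        res.to_json(p)
        again = PLSResults.from_json(p)
        np.testing.assert_array_equal(again.predict(X), res.predict(X))
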