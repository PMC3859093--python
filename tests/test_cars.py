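import numpy as np
import pytest

from powdercal import (
    CARSConfig,
    cv_rmsecv_by_lv,
    edf_retained_fraction,
    run_cars,
)


class TestEDF:
    def test_first_run_retains_everything(self):
        for p, n in [(241, 50), (328, 50), (10, 5)]:
            assert edf_retained_fraction(1, p, n) == pytest.approx(1.0, abs=1e-12)

    def test_last_run_retains_two_of_p(self):
        # closed-form boundary: a·e^(-kN) with a=(p/2)^(1/(N-1)), k=ln(p/2)/(N-1)
        p, n = 241, 50
        a = (p / 2) ** (1 / (n - 1))
        k = np.log(p / 2) / (n - 1)
        direct = a * np.exp(-k * n)
        assert edf_retained_fraction(n, p, n) == pytest.approx(direct, abs=1e-15)
        assert direct == pytest.approx(2 / p, abs=1e-12)

    def test_log_linear_decay(self):
        # log r_i is affine in i: independent log-space evaluation
        p, n = 241, 50
        r25 = edf_retained_fraction(25, p, n)
        assert 2 / p < r25 < 1
        log_interp = np.log(1.0) + (25 - 1) / (n - 1) * (np.log(2 / p) - np.log(1.0))
        assert np.log(r25) == pytest.approx(log_interp, abs=1e-10)

    def test_small_p_rejected(self):
        with pytest.raises(ValueError):
            edf_retained_fraction(1, 1, 50)


def make_informative_data(seed=0, n=60, p=40, k=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:k] = [3.0, -2.0, 1.5]
    y = X @ beta + 0.3 * rng.normal(size=n)
    return X, y


class TestRunCars:
    def test_trace_shapes_match_run_count(self):
        X, y = make_informative_data()
        cfg = CARSConfig(n_runs=20, seed=1)
        res = run_cars(X, y, cfg)
        assert res.retained_counts.shape == (20,)
        assert res.rmsecv_trace.shape == (20,)
        assert res.coefficient_paths.shape == (20, X.shape[1])
        assert res.selected_variables.size >= 2

    def test_retained_counts_non_increasing_and_bounded_by_edf(self):
        X, y = make_informative_data(seed=3)
        cfg = CARSConfig(n_runs=30, seed=3)
        res = run_cars(X, y, cfg)
        counts = res.retained_counts
        assert np.all(np.diff(counts) <= 0)
        p = X.shape[1]
        for i, c in enumerate(counts, start=1):
            assert c <= np.ceil(edf_retained_fraction(i, p, 30) * p)

    def test_eliminated_variables_stay_at_zero(self):
        X, y = make_informative_data(seed=5)
        res = run_cars(X, y, CARSConfig(n_runs=25, seed=5))
        paths = res.coefficient_paths
        for j in range(paths.shape[1]):
            nonzero_runs = np.flatnonzero(paths[:, j])
            if nonzero_runs.size == 0:
                continue
            # once a variable's coefficient drops to zero it never returns
            last = nonzero_runs[-1]
            assert np.all(paths[last + 1:, j] == 0.0)
            dropped = np.flatnonzero(paths[: last + 1, j] == 0.0)
            assert np.all(dropped < nonzero_runs[0])

    def test_best_run_is_argmin_and_selection_consistent(self):
        X, y = make_informative_data(seed=7)
        res = run_cars(X, y, CARSConfig(n_runs=25, seed=7))
        assert res.rmsecv_trace[res.best_run] == res.rmsecv_trace.min()
        # the recorded subset at best_run is exactly the selected set
        recorded = np.flatnonzero(res.coefficient_paths[res.best_run])
        np.testing.assert_array_equal(np.sort(recorded), np.sort(res.selected_variables))

    def test_identical_seed_reproducible(self):
        X, y = make_informative_data(seed=9)
        cfg = CARSConfig(n_runs=15, seed=11)
        r1, r2 = run_cars(X, y, cfg), run_cars(X, y, cfg)
        np.testing.assert_array_equal(r1.rmsecv_trace, r2.rmsecv_trace)
        np.testing.assert_array_equal(r1.selected_variables, r2.selected_variables)
        np.testing.assert_array_equal(r1.coefficient_paths, r2.coefficient_paths)

    def test_planted_signal_recovery_single_seed(self, planted_design_a):
        ds, centers = planted_design_a
        res = run_cars(ds.reflectance, ds.np_percent, CARSConfig(seed=1))
        wl = ds.wavelengths[res.selected_variables]
        for w in wl:
            assert min(abs(w - c) for c in centers) <= 10.0

    def test_removing_planted_variable_raises_rmsecv(self, planted_design_a):
        """Dropping an informative wavelength from the selected subset must
        strictly worsen cross-validated error under measurement noise."""
        from powdercal import NoiseModel, design_spec, generate_design, lnir_grid
        from .conftest import planted_components

        ds, centers = planted_design_a
        res = run_cars(ds.reflectance, ds.np_percent, CARSConfig(seed=1))
        sel = res.selected_variables
        noisy = generate_design(
            design_spec("A", 20),
            components=planted_components(),
            noise=NoiseModel(0.005, 0.0, 0.0, 0.0, seed=4),
            grid=lnir_grid(),
        )
        with_all = cv_rmsecv_by_lv(noisy.reflectance[:, sel], noisy.np_percent,
                                   max_lv=5, seed=0).min()
        # force removal of every selected channel of one planted band
        keep = [j for j in sel if abs(ds.wavelengths[j] - centers[0]) > 10.0]
        assert 2 <= len(keep) < sel.size
        without = cv_rmsecv_by_lv(noisy.reflectance[:, keep], noisy.np_percent,
                                  max_lv=5, seed=0).min()
        assert without > with_all

    def test_degenerate_input_validation(self):
        X, y = make_informative_data()
        with pytest.raises(ValueError):
            run_cars(X[:, :1], y)
        with pytest.raises(ValueError):
            CARSConfig(n_runs=1)
        with pytest.raises(ValueError):
            CARSConfig(mc_ratio=1.5)
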