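import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from pcnir import (PretreatmentSpec, SpectraMatrix, ValidationError,
                   evaluate_regression, fit_plsr, kennard_stone_split,
                   plsr_predict, pretreatment_grid_search, select_n_factors,
                   simulate_dataset)
from pcnir.synth import REGION_CONCENTRATIONS, SyntheticConfig


def random_problem(seed, n=30, p=12, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestFit:
    def test_single_factor_recovers_univariate_signal(self):
        rng = np.random.default_rng(0)
        X = np.zeros((12, 6))
        X[:, 2] = rng.standard_normal(12)
        y = 3.0 * X[:, 2] + 1.0
        model = fit_plsr(X, y, 1)
        np.testing.assert_allclose(plsr_predict(model, X), y, atol=1e-8)

    def test_full_rank_equals_ols(self):
        X, y = random_problem(1, n=8, p=5)
        model = fit_plsr(X, y, 5)
        design = np.column_stack([np.ones(8), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(plsr_predict(model, X), design @ beta,
                                   atol=1e-6)

    def test_agrees_with_sklearn_pls(self):
        X, y = random_problem(2)
        for a in (1, 3, 6):
            mine = plsr_predict(fit_plsr(X, y, a), X)
            ref = PLSRegression(n_components=a, scale=False)
            ref.fit(X, y.reshape(-1, 1))
            np.testing.assert_allclose(mine, ref.predict(X).ravel(), atol=1e-8)

    def test_constant_response_rejected(self):
        X, _ = random_problem(3)
        with pytest.raises(ValidationError, match="constant"):
            fit_plsr(X, np.full(30, 2.0), 2)

    def test_factor_count_bounds(self):
        X, y = random_problem(4, n=10, p=4)
        with pytest.raises(ValidationError):
            fit_plsr(X, y, 5)
        with pytest.raises(ValidationError):
            fit_plsr(X, y, 0)

    def test_shift_equivariance_in_y(self):
        X, y = random_problem(5)
        base = plsr_predict(fit_plsr(X, y, 4), X)
        shifted = plsr_predict(fit_plsr(X, y + 100.0, 4), X)
        np.testing.assert_allclose(shifted, base + 100.0, atol=1e-8)


class TestPredict:
    def test_mean_spectrum_maps_to_mean_response(self):
        X, y = random_problem(6)
        model = fit_plsr(X, y, 3)
        at_mean = plsr_predict(model, np.tile(model.x_mean, (4, 1)))
        np.testing.assert_allclose(at_mean, model.y_mean, atol=1e-10)

    def test_single_row_equals_batch_row(self):
        X, y = random_problem(7)
        model = fit_plsr(X, y, 3)
        batch = plsr_predict(model, X)
        single = plsr_predict(model, X[4:5])
        assert single[0] == pytest.approx(batch[4], abs=1e-12)

    def test_axis_and_width_mismatch_rejected(self):
        X, y = random_problem(8)
        model = fit_plsr(X, y, 2, wavenumbers=np.arange(12.0))
        with pytest.raises(ValidationError, match="columns"):
            plsr_predict(model, np.ones((2, 5)))
        other = SpectraMatrix(np.arange(12.0) + 0.5, X, [f"S{i}" for i in range(30)])
        with pytest.raises(ValidationError, match="axis"):
            plsr_predict(model, other)


class TestFactorSelection:
    def test_noiseless_rank_two_returns_two(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((40, 2))
        X = scores @ rng.standard_normal((2, 30))
        y = scores @ np.array([1.5, -2.0])
        assert select_n_factors(X, y, max_factors=8, k=10, seed=3) == 2

    def test_single_candidate(self):
        X, y = random_problem(9)
        assert select_n_factors(X, y, max_factors=1, k=5, seed=0) == 1

    def test_deterministic_given_seed(self):
        X, y = random_problem(10)
        a1 = select_n_factors(X, y, max_factors=8, k=5, seed=4)
        a2 = select_n_factors(X, y, max_factors=8, k=5, seed=4)
        assert a1 == a2

    def test_too_many_folds_rejected(self):
        X, y = random_problem(11, n=6)
        with pytest.raises(ValidationError):
            select_n_factors(X, y, max_factors=2, k=7)


class TestEvaluation:
    def test_hand_computed_rmsep_and_re(self):
        X, y = random_problem(12, n=10, p=4)
        model = fit_plsr(X, y, 2)
        y_val = np.array([10.0, 20.0])
        yhat = np.array([11.0, 18.0])
        X_val = np.vstack([
            model.x_mean + (t - model.y_mean) / (model.coefficients @
                                                 model.coefficients)
            * model.coefficients for t in yhat])
        ev = evaluate_regression(model, X, y, X_val, y_val)
        assert ev.rmsep == pytest.approx(np.sqrt(5 / 2), abs=1e-8)
        assert ev.re_percent == pytest.approx(10.0, abs=1e-8)

    def test_perfect_predictions(self):
        X, y = random_problem(13, n=10, p=6, noise=0.0)
        model = fit_plsr(X, y, 6)
        ev = evaluate_regression(model, X, y, X, y)
        assert ev.rmsec == pytest.approx(0.0, abs=1e-8)
        assert ev.rmsep == pytest.approx(0.0, abs=1e-8)
        assert ev.r2_cal == pytest.approx(1.0, abs=1e-10)
        assert ev.re_percent == pytest.approx(0.0, abs=1e-6)

    def test_loop_oracle_agreement(self):
        X, y = random_problem(14)
        Xv, yv = random_problem(15, n=9)
        model = fit_plsr(X, y, 4)
        ev = evaluate_regression(model, X, y, Xv, yv)
        yc_hat, yv_hat = plsr_predict(model, X), plsr_predict(model, Xv)
        rmsec = np.sqrt(sum((a - b) ** 2 for a, b in zip(yc_hat, y)) / len(y))
        rmsep = np.sqrt(sum((a - b) ** 2 for a, b in zip(yv_hat, yv)) / len(yv))
        r2p = 1 - (sum((a - b) ** 2 for a, b in zip(yv_hat, yv))
                   / sum((b - np.mean(yv)) ** 2 for b in yv))
        re = 100 * np.mean([abs(a - b) / abs(b) for a, b in zip(yv_hat, yv)])
        assert ev.rmsec == pytest.approx(rmsec, abs=1e-10)
        assert ev.rmsep == pytest.approx(rmsep, abs=1e-10)
        assert ev.r2_pre == pytest.approx(r2p, abs=1e-10)
        assert ev.re_percent == pytest.approx(re, abs=1e-10)

    def test_zero_validation_value_rejected(self):
        X, y = random_problem(16)
        model = fit_plsr(X, y, 2)
        with pytest.raises(ValidationError, match="relative error"):
            evaluate_regression(model, X, y, X[:2], np.array([0.0, 1.0]))


class TestGridSearch:
    def test_single_method_selected(self, small_dataset):
        spectra, table = small_dataset
        split = kennard_stone_split(spectra, ratio=4.0)
        grid = pretreatment_grid_search(spectra, table.response("psc"), split,
                                        [PretreatmentSpec("Raw")], cv_seed=1)
        assert grid.selected == "Raw"
        assert len(grid.table) == 1

    def test_rows_invariant_to_method_order(self, small_dataset):
        spectra, table = small_dataset
        split = kennard_stone_split(spectra, ratio=4.0)
        names = ["Raw", "SNV", "SG-1D"]
        g1 = pretreatment_grid_search(spectra, table.response("wse"), split,
                                      [PretreatmentSpec(n) for n in names],
                                      cv_seed=2)
        g2 = pretreatment_grid_search(spectra, table.response("wse"), split,
                                      [PretreatmentSpec(n) for n in names[::-1]],
                                      cv_seed=2)
        t1 = g1.table.set_index("method").sort_index()
        t2 = g2.table.set_index("method").sort_index()
        np.testing.assert_allclose(t1["rmsep"], t2["rmsep"])
        assert g1.selected == g2.selected

    def test_scatter_correction_beats_raw_under_heavy_scatter(self):
        # few calibration samples cannot spend latent variables on a
        # strong multiplicative scatter, so SNV/MSC pull ahead of Raw
        tight = {k: {r: (m, s * 0.3, lo, hi) for r, (m, s, lo, hi) in v.items()}
                 for k, v in REGION_CONCENTRATIONS.items()}
        cfg = SyntheticConfig(
            seed=7, n_per_region={"YN": 12, "XQ": 8, "DBM": 10},
            scatter_slope_sd=0.3, scatter_offset_sd=0.02, noise_sd=0.002,
            region_effect_amplitude=0.0, region_params=tight)
        spectra, table = simulate_dataset(cfg)
        split = kennard_stone_split(spectra, ratio=4.0)
        grid = pretreatment_grid_search(
            spectra, table.response("wse"), split,
            [PretreatmentSpec(n) for n in ("Raw", "SNV", "MSC")],
            cv_seed=11, k=5, max_factors=3)
        rmsep = grid.table.set_index("method")["rmsep"]
        assert min(rmsep["SNV"], rmsep["MSC"]) < rmsep["Raw"]
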