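"""Cross-validation engine: λ grids, folds, fold fits, λ* selection."""

import logging

import numpy as np
import pytest

from enetfamily.cv import (
    assign_folds,
    extend_lambda_grid,
    fit_alpha,
    fit_fold_path_linear,
    make_lambda_grid,
    select_lambda_star,
    summarize_oob,
)
from enetfamily.quality import make_scorer


class TestLambdaGrid:
    def test_length_order_and_geometry(self, rng):
        x = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        grid = make_lambda_grid(x, y, "linear", 0.5, 3)
        assert len(grid) == 3
        assert np.all(np.diff(grid) < 0)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_lasso_top_of_path_zeroes_single_predictor(self, rng):
        """Closed-form soft-threshold check: with one standardized predictor,
        the lasso coefficient is sign(c)(|c| - λ)+ where c = <x, y>/n, so the
        path top zeroes it while λ_max/2 does not."""
        n = 50
        x = rng.normal(size=(n, 1))
        x = (x - x.mean()) / x.std()
        y = 2.0 * x[:, 0] + rng.normal(scale=0.1, size=n)
        grid = make_lambda_grid(x, y, "linear", 1.0, 5)
        lam_max = grid[0]
        ib = np.ones(n, dtype=bool)
        coefs, _ = fit_fold_path_linear(x, y, ib, 1.0, np.array([lam_max, lam_max / 2]))
        assert coefs[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert abs(coefs[0, 1]) > 0
        # soft-threshold oracle at λ_max/2
        c = float(x[:, 0] @ (y - y.mean())) / n
        expected = np.sign(c) * max(abs(c) - lam_max / 2, 0.0)
        assert coefs[0, 1] == pytest.approx(expected, rel=1e-3)

    def test_categorical_grid_is_positive_descending(self, rng):
        x = rng.normal(size=(30, 6))
        y = rng.integers(0, 3, size=30)
        grid = make_lambda_grid(x, y, "multinomial", 0.4, 10, n_classes=3)
        assert len(grid) == 10 and np.all(grid > 0) and np.all(np.diff(grid) < 0)


class TestExtendGrid:
    def test_symmetric_extension_example(self):
        got = extend_lambda_grid(np.array([1.0, 0.1, 0.01]), 7)
        np.testing.assert_allclose(
            got, [100.0, 10.0, 1.0, 0.1, 0.01, 0.001, 0.0001], rtol=1e-12
        )

    def test_one_point_each_end(self):
        got = extend_lambda_grid(np.array([1.0, 0.5, 0.25]), 5)
        np.testing.assert_allclose(got, [2.0, 1.0, 0.5, 0.25, 0.125])

    def test_odd_surplus_favors_small_lambda_side(self):
        got = extend_lambda_grid(np.array([1.0, 0.1]), 5)
        # 3 extra points: 1 on the large side, 2 on the small side
        np.testing.assert_allclose(got, [10.0, 1.0, 0.1, 0.01, 0.001])

    def test_original_values_preserved_contiguously(self):
        base = np.geomspace(5.0, 0.05, 4)
        got = extend_lambda_grid(base, 10)
        np.testing.assert_allclose(got[3:7], base)

    def test_requires_strictly_larger_target(self):
        with pytest.raises(ValueError):
            extend_lambda_grid(np.array([1.0, 0.1]), 2)


class TestFolds:
    def test_equal_fold_sizes(self):
        folds = assign_folds(None, "linear", 10, n_runs=2, n_folds=5, seed=1)
        for r in range(2):
            assert sorted(np.bincount(folds[r]).tolist()) == [2] * 5

    def test_stratification_binomial(self):
        y = np.array([0] * 6 + [1] * 6)
        folds = assign_folds(y, "binomial", 12, n_runs=3, n_folds=3, seed=2)
        for r in range(3):
            for f in range(3):
                members = y[folds[r] == f]
                assert (members == 0).sum() == 2 and (members == 1).sum() == 2

    def test_reproducible_and_run_distinct(self):
        a = assign_folds(None, "linear", 40, n_runs=4, n_folds=5, seed=9)
        b = assign_folds(None, "linear", 40, n_runs=4, n_folds=5, seed=9)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a[0], a[1])

    def test_small_class_error_names_class(self):
        y = np.array([0] * 10 + [1] * 2)
        with pytest.raises(ValueError, match="n_folds"):
            assign_folds(y, "binomial", 12, n_runs=1, n_folds=5, seed=0)


class TestSelectLambdaStar:
    def test_single_peak_chosen(self):
        lambdas = np.array([1.0, 0.5, 0.25, 0.125])
        qf = np.array([[0.1, 0.2], [0.5, 0.6], [0.3, 0.4], [0.0, 0.1]])
        idx, lam, runs, _ = select_lambda_star(qf, lambdas)
        assert idx == 1 and lam == 0.5
        np.testing.assert_allclose(runs, [0.5, 0.6])

    def test_exact_tie_prefers_larger_lambda(self):
        lambdas = np.array([1.0, 0.5, 0.25])
        qf = np.array([[0.4], [0.4], [0.1]])
        idx, lam, _, _ = select_lambda_star(qf, lambdas)
        assert lam == 1.0

    def test_flat_profile_warns_and_picks_largest(self, caplog):
        lambdas = np.array([1.0, 0.5, 0.25])
        qf = np.full((3, 2), 0.3)
        with caplog.at_level(logging.WARNING):
            idx, lam, _, flat = select_lambda_star(qf, lambdas)
        assert lam == 1.0 and flat
        assert any("extend" in rec.message for rec in caplog.records)

    def test_undefined_lambda_treated_as_worst(self):
        lambdas = np.array([1.0, 0.5, 0.25])
        qf = np.array([[np.nan, 0.9], [0.2, 0.3], [0.1, 0.1]])
        idx, lam, _, _ = select_lambda_star(qf, lambdas)
        assert lam == 0.5

    def test_all_undefined_raises(self):
        with pytest.raises(RuntimeError):
            select_lambda_star(np.full((2, 2), np.nan), np.array([1.0, 0.5]))


def _small_fit(rng, alpha, n_runs=2, p=8, n=40, n_lambda=12):
    x = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[0] = 2.0
    y = x @ beta + rng.normal(scale=0.5, size=n)
    grid = make_lambda_grid(x, y, "linear", alpha, n_lambda)
    folds = assign_folds(None, "linear", n, n_runs=n_runs, n_folds=4, seed=5)
    scorer = make_scorer("linear")
    return x, y, fit_alpha(x, y, "linear", None, alpha, grid, folds, scorer)


class TestFitAlpha:
    def test_every_sample_predicted_once_per_run(self, rng):
        _, _, fit = _small_fit(rng, alpha=0.5)
        assert np.isfinite(fit.oob_predictions).all()

    def test_ridge_selects_every_feature(self, rng):
        _, _, fit = _small_fit(rng, alpha=0.0)
        assert (fit.coefficients != 0).all()

    def test_lasso_keeps_dominant_predictor_drops_noise(self, rng):
        _, _, fit = _small_fit(rng, alpha=1.0)
        coefs = fit.coefficients  # (R, F, 1, p)
        assert (coefs[:, :, 0, 0] != 0).all()
        noise_rate = (coefs[:, :, 0, 1:] != 0).mean()
        assert noise_rate < 0.5

    def test_lambda_star_reproducible(self, rng):
        state = rng.bit_generator.state
        _, _, fit1 = _small_fit(rng, alpha=1.0)
        rng.bit_generator.state = state
        _, _, fit2 = _small_fit(rng, alpha=1.0)
        assert fit1.lambda_star == fit2.lambda_star
        np.testing.assert_array_equal(fit1.qf_model_runs, fit2.qf_model_runs)

    def test_training_never_sees_oob_rows(self, rng):
        """Leakage guard: corrupting the OOB rows must not change the
        coefficients fitted from the in-bag rows."""
        x = rng.normal(size=(30, 5))
        y = x[:, 0] + rng.normal(scale=0.3, size=30)
        ib = np.ones(30, dtype=bool)
        ib[:6] = False
        lam = np.array([0.05])
        coefs_a, _ = fit_fold_path_linear(x, y, ib, 0.8, lam)
        x_corrupt = x.copy()
        x_corrupt[:6] = 1e6
        coefs_b, _ = fit_fold_path_linear(x_corrupt, y, ib, 0.8, lam)
        np.testing.assert_array_equal(coefs_a, coefs_b)


class TestSummarizeOOB:
    def test_linear_single_run_sd_undefined(self, rng):
        _, y, fit = _small_fit(rng, alpha=0.5, n_runs=1)
        s = summarize_oob(fit, y, "linear")
        assert np.isnan(s["pred_sd"]).all()
        assert np.isfinite(s["pred_mean"]).all()

    def test_contingency_row_sums_equal_class_sizes(self, multinomial_results):
        cm = multinomial_results.contingency(0.2)
        y = multinomial_results.model.y
        counts = {c: int(np.sum(y.values == c)) for c in y.classes}
        for c in y.classes:
            assert cm.loc[c].sum() == pytest.approx(counts[c])
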