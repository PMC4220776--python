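"""OLS / log-link GLM / LAD / CLAD estimators against independent oracles."""

import itertools

import numpy as np
import pytest

from utilmap.estimators import (
    CladConfig,
    FittedModel,
    RegressionData,
    bootstrap_vcov,
    fit_clad,
    fit_glm_log,
    fit_lad,
    fit_ols,
    predict_utility,
)
from conftest import random_regression


def intercept_only(y):
    y = np.asarray(y, dtype=float)
    return RegressionData(y=y, X=np.ones((y.size, 1)), labels=("Constant",))


def simple_line(x, y):
    x = np.asarray(x, dtype=float)
    return RegressionData(
        y=np.asarray(y, dtype=float),
        X=np.column_stack([np.ones(x.size), x]),
        labels=("Constant", "slope"),
    )


class TestOls:
    def test_exact_fit_two_points(self):
        model = fit_ols(simple_line([0, 1], [0, 1]), cov_type="HC0")
        assert model.params == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_noiseless_line_perfect_adjusted_r2(self):
        x = np.arange(1.0, 6.0)
        model = fit_ols(simple_line(x, 2 + 3 * x))
        assert model.params == pytest.approx([2.0, 3.0], abs=1e-10)
        assert model.stats["adj_r2"] == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data, _ = random_regression(rng, n=20, k=3)
            beta_oracle = np.linalg.solve(data.X.T @ data.X, data.X.T @ data.y)
            model = fit_ols(data)
            assert model.params == pytest.approx(beta_oracle, abs=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(5)
        data, _ = random_regression(rng, n=60, k=4)
        model = fit_ols(data)
        resid = data.y - data.X @ model.params
        scale = np.abs(data.X).max() * np.abs(data.y).max()
        assert np.abs(data.X.T @ resid).max() < 1e-8 * max(scale, 1.0)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        data = RegressionData(
            y=np.arange(10.0), X=X, labels=("Constant", "x", "x_twice")
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(data)

    def test_hc1_vcov_matches_hand_sandwich(self):
        rng = np.random.default_rng(3)
        data, _ = random_regression(rng, n=40, k=3)
        model = fit_ols(data)
        e = data.y - data.X @ model.params
        X = data.X
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ (X * e[:, None] ** 2)
        n, k = X.shape
        vcov = n / (n - k) * bread @ meat @ bread
        assert model.vcov == pytest.approx(vcov, rel=1e-8)


class TestGlmLog:
    def test_intercept_only_is_log_mean(self):
        model = fit_glm_log(intercept_only([3.0, 3.0, 3.0, 3.0]))
        assert model.params[0] == pytest.approx(np.log(3.0), abs=1e-8)

    def test_noiseless_exponential_recovery(self):
        x = np.arange(0.0, 101.0, 10.0)
        y = np.exp(0.5 + 0.01 * x)
        model = fit_glm_log(simple_line(x, y))
        assert model.params == pytest.approx([0.5, 0.01], abs=1e-6)

    def test_gaussian_family_matches_nls_oracle(self):
        from scipy.optimize import least_squares

        rng = np.random.default_rng(21)
        x = rng.uniform(0, 100, 60)
        y = np.exp(0.3 + 0.005 * x) + 0.05 * rng.normal(size=60)
        data = simple_line(x, y)
        model = fit_glm_log(data)
        nls = least_squares(
            lambda b: np.exp(data.X @ b) - data.y, x0=[0.0, 0.0], xtol=1e-14,
            ftol=1e-14, gtol=1e-14,
        )
        assert model.params == pytest.approx(nls.x, abs=1e-6)

    def test_gamma_rejects_nonpositive_response(self):
        with pytest.raises(ValueError, match="positive"):
            fit_glm_log(intercept_only([0.5, 0.0, 0.7]), family="gamma")

    def test_prediction_is_exponential_of_linear_predictor(self):
        model = FittedModel(
            method="GLM", labels=("Constant", "x"), params=[0.0, 0.0],
            vcov=None, stats={}, link="log",
        )
        assert predict_utility(model, [[1.0, 5.0]]) == pytest.approx([1.0])


class TestLad:
    def test_intercept_only_is_median(self):
        beta = fit_lad(intercept_only([0.0, 1.0, 5.0]))
        assert beta[0] == pytest.approx(1.0, abs=1e-8)

    def test_even_n_returns_deterministic_minimizer(self):
        data = intercept_only([0.0, 2.0])
        beta1 = fit_lad(data)
        beta2 = fit_lad(data)
        assert 0.0 - 1e-9 <= beta1[0] <= 2.0 + 1e-9  # any point minimises
        assert beta1[0] == beta2[0]

    def test_objective_matches_basic_solution_oracle(self):
        # an LAD optimum interpolates >= 2 points: enumerate all pairs
        rng = np.random.default_rng(17)
        x = rng.normal(size=8)
        y = 0.5 + 1.5 * x + rng.laplace(scale=0.5, size=8)
        data = simple_line(x, y)
        beta = fit_lad(data)
        obj = np.abs(y - data.X @ beta).sum()
        best = np.inf
        for i, j in itertools.combinations(range(8), 2):
            A = data.X[[i, j]]
            if abs(np.linalg.det(A)) < 1e-12:
                continue
            cand = np.linalg.solve(A, y[[i, j]])
            best = min(best, np.abs(y - data.X @ cand).sum())
        assert obj == pytest.approx(best, abs=1e-8)

    def test_matches_statsmodels_median_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        y = 1.0 - 0.7 * x + rng.laplace(scale=0.3, size=80)
        data = simple_line(x, y)
        beta = fit_lad(data)
        qr = sm.QuantReg(y, data.X).fit(q=0.5)
        obj_lp = np.abs(y - data.X @ beta).sum()
        obj_qr = np.abs(y - data.X @ qr.params).sum()
        assert obj_lp <= obj_qr + 1e-6


def censored_instance(rng, n=12, censor_frac=0.3):
    """Two-parameter instance with a given share of responses at ceiling 1."""
    x = rng.uniform(0, 1, n)
    y_lat = 0.4 + 0.9 * x + rng.laplace(scale=0.15, size=n)
    cut = np.quantile(y_lat, 1 - censor_frac)
    # shift so the top censor_frac of latent values sits at the ceiling
    y = np.minimum(y_lat - (cut - 1.0), 1.0)
    return simple_line(x, y)


class TestClad:
    def test_intercept_only_median_below_ceiling(self):
        data = intercept_only([0.6, 0.8, 1.0])
        model = fit_clad(data, CladConfig(bootstrap_reps=0), compute_se=False)
        assert model.params[0] == pytest.approx(0.8, abs=1e-8)

    def test_equals_lad_when_censoring_inactive(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.2 + 0.1 * x + 0.05 * rng.laplace(size=30)
        y = np.minimum(y, 1.0)  # nothing near the ceiling
        data = simple_line(x, y)
        model = fit_clad(data, CladConfig(bootstrap_reps=0), compute_se=False)
        assert model.params == pytest.approx(fit_lad(data), abs=1e-8)
        assert model.stats["n_retained"] == 30

    def test_objective_not_worse_than_plain_lad(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            data = censored_instance(rng, n=25, censor_frac=0.25)
            model = fit_clad(data, CladConfig(bootstrap_reps=0),
                             compute_se=False)
            beta_lad = fit_lad(data)
            s_lad = np.sum(np.abs(data.y - np.minimum(data.X @ beta_lad, 1.0)))
            assert model.stats["objective"] <= s_lad + 1e-9

    def test_objective_matches_grid_search_oracle(self):
        rng = np.random.default_rng(99)
        data = censored_instance(rng, n=12, censor_frac=0.3)
        model = fit_clad(data, CladConfig(bootstrap_reps=0), compute_se=False)
        center = fit_lad(data)
        grid = np.linspace(-0.5, 0.5, 81)
        best = np.inf
        for da in grid:
            for db in grid:
                beta = center + [da, db]
                s = np.sum(np.abs(data.y - np.minimum(data.X @ beta, 1.0)))
                best = min(best, s)
        assert model.stats["objective"] <= best + 1e-6

    def test_response_above_ceiling_rejected(self):
        with pytest.raises(ValueError, match="ceiling"):
            fit_clad(intercept_only([0.5, 1.2]), CladConfig(bootstrap_reps=0),
                     compute_se=False)

    def test_ceiling_applied_to_predictions(self):
        model = FittedModel(
            method="CLAD", labels=("Constant", "x"), params=[1.0, 0.1],
            vcov=None, stats={}, ceiling=1.0,
        )
        assert predict_utility(model, [[1.0, 2.0]]) == pytest.approx([1.0])


class TestBootstrap:
    def test_degenerate_data_gives_zero_se(self):
        data = intercept_only([0.7, 0.7, 0.7, 0.7])
        boot = bootstrap_vcov(data, lambda d: fit_lad(d), n_reps=2, seed=0)
        assert boot.se == pytest.approx([0.0], abs=1e-12)

    def test_se_of_mean_close_to_analytic(self):
        rng = np.random.default_rng(42)
        y = rng.normal(0.5, 0.2, size=100)
        data = intercept_only(y)
        boot = bootstrap_vcov(
            data,
            lambda d: np.array([d.y.mean()]),
            n_reps=500,
            seed=1,
        )
        analytic = y.std(ddof=1) / np.sqrt(100)
        assert abs(boot.se[0] - analytic) / analytic < 0.15

    def test_same_seed_identical_vcov(self):
        rng = np.random.default_rng(0)
        data, _ = random_regression(rng, n=30, k=2)
        b1 = bootstrap_vcov(data, lambda d: fit_lad(d), n_reps=25, seed=9)
        b2 = bootstrap_vcov(data, lambda d: fit_lad(d), n_reps=25, seed=9)
        assert np.array_equal(b1.vcov, b2.vcov)

    def test_majority_failures_abort(self):
        data = intercept_only([0.1, 0.2, 0.3])

        def failing_fit(d):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="bootstrap failed"):
            bootstrap_vcov(data, failing_fit, n_reps=10, seed=0)


class TestPredictAndSerialize:
    def test_published_style_arithmetic(self):
        model = FittedModel(
            method="OLS", labels=("Constant", "FACT-G"),
            params=[0.345, 0.006], vcov=None, stats={},
        )
        assert predict_utility(model, [[1.0, 80.0]]) == pytest.approx([0.825])

    def test_label_mismatch_rejected(self):
        model = FittedModel(
            method="OLS", labels=("Constant", "x"), params=[0.0, 1.0],
            vcov=None, stats={},
        )
        with pytest.raises(ValueError, match="labels"):
            predict_utility(model, [[1.0, 2.0]], labels=("Constant", "y"))

    def test_json_roundtrip_predicts_bit_identically(self):
        rng = np.random.default_rng(12)
        data, _ = random_regression(rng, n=50, k=3)
        model = fit_ols(data)
        clone = FittedModel.from_json(model.to_json())
        assert np.array_equal(
            predict_utility(model, data.X), predict_utility(clone, data.X)
        )

    def test_clamp_applied_last(self):
        model = FittedModel(
            method="OLS", labels=("Constant",), params=[1.4], vcov=None,
            stats={},
        )
        out = predict_utility(model, [[1.0]], clamp=(0.0, 1.0))
        assert out == pytest.approx([1.0])
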