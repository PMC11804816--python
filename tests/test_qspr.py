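"""Regression fitting, F/p statistics and significance screening."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from eccqspr.dataset import load_paper_indices, load_properties
from eccqspr.qspr import (
    RegressionFit,
    correlation_table,
    f_statistic,
    fit_all,
    fit_linear,
    fit_quadratic,
    p_from_f,
    significance,
)
from eccqspr.synthetic import RegressionGenSpec, random_regression_data


def f_density(x, d1, d2):
    """F(d1, d2) density written from the gamma-function definition
    (independent of scipy.stats.f)."""
    c = (d1 / d2) ** (d1 / 2) / special.beta(d1 / 2, d2 / 2)
    return c * x ** (d1 / 2 - 1) * (1 + d1 * x / d2) ** (-(d1 + d2) / 2)


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.alpha == pytest.approx(1.0)
        assert fit.beta == pytest.approx(2.0)
        assert fit.r2 == 1.0 and fit.r == 1.0
        assert math.isinf(fit.f) and fit.p == 0.0

    def test_r_equals_abs_pearson_by_covariance_formula(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 13)
        y = rng.normal(size=13)  # independent of x
        fit = fit_linear(x, y)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        pearson = sxy / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert fit.r == pytest.approx(abs(pearson))
        assert fit.r2 == pytest.approx(pearson ** 2)

    def test_f_equals_slope_t_squared(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 20)
        y = 3.0 - 0.5 * x + rng.normal(size=20)
        fit = fit_linear(x, y)
        # classic slope t statistic
        resid_var = (1 - fit.r2) * ((y - y.mean()) ** 2).sum() / (len(x) - 2)
        se_beta = math.sqrt(resid_var / ((x - x.mean()) ** 2).sum())
        t = fit.beta / se_beta
        assert fit.f == pytest.approx(t ** 2)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 50)
        y = 1 + x + rng.normal(size=50)
        fit = fit_quadratic(x, y)
        resid = y - (fit.alpha + fit.beta * x + fit.gamma * x * x)
        for col in (np.ones_like(x), x, x * x):
            assert abs(resid @ col) < 1e-8 * np.abs(y).sum()

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.ones(10), np.arange(10.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.arange(5.0), np.arange(6.0))


class TestFitQuadratic:
    def test_exact_parabola_recovered(self):
        x = np.linspace(-3, 3, 12)
        fit = fit_quadratic(x, x ** 2)
        assert fit.alpha == pytest.approx(0.0, abs=1e-10)
        assert fit.beta == pytest.approx(0.0, abs=1e-10)
        assert fit.gamma == pytest.approx(1.0)
        assert fit.r == 1.0

    def test_nests_linear_model(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 30)
        y = rng.normal(size=30)
        assert fit_quadratic(x, y).r2 >= fit_linear(x, y).r2

    def test_too_few_distinct_x_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic(np.array([1.0, 1.0, 2.0, 2.0]), np.arange(4.0))

    def test_parameter_recovery_within_three_se(self):
        """Quadratic OLS on noisy synthetic data recovers the truth."""
        spec = RegressionGenSpec(n=200, alpha=2.0, beta=-1.5, gamma=0.3,
                                 noise_sd=1.0, seed=2024)
        x, y = random_regression_data(spec)
        fit = fit_quadratic(x, y)
        X = np.column_stack([np.ones_like(x), x, x * x])
        resid = y - X @ np.array([fit.alpha, fit.beta, fit.gamma])
        s2 = resid @ resid / (len(x) - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        for est, truth, s in zip((fit.alpha, fit.beta, fit.gamma),
                                 (spec.alpha, spec.beta, spec.gamma), se):
            assert abs(est - truth) <= 3 * s


class TestFStatistic:
    @pytest.mark.parametrize("r2,n,k,expected", [
        (0.4359, 13, 1, 8.50),     # linear fit of complexity on GA4
        (0.4667, 13, 2, 4.38),     # quadratic counterpart
        (0.0, 13, 1, 0.0),
    ])
    def test_values(self, r2, n, k, expected):
        assert f_statistic(r2, n, k) == pytest.approx(expected, abs=0.005)

    def test_perfect_fit_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 13, 1)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.5, 2, 1)


class TestPFromF:
    def test_zero_f_gives_one(self):
        assert p_from_f(0.0, 1, 11) == 1.0

    @pytest.mark.parametrize("f,k,d", [(8.498, 1, 11), (3.0, 2, 10), (4.376, 2, 10)])
    def test_matches_quadrature_of_f_density(self, f, k, d):
        oracle, err = integrate.quad(f_density, f, np.inf, args=(k, d))
        assert p_from_f(f, k, d) == pytest.approx(oracle, abs=max(1e-9, 10 * err))

    def test_printed_p_for_complexity_fit(self):
        assert p_from_f(8.498, 1, 11) == pytest.approx(0.01406, abs=5e-5)


class TestSignificance:
    def test_flag_boundaries_are_strict_where_stated(self):
        fit = RegressionFit(kind="linear", alpha=0, beta=1, gamma=None,
                            r=0.7, r2=0.49, f=2.5, p=0.05, n=13)
        flags = significance(fit)
        assert flags == {"p_ok": True, "f_ok": False, "r_ok": False,
                         "overall": False}

    def test_perfect_fit_r_ok(self):
        x = np.arange(10.0)
        assert fit_linear(x, 2 * x + 1).flags["r_ok"]

    def test_complexity_ga4_flags(self):
        ind, props = load_paper_indices(), load_properties()
        flags = fit_linear(ind["ga4"], props["C"]).flags
        assert flags["p_ok"] and flags["f_ok"] and not flags["r_ok"]


class TestTables:
    def test_fit_all_produces_full_grid(self):
        ind, props = load_paper_indices(), load_properties()
        recs = fit_all(ind, props)
        assert len(recs) == 2 * 8 * 8
        assert all("error" not in r for r in recs)

    def test_correlation_table_layout_and_self_regression(self):
        ind, props = load_paper_indices(), load_properties()
        table = correlation_table(ind, props, "linear")
        assert table.shape == (8, 8)
        assert ((0 <= table) & (table <= 1)).all().all()
        # a column regressed on itself correlates perfectly
        fake_props = props.copy()
        fake_props["C"] = ind["ga4"]
        assert correlation_table(ind, fake_props, "linear").loc["ga4", "C"] == 1.0

    def test_quadratic_entrywise_at_least_linear(self):
        ind, props = load_paper_indices(), load_properties()
        lin = correlation_table(ind, props, "linear", ndigits=None)
        quad = correlation_table(ind, props, "quadratic", ndigits=None)
        assert (quad.to_numpy() >= lin.to_numpy() - 1e-12).all()

    def test_id_mismatch_rejected(self):
        ind, props = load_paper_indices(), load_properties()
        with pytest.raises(ValueError):
            fit_all(ind.drop(index="a"), props)
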