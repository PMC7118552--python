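"""Random-intercept logistic model: oracle checks, limits, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from exadiary.errors import SeparationError, SingularDesignError, ValidationError
from exadiary.model import (
    chi_square_test,
    fit_random_intercept_logistic,
    marginal_loglik,
    univariate_screen,
)


def simulate_clustered(rng, n_pat, events_per_pat, beta, sigma):
    """Two-level Bernoulli data with a single standard-normal covariate."""
    n = n_pat * events_per_pat
    groups = np.repeat(np.arange(n_pat), events_per_pat)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    u = rng.normal(0.0, sigma, n_pat)
    y = (rng.random(n) < expit(X @ beta + u[groups])).astype(float)
    ids = [f"P{g}" for g in groups]
    return y, pd.DataFrame({"x": x}), ids, X, groups


def trapezoid_loglik(beta, sigma, y, X, groups, span=10.0, n_grid=40001):
    """Brute-force marginal log-likelihood by fine-grid integration."""
    grid = np.linspace(-span * sigma, span * sigma, n_grid)
    total = 0.0
    for g in np.unique(groups):
        m = groups == g
        lp = X[m] @ beta
        ll = (
            y[m][:, None] * (lp[:, None] + grid[None, :])
            - np.logaddexp(0.0, lp[:, None] + grid[None, :])
        ).sum(axis=0)
        density = stats.norm.pdf(grid, scale=sigma)
        total += np.log(np.trapezoid(np.exp(ll) * density, grid))
    return total


class TestMarginalLikelihood:
    def test_quadrature_matches_numerical_integration(self, rng):
        y, pred, ids, X, groups = simulate_clustered(
            rng, n_pat=5, events_per_pat=4, beta=np.array([-0.3, 0.8]), sigma=0.9
        )
        beta = np.array([-0.2, 0.6])
        for sigma in (0.3, 0.9, 2.0):
            ll_quad = marginal_loglik(beta, sigma, y, X, groups, 21)
            ll_trap = trapezoid_loglik(beta, sigma, y, X, groups)
            assert ll_quad == pytest.approx(ll_trap, abs=1e-6)

    def test_node_count_converged(self, rng):
        y, pred, ids, X, groups = simulate_clustered(
            rng, n_pat=8, events_per_pat=5, beta=np.array([0.2, -0.5]), sigma=1.2
        )
        beta = np.array([0.1, -0.4])
        ll21 = marginal_loglik(beta, 1.2, y, X, groups, 21)
        ll51 = marginal_loglik(beta, 1.2, y, X, groups, 51)
        assert abs(ll21 - ll51) < 1e-4


class TestFit:
    def test_degenerate_variance_matches_plain_logit(self, rng):
        y, pred, ids, X, groups = simulate_clustered(
            rng, n_pat=400, events_per_pat=25, beta=np.array([-0.5, 0.7]), sigma=0.0
        )
        fit = fit_random_intercept_logistic(y, pred, ids)
        plain = sm.Logit(y, X).fit(disp=0)
        assert fit.random_intercept_sd < 0.05
        assert np.allclose(fit.coefficients.values, plain.params, atol=1e-3)

    def test_likelihood_at_optimum_beats_truth(self, rng):
        beta_true = np.array([-0.4, 0.6])
        y, pred, ids, X, groups = simulate_clustered(
            rng, n_pat=60, events_per_pat=5, beta=beta_true, sigma=0.8
        )
        fit = fit_random_intercept_logistic(y, pred, ids)
        ll_true = marginal_loglik(beta_true, 0.8, y, X, groups, 21)
        assert fit.log_likelihood >= ll_true - 1e-8

    def test_or_and_ci_transform_consistently(self, rng):
        y, pred, ids, *_ = simulate_clustered(
            rng, n_pat=50, events_per_pat=4, beta=np.array([0.1, 0.5]), sigma=0.6
        )
        fit = fit_random_intercept_logistic(y, pred, ids)
        assert np.allclose(fit.odds_ratios.values, np.exp(fit.coefficients.values))
        assert np.allclose(
            fit.or_ci_95.values, np.exp(fit.wald_ci_95.values)
        )
        assert (fit.wald_ci_95["low"] <= fit.coefficients).all()
        assert (fit.coefficients <= fit.wald_ci_95["high"]).all()

    def test_complete_separation_raises_diagnostic(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0] * 4)
        y = (x > 0).astype(float)
        ids = [f"P{i % 6}" for i in range(len(x))]
        with pytest.raises(SeparationError):
            fit_random_intercept_logistic(y, pd.DataFrame({"x": x}), ids)

    def test_constant_outcome_raises(self):
        with pytest.raises(SeparationError):
            fit_random_intercept_logistic(
                np.ones(10), pd.DataFrame({"x": np.arange(10.0)}),
                ["P1"] * 5 + ["P2"] * 5,
            )

    def test_singular_design_names_columns(self, rng):
        y, pred, ids, *_ = simulate_clustered(
            rng, n_pat=20, events_per_pat=4, beta=np.array([0.0, 0.3]), sigma=0.5
        )
        pred["x_copy"] = pred["x"] * 2.0
        with pytest.raises(SingularDesignError) as err:
            fit_random_intercept_logistic(y, pred, ids)
        assert "x" in err.value.columns and "x_copy" in err.value.columns

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValidationError):
            fit_random_intercept_logistic(
                np.array([0.0, 0.5, 1.0, 0.0]),
                pd.DataFrame({"x": np.arange(4.0)}),
                ["P1", "P1", "P2", "P2"],
            )


class TestUnivariateScreen:
    def test_informative_predictor_selected(self, rng):
        y, pred, ids, *_ = simulate_clustered(
            rng, n_pat=80, events_per_pat=5, beta=np.array([0.0, 1.0]), sigma=0.5
        )
        pred["noise"] = rng.normal(size=len(pred))
        table = univariate_screen(y, pred, ids)
        t = table.set_index("predictor")
        assert bool(t.loc["x", "selected"])
        assert t.loc["x", "or_low"] > 1.0

    def test_empty_candidate_list_gives_empty_table(self, rng):
        y, pred, ids, *_ = simulate_clustered(
            rng, n_pat=10, events_per_pat=3, beta=np.array([0.0, 0.2]), sigma=0.3
        )
        table = univariate_screen(y, pred[[]], ids)
        assert table.empty

    def test_failures_recorded_not_fatal(self, rng):
        y, pred, ids, *_ = simulate_clustered(
            rng, n_pat=30, events_per_pat=4, beta=np.array([0.0, 0.4]), sigma=0.5
        )
        pred["constant"] = 1.0  # collinear with the intercept
        table = univariate_screen(y, pred, ids).set_index("predictor")
        assert table.loc["constant", "error"] != ""
        assert not bool(table.loc["constant", "selected"])
        assert table.loc["x", "error"] == ""


class TestChiSquare:
    def test_proportional_table_has_zero_statistic(self):
        res = chi_square_test([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        res = chi_square_test([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20.0 / 3.0, abs=1e-9)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_test([[10, 0, 5], [20, 0, 7]])

    def test_df_for_2x4(self):
        assert chi_square_test([[5, 6, 7, 8], [8, 7, 6, 5]]).df == 3
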