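"""Two-level logistic regression for the probability of reporting an event.

Exacerbation events (level 1) are nested in patients (level 2).  The
model for event *j* of patient *i* is

    logit P(y_ij = 1 | u_i) = x_ij' beta + u_i,      u_i ~ N(0, sigma^2)

with a patient-level random intercept ``u_i`` absorbing between-patient
heterogeneity in the propensity to seek care.  The marginal likelihood
integrates ``u_i`` out of each patient's contribution; the integral is
evaluated by adaptive Gauss-Hermite quadrature (the integrand is
re-centred at its per-patient mode with matched curvature before the
Hermite rule is applied, which keeps the rule accurate for patients with
many events).  Maximisation is over ``(beta, log sigma)``; Wald
intervals come from the inverse observed information, and odds ratios
are ``exp(beta)`` with CI limits transformed the same way.

Also provided: univariate screening of candidate predictors (each via a
single-predictor two-level fit, selected at p < .10) and a plain Pearson
chi-square test for contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm
from statsmodels.tools import numdiff

from .errors import SeparationError, SingularDesignError, ValidationError

DEFAULT_QUADRATURE_NODES = 21
SCREENING_ALPHA = 0.10

_SIGMA_FLOOR = 1e-5
_SIGMA_CEIL = 50.0
_SEPARATION_COEF_LIMIT = 12.0


def _design(predictors: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(predictors))] + [
        np.asarray(predictors[c], dtype=float) for c in predictors.columns
    ])
    names = ["intercept"] + list(predictors.columns)
    if not np.isfinite(X).all():
        raise ValidationError("predictors must be finite")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the near-null space
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[np.abs(s) < np.max(s) * 1e-10 * max(X.shape)]
        if null.size == 0:
            null = vt[-(X.shape[1] - rank):]
        involved = sorted(
            {names[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]}
        )
        raise SingularDesignError(involved)
    return X, names


def _group_index(patient_ids) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(pd.Series(list(patient_ids)))
    return codes.astype(np.intp), len(uniques)


def marginal_loglik(
    beta: np.ndarray,
    sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = DEFAULT_QUADRATURE_NODES,
) -> float:
    """Marginal log-likelihood with the random intercept integrated out.

    Exposed separately so the quadrature can be validated against
    brute-force numerical integration on small fixtures.
    """
    n_pat = int(groups.max()) + 1
    eta = X @ beta
    sigma = float(sigma)
    inv_var = 1.0 / sigma**2

    # per-patient mode of the integrand (penalised Newton, vectorised)
    u = np.zeros(n_pat)
    for _ in range(100):
        lp = eta + u[groups]
        p = special.expit(lp)
        g = np.bincount(groups, weights=y - p, minlength=n_pat) - u * inv_var
        h = -np.bincount(groups, weights=p * (1.0 - p), minlength=n_pat) - inv_var
        step = g / h
        u -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    tau = 1.0 / np.sqrt(-h)

    z, w = special.roots_hermite(n_nodes)
    log_w = np.log(w) + z**2

    # node grid per patient: u_ik = u_i + sqrt(2) tau_i z_k
    U = u[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    lp = eta[:, None] + U[groups, :]
    # Bernoulli log-likelihood summed within patient, per node
    ll_obs = y[:, None] * lp - np.logaddexp(0.0, lp)
    ll_pat = np.zeros((n_pat, n_nodes))
    np.add.at(ll_pat, groups, ll_obs)
    ll_pat += stats.norm.logpdf(U, scale=sigma)
    log_int = (
        np.log(np.sqrt(2.0) * tau)
        + special.logsumexp(log_w[None, :] + ll_pat, axis=1)
    )
    return float(np.sum(log_int))


@dataclass
class ReportingModelFit:
    """Fitted two-level logistic model."""

    coefficients: pd.Series
    odds_ratios: pd.Series
    wald_ci_95: pd.DataFrame  # columns: low, high (log-odds scale)
    or_ci_95: pd.DataFrame  # columns: low, high (odds-ratio scale)
    std_errors: pd.Series
    p_values: pd.Series
    random_intercept_sd: float
    n_events: int
    n_patients: int
    converged: bool
    log_likelihood: float
    quadrature_nodes: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "odds_ratios": self.odds_ratios.to_dict(),
            "wald_ci_95": {k: list(v) for k, v in self.wald_ci_95.iterrows()},
            "or_ci_95": {k: list(v) for k, v in self.or_ci_95.iterrows()},
            "std_errors": self.std_errors.to_dict(),
            "p_values": self.p_values.to_dict(),
            "random_intercept_sd": self.random_intercept_sd,
            "n_events": self.n_events,
            "n_patients": self.n_patients,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "quadrature_nodes": self.quadrature_nodes,
        }


def _check_separation(y: np.ndarray, X: np.ndarray, names: list[str]) -> np.ndarray:
    """Start values from an ordinary logistic fit, with a separation guard."""
    if y.min() == y.max():
        raise SeparationError("outcome is constant; the model is not identifiable")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(f"ordinary logistic start fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.isfinite(params).all() or np.max(np.abs(params[1:]), initial=0.0) > _SEPARATION_COEF_LIMIT:
        worst = names[int(np.argmax(np.abs(params)))]
        raise SeparationError(
            f"complete or quasi-complete separation suspected (runaway coefficient on {worst!r})"
        )
    return params


def fit_random_intercept_logistic(
    outcome,
    predictors: pd.DataFrame,
    patient_ids,
    quadrature_nodes: int = DEFAULT_QUADRATURE_NODES,
) -> ReportingModelFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Parameters
    ----------
    outcome : array-like of 0/1
        Per-event reported flag.
    predictors : DataFrame
        Per-event covariates; an intercept column is added automatically.
    patient_ids : array-like
        Per-event patient identifiers defining the level-2 grouping.
    quadrature_nodes : int
        Number of adaptive Gauss-Hermite nodes.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcome must be binary 0/1")
    if len(y) != len(predictors):
        raise ValidationError("outcome and predictors must have equal length")
    X, names = _design(predictors)
    groups, n_pat = _group_index(patient_ids)
    if len(groups) != len(y):
        raise ValidationError("patient_ids and outcome must have equal length")
    if n_pat < 2:
        raise ValidationError("need events from at least 2 patients")

    start_beta = _check_separation(y, X, names)
    k = X.shape[1]

    def nll(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:k], theta[k]
        return -marginal_loglik(
            beta, float(np.exp(log_sigma)), y, X, groups, quadrature_nodes
        )

    theta0 = np.append(start_beta, np.log(0.5))
    bounds = [(None, None)] * k + [(np.log(_SIGMA_FLOOR), np.log(_SIGMA_CEIL))]
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta_hat = res.x[:k]
    sigma_hat = float(np.exp(res.x[k]))
    loglik = -float(res.fun)

    # observed information for beta (sigma profiled at its estimate when
    # it sits on the boundary, joint otherwise)
    at_floor = res.x[k] <= np.log(_SIGMA_FLOOR) + 1e-8
    if at_floor:
        def nll_beta(b):
            return -marginal_loglik(b, sigma_hat, y, X, groups, quadrature_nodes)

        hess = numdiff.approx_hess(beta_hat, nll_beta)
        cov = np.linalg.inv(hess)
    else:
        hess = numdiff.approx_hess(res.x, nll)
        cov_full = np.linalg.inv(hess)
        cov = cov_full[:k, :k]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    zcrit = stats.norm.ppf(0.975)
    lo, hi = beta_hat - zcrit * se, beta_hat + zcrit * se
    zstat = np.divide(beta_hat, se, out=np.zeros_like(beta_hat), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    idx = pd.Index(names, name="predictor")
    return ReportingModelFit(
        coefficients=pd.Series(beta_hat, index=idx),
        odds_ratios=pd.Series(np.exp(beta_hat), index=idx),
        wald_ci_95=pd.DataFrame({"low": lo, "high": hi}, index=idx),
        or_ci_95=pd.DataFrame({"low": np.exp(lo), "high": np.exp(hi)}, index=idx),
        std_errors=pd.Series(se, index=idx),
        p_values=pd.Series(pvals, index=idx),
        random_intercept_sd=sigma_hat,
        n_events=len(y),
        n_patients=n_pat,
        converged=bool(res.success),
        log_likelihood=loglik,
        quadrature_nodes=quadrature_nodes,
        diagnostics={"optimizer_message": str(res.message), "n_iter": int(res.nit),
                     "sigma_at_floor": bool(at_floor)},
    )


def univariate_screen(
    outcome,
    candidates: pd.DataFrame,
    patient_ids,
    alpha: float = SCREENING_ALPHA,
    quadrature_nodes: int = DEFAULT_QUADRATURE_NODES,
) -> pd.DataFrame:
    """Single-predictor two-level fits with a p < alpha selection flag.

    One row per candidate with the crude odds ratio, 95% CI and p-value;
    fit failures are recorded per predictor, never fatal.
    """
    rows = []
    for col in candidates.columns:
        try:
            fit = fit_random_intercept_logistic(
                outcome, candidates[[col]], patient_ids, quadrature_nodes
            )
            rows.append(
                {
                    "predictor": col,
                    "odds_ratio": fit.odds_ratios[col],
                    "or_low": fit.or_ci_95.loc[col, "low"],
                    "or_high": fit.or_ci_95.loc[col, "high"],
                    "p_value": fit.p_values[col],
                    "selected": bool(fit.p_values[col] < alpha),
                    "error": "",
                }
            )
        except (SeparationError, SingularDesignError, ValidationError) as exc:
            rows.append(
                {
                    "predictor": col,
                    "odds_ratio": np.nan,
                    "or_low": np.nan,
                    "or_high": np.nan,
                    "p_value": np.nan,
                    "selected": False,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows, columns=[
        "predictor", "odds_ratio", "or_low", "or_high", "p_value", "selected", "error",
    ])


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def chi_square_test(table) -> Chi2Result:
    """Pearson chi-square without continuity correction.

    ``table`` is an r x k array of non-negative integer counts; any zero
    row or column margin is a validation error.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return Chi2Result(float(stat), int(df), float(p))
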