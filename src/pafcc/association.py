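"""Exposure-disease association estimators for case-control data.

Three estimation routes, matching how such studies are typically analyzed:

* ``corrected_or_woolf`` — contingency-table odds ratio with a 0.5
  continuity correction added to all four cells and a Woolf (log-scale Wald)
  interval, used for descriptive feature comparisons where zero cells occur.
* ``fit_logistic`` — maximum-likelihood logistic regression via iteratively
  reweighted least squares (IRLS), with both the model-based (inverse
  observed information) and robust sandwich covariance.
* ``fit_logistic_firth`` — Firth's penalized logistic regression, maximizing
  l(b) + 0.5*log|I(b)|, which keeps coefficients finite under complete or
  quasi-complete separation (e.g. a zero exposed-control cell).

Risk-factor inference is one-sided in the risk-increasing direction: the
reported interval is [exp(b - z90*SE), +inf) — the lower bound of a
two-sided 90% Wald CI — with an upper-tail p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .cohort import CodedDataset, TwoByTwoTable

Z_TWO_SIDED_95 = 1.959964
Z_ONE_SIDED_95 = 1.644854  # = two-sided 90% quantile

# IRLS / Firth iteration controls
MAX_ITER = 100
COEF_TOL = 1e-10
DEV_TOL = 1e-12
SEPARATION_BETA = 15.0  # |b| beyond this during unpenalized IRLS flags separation
SEPARATION_RCOND = 1e-12


class SeparationError(RuntimeError):
    """Unpenalized fit hit (quasi-)complete separation; use the Firth penalty."""


class ConvergenceError(RuntimeError):
    """The optimizer did not converge; no inference is available."""


@dataclass(frozen=True)
class ORResult:
    """An odds ratio with its interval, p-value and provenance."""

    term: str
    or_point: float
    ci_low: float
    ci_high: float  # +inf for one-sided results
    p_value: float
    sidedness: str  # one_sided | two_sided
    method: str  # corrected_woolf | logistic_wald | firth_wald
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")
        if self.sidedness == "one_sided" and not math.isinf(self.ci_high):
            raise ValueError("one-sided results have an infinite upper bound")


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, ordered covariate list, penalty, optional interaction pairs."""

    covariates: tuple[str, ...]
    outcome: str = "status"
    penalty: str = "none"  # none | firth
    interaction_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates must be distinct")
        if self.penalty not in ("none", "firth"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        for a, b in self.interaction_pairs:
            if a not in self.covariates or b not in self.covariates:
                raise ValueError(f"interaction pair ({a},{b}) not among covariates")


@dataclass
class LogisticFit:
    """A fitted (optionally Firth-penalized) logistic model.

    Coefficients are on the log-odds scale.  ``model_covariance`` is the
    inverse (penalized) observed information; ``robust_covariance`` the
    sandwich estimator bread*meat*bread.  The design and response are kept
    so downstream functionals (e.g. PAF intervals) can form joint
    estimating-equation covariances.
    """

    terms: tuple[str, ...]
    coefficients: np.ndarray
    model_covariance: np.ndarray
    robust_covariance: np.ndarray
    penalty: str
    converged: bool
    n_used: int
    log_likelihood: float
    separation: bool = False
    design: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    response: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str, robust: bool = False) -> float:
        i = self.terms.index(term)
        cov = self.robust_covariance if robust else self.model_covariance
        return float(math.sqrt(cov[i, i]))

    def fitted_probabilities(self) -> np.ndarray:
        return special.expit(self.design @ self.coefficients)

    def require_converged(self) -> None:
        if not self.converged:
            hint = ("; quasi-complete separation detected — refit with "
                    "penalty='firth'" if self.separation else "")
            raise ConvergenceError(f"fit did not converge{hint}")


# ---------------------------------------------------------------------------
# contingency-table OR

def corrected_or_woolf(table: TwoByTwoTable, correction: float = 0.5,
                       level: float = 0.95) -> ORResult:
    """Continuity-corrected odds ratio with a Woolf confidence interval.

    The correction ``k`` is added to *all four* cells unconditionally, so the
    estimate and its variance Sum 1/(cell+k) are defined even with a zero
    cell.  Two-sided Wald p on the log scale.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("a status margin is zero; the OR is undefined")
    k = correction
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float) + k
    if (cells == 0).any():
        raise ValueError("zero cell with zero correction; the OR is undefined")
    log_or = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = math.sqrt(float(np.sum(1.0 / cells)))
    z = stats.norm.ppf(0.5 + level / 2)
    p = 2 * stats.norm.sf(abs(log_or / se))
    return ORResult(
        term="exposure",
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
        sidedness="two_sided",
        method="corrected_woolf",
        n_cases=table.n_cases,
        n_controls=table.n_controls,
    )


# ---------------------------------------------------------------------------
# logistic regression

def _design_matrix(dataset: CodedDataset, spec: ModelSpec
                   ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    df = dataset.df
    missing = [c for c in (spec.outcome, *spec.covariates) if c not in df.columns]
    if missing:
        raise KeyError(f"unknown variable(s): {missing}")
    cols = df[list(spec.covariates)]
    if cols.isna().any().any() or df[spec.outcome].isna().any():
        raise ValueError("model variables contain missing values; "
                         "apply complete_case_subset first")
    y = df[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all() or len(np.unique(y)) < 2:
        raise ValueError("outcome must be binary with both classes present")
    terms = ["intercept", *spec.covariates]
    X = np.column_stack([np.ones(len(df)), cols.to_numpy(dtype=float)])
    for a, b in spec.interaction_pairs:
        terms.append(f"{a}:{b}")
        X = np.column_stack([X, df[a].to_numpy(float) * df[b].to_numpy(float)])
    for j, t in enumerate(terms[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"degenerate design: {t!r} is constant")
    return X, y, tuple(terms)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _information(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (X * w[:, None]).T @ X


def _covariances(X: np.ndarray, y: np.ndarray, beta: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    p = special.expit(X @ beta)
    bread = linalg.inv(_information(X, p * (1 - p)))
    resid = y - p
    meat = (X * (resid ** 2)[:, None]).T @ X
    return bread, bread @ meat @ bread


def fit_logistic(dataset: CodedDataset, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Starts at beta = 0; converges when max|step| < 1e-10 or the deviance
    change < 1e-12.  (Quasi-)complete separation — a coefficient escaping
    past |b| = 15 or the information matrix degenerating — is flagged on the
    returned fit rather than silently reported; refit with the Firth penalty.
    """
    if spec.penalty == "firth":
        return fit_logistic_firth(dataset, spec)
    X, y, terms = _design_matrix(dataset, spec)
    beta = np.zeros(X.shape[1])
    ll_old = _loglik(X, y, beta)
    converged = separated = False
    info = _information(X, np.full(len(y), 0.25))
    for _ in range(MAX_ITER):
        p = special.expit(X @ beta)
        w = p * (1 - p)
        info = _information(X, w)
        if np.linalg.cond(info) > 1 / SEPARATION_RCOND:
            separated = True
            break
        step = linalg.solve(info, X.T @ (y - p), assume_a="pos")
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            separated = True
            break
        ll = _loglik(X, y, beta)
        if np.max(np.abs(step)) < COEF_TOL or abs(ll - ll_old) < DEV_TOL:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    if converged:
        model_cov, robust_cov = _covariances(X, y, beta)
    else:
        k = X.shape[1]
        model_cov = robust_cov = np.full((k, k), np.nan)
    return LogisticFit(terms=terms, coefficients=beta, model_covariance=model_cov,
                       robust_covariance=robust_cov, penalty="none",
                       converged=converged, n_used=len(y),
                       log_likelihood=ll_old, separation=separated,
                       design=X, response=y)


def _hat_diagonal(X: np.ndarray, w: np.ndarray, info: np.ndarray) -> np.ndarray:
    # h_i = w_i * x_i' I^{-1} x_i
    sol = linalg.solve(info, X.T, assume_a="pos")
    return w * np.einsum("ij,ji->i", X, sol)


def fit_logistic_firth(dataset: CodedDataset, spec: ModelSpec) -> LogisticFit:
    """Firth's penalized logistic regression.

    Maximizes the Jeffreys-penalized log-likelihood l(b) + 0.5*log|I(b)| by
    modified-score Newton steps with step-halving; coefficients stay finite
    under separation.  Covariance is the inverse penalized information,
    evaluated at the optimum.
    """
    X, y, terms = _design_matrix(dataset, spec)
    beta = np.zeros(X.shape[1])

    def penalized_ll(b: np.ndarray) -> float:
        p = special.expit(X @ b)
        info = _information(X, p * (1 - p))
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return _loglik(X, y, b) + 0.5 * logdet

    pll_old = penalized_ll(beta)
    converged = False
    info = _information(X, np.full(len(y), 0.25))
    for _ in range(MAX_ITER):
        p = special.expit(X @ beta)
        w = p * (1 - p)
        info = _information(X, w)
        h = _hat_diagonal(X, w, info)
        score = X.T @ (y - p + h * (0.5 - p))
        step = linalg.solve(info, score, assume_a="pos")
        # step-halving on the penalized likelihood
        scale = 1.0
        for _ in range(25):
            cand = beta + scale * step
            pll = penalized_ll(cand)
            if pll >= pll_old - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        pll = penalized_ll(beta)
        if np.max(np.abs(scale * step)) < COEF_TOL or abs(pll - pll_old) < DEV_TOL:
            converged = True
            pll_old = pll
            break
        pll_old = pll

    model_cov, robust_cov = _covariances(X, y, beta)
    return LogisticFit(terms=terms, coefficients=beta, model_covariance=model_cov,
                       robust_covariance=robust_cov, penalty="firth",
                       converged=converged, n_used=len(y),
                       log_likelihood=pll_old, separation=False,
                       design=X, response=y)


def fit_auto(dataset: CodedDataset, spec: ModelSpec) -> LogisticFit:
    """Unpenalized fit, automatically retried with Firth on separation."""
    fit = fit_logistic(dataset, spec)
    if fit.separation or not fit.converged:
        fit = fit_logistic_firth(dataset, spec)
    return fit


# ---------------------------------------------------------------------------
# inference summaries

def one_sided_wald_summary(fit: LogisticFit, term: str) -> ORResult:
    """One-sided (risk-increasing) OR summary for one model term.

    OR = exp(b); lower bound = exp(b - 1.644854*SE) (the lower bound of a
    two-sided 90% Wald interval); upper bound infinity; p = upper-tail normal
    probability of b/SE.  Model-based standard errors.
    """
    fit.require_converged()
    beta = fit.coef(term)
    se = fit.se(term)
    if se == 0 or not math.isfinite(se):
        raise ValueError(f"degenerate standard error for {term!r}")
    n1 = int(fit.response.sum())
    return ORResult(
        term=term,
        or_point=math.exp(beta),
        ci_low=math.exp(beta - Z_ONE_SIDED_95 * se),
        ci_high=math.inf,
        p_value=float(stats.norm.sf(beta / se)),
        sidedness="one_sided",
        method="firth_wald" if fit.penalty == "firth" else "logistic_wald",
        n_cases=n1,
        n_controls=fit.n_used - n1,
    )


def one_proportion_z(successes: int, n: int, null_p: float = 0.5
                     ) -> tuple[float, float]:
    """One-proportion Z test; returns (z, upper-tail p)."""
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n, n > 0")
    if not 0 < null_p < 1:
        raise ValueError("null_p must be strictly inside (0, 1)")
    z = (successes / n - null_p) / math.sqrt(null_p * (1 - null_p) / n)
    return z, float(stats.norm.sf(z))


def interaction_pvalue(dataset: CodedDataset, base_spec: ModelSpec,
                       pair: tuple[str, str]) -> float:
    """Two-sided Wald p-value of a product term added to the base model.

    The penalty follows the base fit: if the unpenalized base model hits
    separation, both fits use the Firth penalty.
    """
    a, b = pair
    if a not in base_spec.covariates or b not in base_spec.covariates:
        raise ValueError(f"pair ({a},{b}) not among base covariates")
    penalty = base_spec.penalty
    if penalty == "none":
        base = fit_logistic(dataset, base_spec)
        if base.separation or not base.converged:
            penalty = "firth"
    spec = ModelSpec(covariates=base_spec.covariates, outcome=base_spec.outcome,
                     penalty=penalty, interaction_pairs=((a, b),))
    fit = fit_logistic(dataset, spec) if penalty == "none" else fit_logistic_firth(dataset, spec)
    if penalty == "none" and (fit.separation or not fit.converged):
        fit = fit_logistic_firth(dataset, spec)
    fit.require_converged()
    term = f"{a}:{b}"
    z = fit.coef(term) / fit.se(term)
    return float(2 * stats.norm.sf(abs(z)))
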