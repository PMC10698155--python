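"""Miettinen population attributable fractions with case-control intervals.

The case-based (Miettinen) form

    PAF = p_c * (1 - 1/RR)

uses the exposure prevalence among cases, p_c, and the relative risk RR,
approximated by the odds ratio under the rare-disease assumption.  Adjusted
PAFs plug in the exposure's adjusted OR from a multivariable logistic model
fitted on the same complete-case subset that supplies p_c.

Confidence intervals treat PAF = p_c * (1 - exp(-b_e)) as a smooth
functional of (p_c, b_e) and apply the delta method with a sandwich
covariance from the stacked estimating equations

    sum_i x_i (y_i - p_i)      = 0        (logistic score)
    sum_i y_i (e_i - p_c)      = 0        (case exposure prevalence)

The p_c equation does not involve b and the score does not involve p_c, so
the M-estimator "bread" is block-diagonal and the cross-covariance between
b-hat and p_c-hat reduces to I(b)^-1 * sum_i psi_b,i * psi_pc,i / n_cases.
Intervals are symmetric on the PAF scale and truncated above at 1.

Joint PAF across several factors, valid when no pairwise interaction is
detected, is 1 - prod_i (1 - PAF_i); its plug-in interval applies the same
formula to the sets of component lower and upper bounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, special

from .association import (LogisticFit, ModelSpec, Z_TWO_SIDED_95, fit_auto,
                          interaction_pvalue)
from .cohort import CodedDataset


@dataclass(frozen=True)
class PAFResult:
    """A Miettinen PAF with its inputs and confidence interval."""

    exposure: str
    paf: float
    p_c: float
    rr: float
    ci_low: float
    ci_high: float
    adjusted: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.paf <= self.ci_high:
            raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class JointPAFResult:
    """A joint PAF over several factors with plug-in bounds."""

    joint_paf: float
    components: tuple[PAFResult, ...]
    ci_low: float
    ci_high: float
    interaction_checked: bool
    interaction_pvalues: tuple[float, ...] = ()


def miettinen_paf(p_c: float, rr: float) -> float:
    """Case-based attributable fraction p_c * (1 - 1/rr)."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    if not 0 <= p_c <= 1:
        raise ValueError("p_c must be a probability")
    return p_c * (1.0 - 1.0 / rr)


def joint_paf(pafs: Sequence[float]) -> float:
    """Combined fraction 1 - prod(1 - PAF_i), accounting for overlap."""
    pafs = list(pafs)
    if any(p >= 1 for p in pafs):
        raise ValueError("each component PAF must be < 1")
    prod = 1.0
    for p in pafs:
        prod *= 1.0 - p
    return 1.0 - prod


def joint_paf_ci(component_bounds: Sequence[tuple[float, float]]
                 ) -> tuple[float, float]:
    """Plug-in joint interval from component (low, high) bounds."""
    lows = [lo for lo, _ in component_bounds]
    highs = [hi for _, hi in component_bounds]
    if any(lo > hi for lo, hi in component_bounds):
        raise ValueError("each low bound must not exceed its high bound")
    return joint_paf(lows), joint_paf(highs)


def paf_sandwich_ci(fit: LogisticFit, p_c: float, n_cases: int, exposure: str,
                    level: float = 0.95) -> tuple[float, float]:
    """Delta-method sandwich interval for PAF = p_c * (1 - exp(-b_e)).

    Variance combines the binomial variance of p_c over cases, the robust
    (sandwich) variance of the exposure coefficient, and their estimated
    covariance from the stacked estimating equations (see module docstring).
    The interval is symmetric on the PAF scale and truncated above at 1.
    """
    fit.require_converged()
    j = fit.terms.index(exposure)
    beta_e = float(fit.coefficients[j])
    paf = p_c * (1.0 - math.exp(-beta_e))

    var_b = float(fit.robust_covariance[j, j])
    if p_c in (0.0, 1.0):
        warnings.warn("degenerate case-prevalence; interval is unreliable",
                      stacklevel=2)
    var_pc = p_c * (1.0 - p_c) / n_cases

    # cross-covariance via joint estimating equations
    X, y = fit.design, fit.response
    p_hat = fit.fitted_probabilities()
    e = X[:, j]
    psi_pc = y * (e - p_c)  # nonzero for cases only
    cross_scores = X.T @ ((y - p_hat) * psi_pc)
    p_mean = special.expit(X @ fit.coefficients)
    info = (X * (p_mean * (1 - p_mean))[:, None]).T @ X
    cov_b_pc = float(linalg.solve(info, cross_scores, assume_a="pos")[j]) / n_cases
    # keep the 2x2 joint covariance positive semi-definite (Cauchy-Schwarz)
    bound = math.sqrt(max(var_b, 0.0) * var_pc)
    cov_b_pc = min(max(cov_b_pc, -bound), bound)

    g_pc = 1.0 - math.exp(-beta_e)
    g_b = p_c * math.exp(-beta_e)
    var = (g_pc ** 2 * var_pc + g_b ** 2 * var_b + 2 * g_pc * g_b * cov_b_pc)
    var = max(var, 0.0)
    z = Z_TWO_SIDED_95 if level == 0.95 else float(
        -np.asarray(special.ndtri((1 - level) / 2)))
    half = z * math.sqrt(var)
    return paf - half, min(paf + half, 1.0)


def adjusted_paf(dataset: CodedDataset, spec: ModelSpec, exposure: str,
                 level: float = 0.95) -> PAFResult:
    """Adjusted PAF for one exposure from a multivariable model.

    Fits the model (auto-switching to the Firth penalty on separation),
    computes p_c as the exposed fraction of cases on the same analytic
    subset, and attaches the sandwich delta-method interval.  A protective
    estimate (PAF < 0) is returned as computed, with a warning.
    """
    if exposure not in spec.covariates:
        raise ValueError(f"{exposure!r} is not among the model covariates")
    fit = fit_auto(dataset, spec)
    fit.require_converged()
    j = fit.terms.index(exposure)
    cases = fit.response == 1
    n_cases = int(cases.sum())
    p_c = float(fit.design[cases, j].mean())
    rr = math.exp(fit.coef(exposure))
    paf = miettinen_paf(p_c, rr)
    if paf < 0:
        warnings.warn(f"{exposure}: protective estimate (PAF={paf:.3f})",
                      stacklevel=2)
    lo, hi = paf_sandwich_ci(fit, p_c, n_cases, exposure, level=level)
    return PAFResult(exposure=exposure, paf=paf, p_c=p_c, rr=rr,
                     ci_low=lo, ci_high=hi, adjusted=len(spec.covariates) > 1)


def joint_paf_guard(dataset: CodedDataset, base_spec: ModelSpec,
                    factors: Sequence[str], threshold: float = 0.05
                    ) -> tuple[bool, dict[tuple[str, str], float]]:
    """Pairwise interaction screen gating the joint PAF.

    Returns (permitted, p-values): permitted is True iff every pairwise
    product-term Wald p-value exceeds ``threshold`` (no interaction
    detected), the assumption under which the joint formula is valid.
    A single factor passes vacuously.
    """
    factors = list(factors)
    pvals: dict[tuple[str, str], float] = {}
    for i in range(len(factors)):
        for k in range(i + 1, len(factors)):
            pair = (factors[i], factors[k])
            pvals[pair] = interaction_pvalue(dataset, base_spec, pair)
    return all(p > threshold for p in pvals.values()), pvals


def joint_adjusted_paf(dataset: CodedDataset, spec: ModelSpec,
                       factors: Sequence[str], threshold: float = 0.05,
                       level: float = 0.95) -> JointPAFResult:
    """Adjusted PAFs for several factors combined into a joint PAF.

    Runs the interaction guard first; the joint estimate is still returned
    when the guard fails, but ``interaction_checked`` is False and callers
    should report the failing p-values instead of the joint figure.
    """
    ok, pvals = joint_paf_guard(dataset, spec, factors, threshold=threshold)
    comps = tuple(adjusted_paf(dataset, spec, f, level=level) for f in factors)
    point = joint_paf([c.paf for c in comps])
    lo, hi = joint_paf_ci([(c.ci_low, c.ci_high) for c in comps])
    return JointPAFResult(joint_paf=point, components=comps, ci_low=lo,
                          ci_high=hi, interaction_checked=ok,
                          interaction_pvalues=tuple(pvals.values()))
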