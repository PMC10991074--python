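"""Intervention evaluation and design utilities.

Pre/post evaluation of a media-literacy intervention on the five
Verification-done dimensions (paired t-tests with Cohen's d and
noncentral-t confidence intervals), power/sample-size solvers for
two-sample t-tests and correlations, and incremental-validity regressions
(adjusted R-squared gain of adding a predictor block).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .scoring import VerificationScores, scores_to_frame

__all__ = [
    "PairedTestResult",
    "PowerQuery",
    "IncrementalResult",
    "EvaluateError",
    "paired_change_test",
    "paired_change_suite",
    "required_n_ttest",
    "required_n_correlation",
    "power_two_sample_t",
    "incremental_validity",
]

DIMENSIONS = ("V", "r", "f", "d", "n")


class EvaluateError(ValueError):
    pass


@dataclass
class PairedTestResult:
    dimension: str
    mean_diff: float
    ci: tuple[float, float]
    t: float
    df: int
    p: float
    d_z: float
    d_av: float
    d_ci: tuple[float, float]
    n_pairs: int


@dataclass
class PowerQuery:
    test: str  # "two_sample_t" | "correlation"
    effect: float
    alpha: float = 0.05
    power: float = 0.90
    sides: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise EvaluateError("alpha and power must lie in (0, 1)")
        if self.effect <= 0:
            raise EvaluateError("effect-error: effect size must be positive")
        if self.power <= self.alpha:
            raise EvaluateError("infeasible: power must exceed alpha")


@dataclass
class IncrementalResult:
    adj_r2_base: float
    adj_r2_full: float
    delta_r2: float
    r2_base: float
    r2_full: float
    coefficients: pd.DataFrame | None = None


def _d_ci_noncentral(t_stat: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """CI for d_z by inverting the noncentral t distribution of the statistic."""
    df = n - 1
    lo_p, hi_p = (1 + conf) / 2, (1 - conf) / 2

    def solve(target_p):
        def f(ncp):
            return stats.nct.cdf(t_stat, df, ncp) - target_p
        lo, hi = t_stat - 10 - 10 / np.sqrt(n), t_stat + 10 + 10 / np.sqrt(n)
        try:
            return optimize.brentq(f, lo, hi)
        except ValueError:
            return np.nan
    ncp_lo = solve(lo_p)
    ncp_hi = solve(hi_p)
    return ncp_lo / np.sqrt(n), ncp_hi / np.sqrt(n)


def paired_change_test(
    pre: Sequence[float], post: Sequence[float], dimension: str = ""
) -> PairedTestResult:
    """Repeated-measures t-test on post - pre with effect sizes.

    Reports d_z = mean_diff / SD(diff) (so t = d_z * sqrt(n)) and
    d_av = mean_diff / mean(SD_pre, SD_post), each with a 95% CI; the d_z
    CI inverts the noncentral t distribution.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise EvaluateError("alignment-error: pre/post lengths differ")
    n = pre.size
    if n < 3:
        raise EvaluateError("need at least 3 pairs")
    diff = post - pre
    sd_diff = diff.std(ddof=1)
    if sd_diff == 0:
        if np.all(diff == 0):
            # no change at all: the null result, not an error
            return PairedTestResult(
                dimension=dimension, mean_diff=0.0, ci=(0.0, 0.0),
                t=0.0, df=n - 1, p=1.0, d_z=0.0, d_av=0.0,
                d_ci=(0.0, 0.0), n_pairs=n,
            )
        raise EvaluateError(
            "degenerate-variance: nonzero but constant differences"
        )
    mean_diff = float(diff.mean())
    se = sd_diff / np.sqrt(n)
    t_stat = mean_diff / se
    df = n - 1
    p = 2 * stats.t.sf(abs(t_stat), df)
    t_crit = stats.t.ppf(0.975, df)
    d_z = mean_diff / sd_diff
    sd_av = 0.5 * (pre.std(ddof=1) + post.std(ddof=1))
    d_av = mean_diff / sd_av if sd_av > 0 else np.nan
    return PairedTestResult(
        dimension=dimension,
        mean_diff=mean_diff,
        ci=(mean_diff - t_crit * se, mean_diff + t_crit * se),
        t=float(t_stat), df=df, p=float(p),
        d_z=float(d_z), d_av=float(d_av),
        d_ci=_d_ci_noncentral(t_stat, n),
        n_pairs=n,
    )


def paired_change_suite(
    pre: Sequence[VerificationScores],
    post: Sequence[VerificationScores],
) -> dict[str, PairedTestResult]:
    """Paired tests for all five dimensions, aligned on respondent id."""
    pre_f = scores_to_frame(pre)
    post_f = scores_to_frame(post)
    if set(pre_f.index) != set(post_f.index):
        raise EvaluateError("alignment-error: pre/post respondent ids differ")
    post_f = post_f.loc[pre_f.index]
    return {
        dim: paired_change_test(pre_f[dim], post_f[dim], dimension=dim)
        for dim in DIMENSIONS
    }


def power_two_sample_t(n_per_group: float, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    )


def required_n_ttest(query: PowerQuery) -> tuple[float, int]:
    """Per-group n for a two-sample t-test, solved on the noncentral t."""
    if query.test != "two_sample_t":
        raise EvaluateError(f"wrong test {query.test!r} for required_n_ttest")

    def gap(n):
        return power_two_sample_t(n, query.effect, query.alpha) - query.power

    hi = 4.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e7:
            raise EvaluateError("infeasible: required n exceeds 1e7 per group")
    n_real = optimize.brentq(gap, 2.001, hi)
    return float(n_real), int(np.ceil(n_real))


def required_n_correlation(query: PowerQuery) -> tuple[float, int]:
    """N to detect a correlation via the Fisher-z approximation:
    n = ((z_{1-alpha/2} + z_{power}) / atanh(r))^2 + 3."""
    if query.test != "correlation":
        raise EvaluateError(f"wrong test {query.test!r} for required_n_correlation")
    r = query.effect
    if r >= 1:
        raise EvaluateError("effect-error: |r| must be < 1")
    z_a = stats.norm.ppf(1 - query.alpha / 2)
    z_b = stats.norm.ppf(query.power)
    n_real = ((z_a + z_b) / np.arctanh(r)) ** 2 + 3
    return float(n_real), int(np.ceil(n_real))


def incremental_validity(
    outcome: Sequence[float],
    base: np.ndarray,
    added: np.ndarray,
    names_base: list[str] | None = None,
    names_added: list[str] | None = None,
) -> IncrementalResult:
    """Adjusted-R^2 gain from adding a predictor block, on standardized data.

    Fits OLS of the standardized outcome on the standardized base predictors
    and on base + added; reports adjusted R^2 for both, the gain, and the
    full-model coefficient table with 95% CIs.
    """
    y = np.asarray(outcome, dtype=float)
    xb = np.atleast_2d(np.asarray(base, dtype=float))
    xa = np.atleast_2d(np.asarray(added, dtype=float))
    if xb.shape[0] != y.size:
        xb = xb.T
    if xa.shape[0] != y.size:
        xa = xa.T
    n = y.size
    k_full = xb.shape[1] + xa.shape[1]
    if n <= k_full + 2:
        raise EvaluateError("too few complete cases for the full model")

    def z(v):
        sd = v.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise EvaluateError("collinearity: constant predictor")
        return (v - v.mean(axis=0)) / sd

    yz = z(y[:, None]).ravel()
    xbz, xaz = z(xb), z(xa)
    full_x = np.column_stack([xbz, xaz])
    if np.linalg.matrix_rank(full_x) < full_x.shape[1]:
        raise EvaluateError("collinearity: rank-deficient design")

    names = (names_base or [f"base_{j}" for j in range(xb.shape[1])]) + (
        names_added or [f"added_{j}" for j in range(xa.shape[1])]
    )
    m_base = sm.OLS(yz, sm.add_constant(xbz)).fit()
    m_full = sm.OLS(yz, sm.add_constant(pd.DataFrame(full_x, columns=names))).fit()
    ci = m_full.conf_int()
    coefs = pd.DataFrame({
        "beta": m_full.params, "ci_low": ci[0], "ci_high": ci[1],
        "t": m_full.tvalues, "p": m_full.pvalues,
    })
    return IncrementalResult(
        adj_r2_base=float(m_base.rsquared_adj),
        adj_r2_full=float(m_full.rsquared_adj),
        delta_r2=float(m_full.rsquared_adj - m_base.rsquared_adj),
        r2_base=float(m_base.rsquared),
        r2_full=float(m_full.rsquared),
        coefficients=coefs,
    )
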