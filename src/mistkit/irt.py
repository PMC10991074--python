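"""Three-parameter logistic (3PL) item response model.

The response curve is the logistic-metric 3PL without the historical 1.702
scaling constant:

    P(correct | theta) = c + (1 - c) / (1 + exp(-a (theta - b)))

with discrimination ``a``, difficulty ``b`` and guessing floor ``c``.  For a
binary real/fake judgment the floor is fixed at c = 0.5: a respondent with
no ability still has a coin-flip chance of the correct label.

Provided here: item/test information, EAP ability scoring under a standard
normal prior, marginal maximum-likelihood EM calibration with c fixed, and
a likelihood-ratio test for differential item functioning (DIF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "IRTParams",
    "ThetaEstimate",
    "CalibrationResult",
    "DIFResult",
    "IRTError",
    "icc_3pl",
    "item_information",
    "test_information",
    "estimate_theta_eap",
    "calibrate_3pl_em",
    "dif_likelihood_ratio",
    "quadrature_grid",
]

A_BOUNDS = (0.05, 10.0)
B_BOUNDS = (-6.0, 6.0)


class IRTError(ValueError):
    pass


@dataclass
class IRTParams:
    """Per-item 3PL parameters (aligned arrays)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    item_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        c = np.asarray(self.c, dtype=float)
        if c.ndim == 0:
            c = np.full_like(self.a, float(c))
        self.c = c
        if not (self.a.shape == self.b.shape == self.c.shape):
            raise IRTError("a, b, c must be aligned")
        if np.any(self.a <= 0):
            raise IRTError("discriminations must be positive")
        if np.any((self.c < 0) | (self.c >= 1)):
            raise IRTError("guessing parameters must lie in [0, 1)")

    @property
    def n_items(self) -> int:
        return self.a.size


@dataclass
class ThetaEstimate:
    theta: float
    sd: float
    method: str = "EAP"


@dataclass
class CalibrationResult:
    params: IRTParams
    loglik_trace: list[float]
    converged: bool
    n_cycles: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class DIFResult:
    """Per-item likelihood-ratio DIF statistics (df = 2: group-specific a, b)."""

    item_ids: list[str]
    chi2: np.ndarray
    df: int
    p: np.ndarray
    flagged: np.ndarray
    alpha: float


def icc_3pl(a, b, c, theta):
    """3PL response probability; broadcasts over items and theta."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.asarray(theta, dtype=float)
    z = a * (theta - b)
    return c + (1.0 - c) / (1.0 + np.exp(-z))


def item_information(a, b, c, theta):
    """Fisher information of one 3PL item: a^2 (Q/P) ((P-c)/(1-c))^2."""
    p = icc_3pl(a, b, c, theta)
    q = 1.0 - p
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    return a**2 * (q / p) * ((p - c) / (1.0 - c)) ** 2


def test_information(params: IRTParams, theta_grid, by_subscale=None):
    """Pointwise sum of item information over a theta grid.

    ``by_subscale`` optionally maps subscale name -> boolean item mask and
    adds per-subscale curves.
    """
    if params.n_items == 0:
        raise IRTError("empty parameter set")
    grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    info = item_information(
        params.a[:, None], params.b[:, None], params.c[:, None], grid[None, :]
    )
    out = {"theta": grid, "total": info.sum(axis=0)}
    if by_subscale:
        for name, mask in by_subscale.items():
            out[name] = info[np.asarray(mask, dtype=bool)].sum(axis=0)
    return out


def quadrature_grid(n_nodes: int = 61, span: float = 6.0):
    """Equally spaced quadrature nodes on [-span, span] with N(0,1) weights."""
    nodes = np.linspace(-span, span, n_nodes)
    w = stats.norm.pdf(nodes)
    return nodes, w / w.sum()


def estimate_theta_eap(
    params: IRTParams,
    pattern,
    n_nodes: int = 61,
) -> ThetaEstimate:
    """Expected-a-posteriori ability under a N(0,1) prior on a fixed grid.

    ``pattern`` holds 1 (correct), 0 (incorrect) or -1/NaN (not answered);
    unanswered items contribute nothing to the likelihood.
    """
    pattern = np.asarray(pattern, dtype=float).ravel()
    if pattern.size != params.n_items:
        raise IRTError("response pattern not aligned to parameters")
    answered = np.isfinite(pattern) & (pattern >= 0)
    if not answered.any():
        raise IRTError("empty response pattern")

    nodes, weights = quadrature_grid(n_nodes)
    p = icc_3pl(
        params.a[answered, None], params.b[answered, None],
        params.c[answered, None], nodes[None, :],
    )
    p = np.clip(p, 1e-12, 1 - 1e-12)
    x = pattern[answered][:, None]
    loglik = np.sum(x * np.log(p) + (1 - x) * np.log1p(-p), axis=0)
    post = weights * np.exp(loglik - loglik.max())
    post /= post.sum()
    mean = float(post @ nodes)
    var = float(post @ (nodes - mean) ** 2)
    return ThetaEstimate(theta=mean, sd=float(np.sqrt(var)))


def _e_step(data01, a, b, c, nodes, weights):
    """Expected counts per quadrature node; returns (loglik, n_q, r_jq)."""
    p = icc_3pl(a[:, None], b[:, None], c[:, None], nodes[None, :])  # items x Q
    p = np.clip(p, 1e-10, 1 - 1e-10)
    logp, log1p = np.log(p), np.log1p(-p)
    # respondents x Q
    ll = data01 @ logp + (1 - data01) @ log1p
    ll += np.log(weights)[None, :]
    m = ll.max(axis=1, keepdims=True)
    post = np.exp(ll - m)
    norm = post.sum(axis=1, keepdims=True)
    post /= norm
    loglik = float(np.sum(m.ravel() + np.log(norm.ravel())))
    n_q = post.sum(axis=0)                     # Q
    r_jq = data01.T @ post                     # items x Q
    return loglik, n_q, r_jq


def _m_step_item(n_q, r_j, c_j, nodes, start):
    """Maximize one item's expected complete-data log-likelihood over (a, b)."""

    def neg(ab):
        a_j, b_j = ab
        p = icc_3pl(a_j, b_j, c_j, nodes)
        p = np.clip(p, 1e-10, 1 - 1e-10)
        return -float(np.sum(r_j * np.log(p) + (n_q - r_j) * np.log(1 - p)))

    res = optimize.minimize(
        neg, np.asarray(start, dtype=float), method="L-BFGS-B",
        bounds=[A_BOUNDS, B_BOUNDS],
    )
    return res.x


def calibrate_3pl_em(
    data,
    fixed_c: float = 0.5,
    item_ids: list[str] | None = None,
    max_cycles: int = 500,
    tol_param: float = 1e-4,
    tol_loglik: float = 1e-6,
    n_nodes: int = 61,
) -> CalibrationResult:
    """Marginal maximum-likelihood EM calibration with the guessing floor fixed.

    ``data`` is an n x p 0/1 matrix.  a and b are free per item within box
    constraints (a in (0.05, 10], b in [-6, 6]); c is fixed (default 0.5).
    Convergence when max |param change| < ``tol_param`` or the marginal
    log-likelihood improves by less than ``tol_loglik``.
    """
    data01 = np.asarray(data, dtype=float)
    if data01.ndim != 2:
        raise IRTError("data must be an n x p matrix")
    n, p_items = data01.shape
    warnings: list[str] = []
    if n < 200:
        warnings.append(f"n = {n} < 200; calibration may be unstable")

    means = data01.mean(axis=0)
    for j, m in enumerate(means):
        if m in (0.0, 1.0):
            name = item_ids[j] if item_ids else f"item {j}"
            raise IRTError(f"degenerate-item: {name} has a constant column")

    nodes, weights = quadrature_grid(n_nodes)
    c = np.full(p_items, float(fixed_c))
    a = np.ones(p_items)
    # start b from the c-corrected proportion correct
    prop = np.clip((means - c) / (1 - c), 0.02, 0.98)
    b = -stats.norm.ppf(prop)

    trace: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        loglik, n_q, r_jq = _e_step(data01, a, b, c, nodes, weights)
        trace.append(loglik)
        a_new, b_new = a.copy(), b.copy()
        for j in range(p_items):
            a_new[j], b_new[j] = _m_step_item(
                n_q, r_jq[j], c[j], nodes, (a[j], b[j])
            )
        delta = max(np.max(np.abs(a_new - a)), np.max(np.abs(b_new - b)))
        a, b = a_new, b_new
        if delta < tol_param:
            converged = True
            break
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol_loglik:
            converged = True
            break

    params = IRTParams(a=a, b=b, c=c, item_ids=item_ids)
    return CalibrationResult(
        params=params, loglik_trace=trace, converged=converged,
        n_cycles=cycle, warnings=warnings,
    )


def _joint_loglik(data01, a, b, c, nodes, weights):
    loglik, _, _ = _e_step(data01, a, b, c, nodes, weights)
    return loglik


def dif_likelihood_ratio(
    data,
    group,
    alpha: float = 0.05,
    item_ids: list[str] | None = None,
    max_cycles: int = 200,
    n_nodes: int = 41,
) -> DIFResult:
    """Likelihood-ratio DIF test per item (df = 2), anchored on all other items.

    The constrained model calibrates both groups jointly with equal item
    parameters.  For each studied item, the free model lets that item's
    (a, b) differ by group while all remaining items stay anchored at the
    pooled estimates; 2 * (LL_free - LL_constrained) is referred to a
    chi-square with 2 df.  Flags at ``alpha``, uncorrected.
    """
    data01 = np.asarray(data, dtype=float)
    group = np.asarray(group).ravel()
    levels = np.unique(group)
    if levels.size != 2:
        raise IRTError("DIF needs exactly two groups")
    g0, g1 = data01[group == levels[0]], data01[group == levels[1]]

    pooled = calibrate_3pl_em(
        data01, item_ids=item_ids, max_cycles=max_cycles, n_nodes=n_nodes
    )
    a0, b0, c = pooled.params.a, pooled.params.b, pooled.params.c
    nodes, weights = quadrature_grid(n_nodes)

    ll_constrained = _joint_loglik(g0, a0, b0, c, nodes, weights) + _joint_loglik(
        g1, a0, b0, c, nodes, weights
    )

    p_items = data01.shape[1]
    chi2 = np.zeros(p_items)
    for j in range(p_items):
        ll_free = 0.0
        for g in (g0, g1):
            # refit item j's (a, b) within this group, others anchored
            _, n_q, r_jq = _e_step(g, a0, b0, c, nodes, weights)
            aj, bj = _m_step_item(n_q, r_jq[j], c[j], nodes, (a0[j], b0[j]))
            a_g, b_g = a0.copy(), b0.copy()
            a_g[j], b_g[j] = aj, bj
            # one extra EM refinement of item j with updated posteriors
            _, n_q, r_jq = _e_step(g, a_g, b_g, c, nodes, weights)
            a_g[j], b_g[j] = _m_step_item(n_q, r_jq[j], c[j], nodes, (aj, bj))
            ll_free += _joint_loglik(g, a_g, b_g, c, nodes, weights)
        chi2[j] = max(0.0, 2.0 * (ll_free - ll_constrained))

    p = stats.chi2.sf(chi2, df=2)
    ids = item_ids if item_ids is not None else [f"item_{j}" for j in range(p_items)]
    return DIFResult(
        item_ids=list(ids), chi2=chi2, df=2, p=p, flagged=p < alpha, alpha=alpha
    )
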