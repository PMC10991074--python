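"""Classical test theory engine for binary response matrices.

Covers the analysis chain used when developing a true/false test from a
scored correctness matrix: tetrachoric correlations (maximum likelihood on
each 2x2 table under a latent bivariate normal), parallel analysis for
factor retention, exploratory factor analysis (principal axis factoring or
unweighted least squares, with varimax/promax rotation), 3PL-based
communalities, Cronbach's alpha with iterative item pruning, and a
reliability report with two-factor McDonald's omega via Schmid-Leiman
orthogonalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .irt import IRTParams

__all__ = [
    "BinaryDataMatrix",
    "CorrelationMatrix",
    "ParallelAnalysisResult",
    "FactorSolution",
    "ReliabilityReport",
    "ClassicalError",
    "bvn_cdf",
    "tetrachoric_pair",
    "tetrachoric_matrix",
    "smooth_to_pd",
    "parallel_analysis",
    "efa",
    "varimax",
    "promax",
    "communalities_from_3pl",
    "cronbach_alpha",
    "alpha_if_deleted_prune",
    "reliability_report",
]


class ClassicalError(ValueError):
    pass


@dataclass
class BinaryDataMatrix:
    """n x p 0/1 matrix with row/column identifiers."""

    values: np.ndarray
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ClassicalError("values must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ClassicalError("entries must be 0/1 with no missing values")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ClassicalError("need at least 2 rows and 2 columns")
        if self.col_ids is None:
            self.col_ids = [f"item_{j}" for j in range(p)]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    kind: str = "tetrachoric"
    smoothed: bool = False
    col_ids: list[str] | None = None


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    sim_p95: np.ndarray
    n_retained: int
    n_sim: int


@dataclass
class FactorSolution:
    loadings: np.ndarray
    rotation: str
    communalities: np.ndarray
    method: str
    converged: bool = True
    heywood: bool = False
    phi: np.ndarray | None = None  # factor correlations (oblique rotations)


@dataclass
class ReliabilityReport:
    alpha: float
    iic_min: float
    iic_max: float
    itc_min: float
    itc_max: float
    omega_g: float
    omega_F1: float
    omega_F2: float
    variance_decomposition: dict[str, float] = field(default_factory=dict)
    test_retest: float | None = None


# ---------------------------------------------------------------------------
# bivariate normal CDF and tetrachoric correlation


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T.

    Vectorized over all arguments; |rho| is clipped just inside (-1, 1).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -0.9999, 0.9999)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    eps = 1e-12
    hs = np.where(np.abs(h) < eps, eps, h)
    ks = np.where(np.abs(k) < eps, eps, k)
    denom = np.sqrt(1.0 - rho**2)
    ah = (ks - rho * hs) / (hs * denom)
    ak = (hs - rho * ks) / (ks * denom)
    t1 = special.owens_t(hs, ah)
    t2 = special.owens_t(ks, ak)
    beta = np.where(hs * ks < 0, 0.5, 0.0)
    out = 0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k)) - t1 - t2 - beta
    return np.clip(out, 0.0, 1.0)


def _table_counts(x, y):
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    return np.array([n00, n01, n10, n11], dtype=float)


_RHO_GRID = np.linspace(-0.999, 0.999, 401)


def _pair_loglik(counts, tau1, tau2, rho):
    """Multinomial log-likelihood of one 2x2 table over a rho array."""
    p00 = bvn_cdf(tau1, tau2, rho)
    p0x = stats.norm.cdf(tau1)
    px0 = stats.norm.cdf(tau2)
    p01 = np.clip(p0x - p00, 1e-12, 1)
    p10 = np.clip(px0 - p00, 1e-12, 1)
    p11 = np.clip(1 - p0x - px0 + p00, 1e-12, 1)
    p00 = np.clip(p00, 1e-12, 1)
    n00, n01, n10, n11 = counts
    return (
        n00 * np.log(p00) + n01 * np.log(p01) + n10 * np.log(p10) + n11 * np.log(p11)
    )


def tetrachoric_pair(x, y) -> float:
    """ML tetrachoric correlation for one pair of binary variables.

    Thresholds come from the margins; rho is found by a vectorized grid
    search with quadratic refinement.  Zero cells receive a +0.5 continuity
    correction before estimation.
    """
    counts = _table_counts(x, y)
    if counts.sum() == 0:
        raise ClassicalError("empty table")
    if np.any(counts == 0):
        counts = counts + np.where(counts == 0, 0.5, 0.0)
    n = counts.sum()
    # margins: P(x=0), P(y=0)
    p_x0 = (counts[0] + counts[1]) / n
    p_y0 = (counts[0] + counts[2]) / n
    tau1 = stats.norm.ppf(np.clip(p_x0, 1e-10, 1 - 1e-10))
    tau2 = stats.norm.ppf(np.clip(p_y0, 1e-10, 1 - 1e-10))
    ll = _pair_loglik(counts, tau1, tau2, _RHO_GRID)
    i = int(np.argmax(ll))
    if 0 < i < len(_RHO_GRID) - 1:
        # quadratic interpolation around the grid maximum
        y0, y1, y2 = ll[i - 1], ll[i], ll[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        step = _RHO_GRID[1] - _RHO_GRID[0]
        return float(np.clip(_RHO_GRID[i] + shift * step, -0.999, 0.999))
    return float(_RHO_GRID[i])


def smooth_to_pd(mat: np.ndarray, min_eig: float = 1e-6):
    """Eigen-clip to positive definite, rescale to unit diagonal.

    Returns (matrix, smoothed_flag).
    """
    mat = np.asarray(mat, dtype=float)
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    if w.min() >= min_eig:
        return mat, False
    w = np.clip(w, min_eig, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, True


def tetrachoric_matrix(data: BinaryDataMatrix) -> CorrelationMatrix:
    """Pairwise ML tetrachoric correlation matrix, smoothed to PD if needed."""
    x = data.values
    means = x.mean(axis=0)
    for j, m in enumerate(means):
        if m in (0.0, 1.0):
            raise ClassicalError(
                f"degenerate-item: column {data.col_ids[j]} is constant"
            )
    p = data.p
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            out[i, j] = out[j, i] = tetrachoric_pair(x[:, i], x[:, j])
    smoothed_mat, was_smoothed = smooth_to_pd(out)
    return CorrelationMatrix(
        values=smoothed_mat, kind="tetrachoric", smoothed=was_smoothed,
        col_ids=data.col_ids,
    )


# ---------------------------------------------------------------------------
# parallel analysis


def parallel_analysis(
    data: BinaryDataMatrix,
    n_sim: int = 500,
    quantile: float = 0.95,
    seed: int | np.random.Generator | None = 0,
) -> ParallelAnalysisResult:
    """Factor retention by comparison with column-permuted null datasets.

    Null datasets permute each column of the observed matrix independently
    (preserving the binary margins); retention counts the leading run of
    observed tetrachoric eigenvalues above the per-rank 95th percentile.
    """
    rng = np.random.default_rng(seed)
    obs = np.sort(np.linalg.eigvalsh(tetrachoric_matrix(data).values))[::-1]
    p = data.p
    sims = np.empty((n_sim, p))
    x = data.values
    for s in range(n_sim):
        perm = np.column_stack(
            [rng.permutation(x[:, j]) for j in range(p)]
        )
        sim_corr = tetrachoric_matrix(
            BinaryDataMatrix(perm, col_ids=data.col_ids)
        ).values
        sims[s] = np.sort(np.linalg.eigvalsh(sim_corr))[::-1]
    p95 = np.quantile(sims, quantile, axis=0)
    n_retained = 0
    for o, t in zip(obs, p95):
        if o > t:
            n_retained += 1
        else:
            break
    return ParallelAnalysisResult(
        observed_eigenvalues=obs, sim_p95=p95, n_retained=n_retained, n_sim=n_sim
    )


# ---------------------------------------------------------------------------
# exploratory factor analysis


def _principal_loadings(r: np.ndarray, k: int) -> np.ndarray:
    w, v = np.linalg.eigh(r)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def _smc(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations from the inverse correlation matrix."""
    try:
        inv = np.linalg.inv(r)
        return np.clip(1.0 - 1.0 / np.diag(inv), 0.0, 1.0)
    except np.linalg.LinAlgError:
        return np.full(r.shape[0], 0.5)


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation (orthogonal), with Kaiser row normalization."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt(np.sum(L**2, axis=1))
    if kaiser:
        h_safe = np.where(h > 1e-12, h, 1.0)
        L = L / h_safe[:, None]
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        lr = L @ rot
        u, s, vt = np.linalg.svd(
            L.T @ (lr**3 - lr @ np.diag(np.sum(lr**2, axis=0)) / p)
        )
        rot = u @ vt
        d_new = np.sum(s)
        if d_new < d * (1 + tol):
            break
        d = d_new
    out = L @ rot
    if kaiser:
        out = out * np.where(h > 1e-12, h, 1.0)[:, None]
    # sign convention: dominant direction of each factor positive
    signs = np.sign(np.sum(out**3, axis=0))
    signs[signs == 0] = 1.0
    return out * signs


def promax(loadings: np.ndarray, power: int = 4):
    """Promax oblique rotation; returns (pattern, phi)."""
    x = varimax(loadings)
    q = x * np.abs(x) ** (power - 1)
    u, *_ = np.linalg.lstsq(x, q, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u * np.sqrt(d)
    pattern = x @ u
    u_inv = np.linalg.inv(u)
    phi = u_inv @ u_inv.T
    return pattern, phi


def _paf(r: np.ndarray, k: int, tol: float = 1e-3, max_iter: int = 100):
    h2 = _smc(r)
    converged = False
    for _ in range(max_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        loadings = _principal_loadings(rr, k)
        h2_new = np.clip(np.sum(loadings**2, axis=1), 0.0, None)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new
    return loadings, h2, converged


def _uls(r: np.ndarray, k: int):
    p = r.shape[0]

    def loss(psi):
        rr = r - np.diag(psi)
        loadings = _principal_loadings(rr, k)
        resid = r - loadings @ loadings.T
        np.fill_diagonal(resid, 0.0)
        return np.sum(resid**2)

    psi0 = 1.0 - _smc(r)
    res = optimize.minimize(
        loss, psi0, method="L-BFGS-B", bounds=[(1e-3, 1.0)] * p
    )
    rr = r - np.diag(res.x)
    loadings = _principal_loadings(rr, k)
    h2 = np.sum(loadings**2, axis=1)
    return loadings, h2, bool(res.success)


def efa(
    data: BinaryDataMatrix | None,
    k: int,
    method: str = "PAF",
    rotation: str = "varimax",
    corr: CorrelationMatrix | np.ndarray | None = None,
) -> FactorSolution:
    """Exploratory factor analysis on the tetrachoric correlation matrix.

    ``corr`` may supply a precomputed correlation matrix; otherwise it is
    estimated from ``data``.  Heywood cases (communality > 1) are clipped
    and flagged.
    """
    if corr is None:
        if data is None:
            raise ClassicalError("need data or a correlation matrix")
        corr = tetrachoric_matrix(data)
    r = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    r, _ = smooth_to_pd(r)
    p = r.shape[0]
    if not 0 < k < p:
        raise ClassicalError(f"k must be in (0, {p})")

    if method.upper() == "PAF":
        loadings, h2, converged = _paf(r, k)
    elif method.upper() == "ULS":
        loadings, h2, converged = _uls(r, k)
    else:
        raise ClassicalError(f"unknown method {method!r}")

    heywood = bool(np.any(h2 > 1.0 + 1e-9))
    if heywood:
        scale = np.where(h2 > 1.0, np.sqrt(1.0 / h2), 1.0)
        loadings = loadings * scale[:, None]
        h2 = np.clip(h2, None, 1.0)

    phi = None
    if rotation == "varimax" and k >= 2:
        loadings = varimax(loadings)
    elif rotation == "promax" and k >= 2:
        loadings, phi = promax(loadings)
    elif rotation not in ("none", "varimax", "promax"):
        raise ClassicalError(f"unknown rotation {rotation!r}")

    return FactorSolution(
        loadings=loadings, rotation=rotation, communalities=h2,
        method=method.upper(), converged=converged, heywood=heywood, phi=phi,
    )


def communalities_from_3pl(params: IRTParams) -> np.ndarray:
    """Communalities implied by 3PL discriminations.

    Converts each discrimination to a normal-ogive factor loading,
    lambda = (a/1.702) / sqrt(1 + (a/1.702)^2), and squares it.
    """
    if params.a is None or np.any(~np.isfinite(params.a)):
        raise ClassicalError("missing-parameter: every item needs a discrimination")
    a_star = params.a / 1.702
    lam = a_star / np.sqrt(1.0 + a_star**2)
    return lam**2


# ---------------------------------------------------------------------------
# reliability


def cronbach_alpha(values: np.ndarray) -> float:
    """Cronbach's alpha on 0/1 items (KR-20 equivalent)."""
    x = np.asarray(values, dtype=float)
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return 1.0
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def alpha_if_deleted_prune(
    data: BinaryDataMatrix, delta: float = 0.001
) -> tuple[list[str], list[dict]]:
    """Iteratively drop the item whose removal raises alpha the most (> delta).

    Returns (kept item ids, removal trace).  Stops when no removal clears
    ``delta`` or only 3 items remain.
    """
    x = data.values.astype(float)
    ids = list(data.col_ids)
    trace: list[dict] = []
    while x.shape[1] > 3:
        current = cronbach_alpha(x)
        gains = np.array([
            cronbach_alpha(np.delete(x, j, axis=1)) - current
            for j in range(x.shape[1])
        ])
        j = int(np.argmax(gains))
        if gains[j] <= delta:
            break
        trace.append({
            "removed": ids[j],
            "alpha_before": current,
            "alpha_after": current + float(gains[j]),
        })
        x = np.delete(x, j, axis=1)
        del ids[j]
    return ids, trace


def _schmid_leiman(r: np.ndarray, assignment: np.ndarray):
    """Two-factor promax EFA + Schmid-Leiman; returns (g, group) loadings.

    ``assignment`` holds 0/1 factor labels per item and is used to align the
    EFA factors to the declared subscales.
    """
    sol = efa(None, k=2, method="PAF", rotation="promax", corr=r)
    pattern, phi = sol.loadings, sol.phi
    # align factor columns to the assignment groups
    strength = np.zeros((2, 2))
    for f in (0, 1):
        mask = assignment == f
        strength[f] = np.abs(pattern[mask]).sum(axis=0)
    if strength[0, 1] + strength[1, 0] > strength[0, 0] + strength[1, 1]:
        pattern = pattern[:, ::-1]
        phi = phi[::-1][:, ::-1]
    # higher-order loading of each first-order factor on g
    gamma = np.sqrt(np.clip(phi[0, 1], 0.0, 1.0))
    g = pattern @ np.array([gamma, gamma])
    group = pattern * np.sqrt(max(0.0, 1.0 - gamma**2))
    return g, group


def reliability_report(
    data: BinaryDataMatrix,
    factor_assignment: dict[str, int] | np.ndarray,
    retest: BinaryDataMatrix | None = None,
    kind: str = "pearson",
) -> ReliabilityReport:
    """Internal-consistency summary for a two-factor binary scale.

    Inter-item and corrected item-total correlation ranges, Cronbach's
    alpha, McDonald's omega (general and per group factor) via a two-factor
    oblique EFA followed by Schmid-Leiman orthogonalization, variance
    decomposition, and optionally test-retest correlation of total scores.

    ``kind`` selects the correlation matrix behind the omega/variance
    decomposition: ``pearson`` (observed 0/1 scale, the conventional
    choice) or ``tetrachoric`` (latent scale, free of dichotomization
    attenuation).  IIC/ITC/alpha always use the observed scale.
    """
    x = data.values.astype(float)
    if isinstance(factor_assignment, dict):
        assignment = np.array([factor_assignment[c] for c in data.col_ids])
    else:
        assignment = np.asarray(factor_assignment)
    labels = np.unique(assignment)
    if labels.size != 2:
        raise ClassicalError("factor assignment must define exactly two factors")
    assignment = (assignment == labels[1]).astype(int)

    r = np.corrcoef(x, rowvar=False)
    off = r[np.triu_indices_from(r, k=1)]
    total = x.sum(axis=1)
    itc = np.array([
        np.corrcoef(x[:, j], total - x[:, j])[0, 1] for j in range(x.shape[1])
    ])

    if kind == "tetrachoric":
        r_model = tetrachoric_matrix(data).values
    elif kind == "pearson":
        r_model = r
    else:
        raise ClassicalError(f"unknown correlation kind {kind!r}")
    r_pd, _ = smooth_to_pd(r_model)
    g, group = _schmid_leiman(r_pd, assignment)
    var_total = float(r_pd.sum())
    omega_g = float(g.sum() ** 2 / var_total)

    omegas = []
    for f in (0, 1):
        mask = assignment == f
        sub_var = float(r_pd[np.ix_(mask, mask)].sum())
        num = g[mask].sum() ** 2 + group[mask, f].sum() ** 2
        omegas.append(float(num / sub_var))

    ortho = efa(None, k=2, method="PAF", rotation="varimax", corr=r_pd)
    per_factor = (ortho.loadings**2).sum(axis=0) / r_pd.shape[0]

    test_retest = None
    if retest is not None:
        if retest.values.shape[0] != x.shape[0] or (
            data.row_ids is not None
            and retest.row_ids is not None
            and data.row_ids != retest.row_ids
        ):
            raise ClassicalError("alignment-error: retest rows do not match")
        test_retest = float(
            np.corrcoef(total, retest.values.sum(axis=1))[0, 1]
        )

    return ReliabilityReport(
        alpha=float(cronbach_alpha(x)),
        iic_min=float(off.min()), iic_max=float(off.max()),
        itc_min=float(itc.min()), itc_max=float(itc.max()),
        omega_g=omega_g, omega_F1=omegas[0], omega_F2=omegas[1],
        variance_decomposition={
            "F1": float(per_factor[0]), "F2": float(per_factor[1]),
            "share_F1": float(per_factor[0] / per_factor.sum()),
            "share_F2": float(per_factor[1] / per_factor.sum()),
        },
        test_retest=test_retest,
    )
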