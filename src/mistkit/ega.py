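"""Exploratory graph analysis (EGA).

Dimensionality analysis via a regularized partial-correlation network: a
Gaussian graphical model estimated with the graphical lasso over a penalty
path, the penalty chosen by the extended Bayesian information criterion
(EBIC), and dimensions identified by Walktrap community detection on the
weighted network.  On top of the point estimate sit network loadings (the
network analogue of factor loadings), unique variable analysis (weighted
topological overlap for redundancy), a parametric bootstrap yielding item
stability and structural consistency, and the total entropy fit index
(TEFI) for comparing candidate partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from sklearn.covariance import graphical_lasso

from .classical import BinaryDataMatrix, CorrelationMatrix, smooth_to_pd, tetrachoric_matrix

__all__ = [
    "Network",
    "Partition",
    "EGAResult",
    "BootEGAResult",
    "UVAResult",
    "EGAError",
    "estimate_network",
    "detect_communities",
    "network_loadings",
    "uva_redundancy",
    "ega",
    "boot_ega",
    "tefi",
    "von_neumann_entropy",
]

EDGE_TOL = 1e-8


class EGAError(ValueError):
    pass


@dataclass
class Network:
    partial_correlations: np.ndarray
    n: int
    lambda_selected: float
    ebic: float
    gamma: float
    col_ids: list[str] | None = None

    @property
    def p(self) -> int:
        return self.partial_correlations.shape[0]

    @property
    def n_edges(self) -> int:
        w = self.partial_correlations
        return int(np.sum(np.abs(w[np.triu_indices(self.p, k=1)]) > EDGE_TOL))


@dataclass
class Partition:
    labels: dict[str, int]

    @property
    def n_dims(self) -> int:
        return len(set(self.labels.values()))

    def members(self, dim: int) -> set[str]:
        return {i for i, d in self.labels.items() if d == dim}

    def as_array(self, col_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in col_ids])


@dataclass
class EGAResult:
    network: Network
    partition: Partition
    network_loadings: np.ndarray
    dims: list[int]
    tefi: float


@dataclass
class BootEGAResult:
    n_dims_distribution: dict[int, int]
    median_dims: float
    ci: tuple[float, float]
    item_stability: dict[str, float]
    structural_consistency: dict[int, float]
    n_boot: int
    n_failures: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class UVAResult:
    wto: np.ndarray
    flagged_pairs: list[dict]
    threshold: float


def _precision_to_pcor(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


def estimate_network(
    corr: CorrelationMatrix | np.ndarray,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambdas=None,
    col_ids: list[str] | None = None,
) -> Network:
    """EBIC-selected graphical-lasso network as partial correlations.

    The penalty path runs log-spaced from the largest absolute off-diagonal
    correlation down to 1% of it; per penalty, EBIC = -2 loglik +
    E log n + 4 gamma E log p with E the edge count.  The minimal-EBIC
    model wins.  ``lambdas`` overrides the path (e.g. [0.0] for the
    unregularized limit).
    """
    if isinstance(corr, CorrelationMatrix):
        if col_ids is None:
            col_ids = corr.col_ids
        r = corr.values
    else:
        r = np.asarray(corr, dtype=float)
    r, _ = smooth_to_pd(r)
    p = r.shape[0]
    if col_ids is None:
        col_ids = [f"item_{j}" for j in range(p)]

    if lambdas is None:
        off = np.abs(r[np.triu_indices(p, k=1)])
        lam_max = off.max()
        if lam_max <= EDGE_TOL:
            return Network(
                partial_correlations=np.zeros((p, p)), n=n,
                lambda_selected=0.0, ebic=np.inf, gamma=gamma, col_ids=col_ids,
            )
        lambdas = np.geomspace(lam_max, 0.01 * lam_max, n_lambda)

    best = None
    since_best = 0
    for lam in lambdas:
        if since_best >= 20:
            # EBIC is past its minimum on the densifying path; skip the
            # expensive near-unpenalized tail
            break
        try:
            if lam <= 0:
                theta = np.linalg.inv(r)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # near-unpenalized fits stop at max_iter
                    _, theta = graphical_lasso(r, alpha=float(lam), max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        pcor = _precision_to_pcor(theta)
        edges = np.abs(pcor[np.triu_indices(p, k=1)]) > EDGE_TOL
        n_edges = int(edges.sum())
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            continue
        loglik = (n / 2.0) * (logdet - np.trace(r @ theta))
        ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)
        if best is None or ebic < best[0]:
            pcor_clean = np.where(np.abs(pcor) > EDGE_TOL, pcor, 0.0)
            best = (ebic, float(lam), pcor_clean)
            since_best = 0
        else:
            since_best += 1

    if best is None:
        raise EGAError("matrix-error: no penalty produced a valid network")
    ebic, lam, pcor = best
    return Network(
        partial_correlations=pcor, n=n, lambda_selected=lam,
        ebic=float(ebic), gamma=gamma, col_ids=col_ids,
    )


def detect_communities(network: Network, steps: int = 4) -> Partition:
    """Walktrap communities on the |partial correlation| weighted graph.

    Singleton communities are merged into the community with the greatest
    summed connection strength to the singleton.
    """
    w = np.abs(network.partial_correlations)
    p = network.p
    ii, jj = np.triu_indices(p, k=1)
    mask = w[ii, jj] > EDGE_TOL
    if not mask.any():
        raise EGAError("no-structure: the network has no edges")
    edges = list(zip(ii[mask], jj[mask]))
    weights = w[ii, jj][mask]
    g = ig.Graph(n=p, edges=edges)
    dendro = g.community_walktrap(weights=list(weights), steps=steps)
    membership = np.array(dendro.as_clustering().membership)

    # merge singletons into the strongest-connected community
    for _ in range(p):
        counts = {c: int((membership == c).sum()) for c in np.unique(membership)}
        singles = [c for c, cnt in counts.items() if cnt == 1]
        if not singles or len(counts) == 1:
            break
        moved = False
        for c in singles:
            node = int(np.where(membership == c)[0][0])
            strengths = {}
            for other in counts:
                if other == c:
                    continue
                strengths[other] = w[node, membership == other].sum()
            if strengths:
                target = max(strengths, key=lambda o: strengths[o])
                if strengths[target] > 0:
                    membership[node] = target
                    moved = True
        if not moved:
            break

    # relabel 1..K by first appearance
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for idx, c in enumerate(membership):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[network.col_ids[idx]] = relabel[c]
    return Partition(labels=labels)


def network_loadings(network: Network, partition: Partition) -> np.ndarray:
    """Standardized network loadings (p x K).

    The raw loading of item i on dimension d is its summed absolute edge
    weight to the members of d (node strength split by dimension); each
    dimension's column is standardized by the square root of the summed
    within-dimension strength of that dimension's own members, and signs
    are restored from the dominant edge sign.
    """
    w = network.partial_correlations
    ids = network.col_ids
    dims = sorted(set(partition.labels.values()))
    p = network.p
    raw = np.zeros((p, len(dims)))
    signed = np.zeros((p, len(dims)))
    member_idx = {
        d: [k for k, i in enumerate(ids) if partition.labels[i] == d] for d in dims
    }
    for k_dim, d in enumerate(dims):
        cols = member_idx[d]
        for i in range(p):
            others = [j for j in cols if j != i]
            raw[i, k_dim] = np.sum(np.abs(w[i, others]))
            signed[i, k_dim] = np.sum(w[i, others])
    std = raw.copy()
    for k_dim, d in enumerate(dims):
        denom = raw[member_idx[d], k_dim].sum()
        if denom > 0:
            std[:, k_dim] = raw[:, k_dim] / np.sqrt(denom)
    return std * np.where(signed < 0, -1.0, 1.0)


def uva_redundancy(
    network: Network,
    loadings: np.ndarray | None = None,
    partition: Partition | None = None,
    threshold: float = 0.25,
) -> UVAResult:
    """Unique variable analysis: weighted topological overlap per item pair.

    Pairs with wTO >= threshold are flagged as redundant; when loadings and
    a partition are given, the keep/drop suggestion retains the item with
    the higher main-to-cross network-loading ratio.
    """
    a = np.abs(network.partial_correlations)
    p = network.p
    strength = a.sum(axis=1)
    wto = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            num = float(a[i] @ a[j] - a[i, i] * a[j, i] - a[i, j] * a[j, j] + a[i, j])
            den = min(strength[i], strength[j]) + 1.0 - a[i, j]
            wto[i, j] = wto[j, i] = num / den if den > 0 else 0.0

    flagged = []
    ids = network.col_ids
    dims = sorted(set(partition.labels.values())) if partition else None
    for i in range(p):
        for j in range(i + 1, p):
            if wto[i, j] < threshold:
                continue
            entry = {"pair": (ids[i], ids[j]), "wto": float(wto[i, j])}
            if loadings is not None and partition is not None:
                ratios = []
                for node in (i, j):
                    own = dims.index(partition.labels[ids[node]])
                    main = abs(loadings[node, own])
                    cross = max(
                        (abs(loadings[node, kk]) for kk in range(len(dims)) if kk != own),
                        default=0.0,
                    )
                    ratios.append(main / (cross + 1e-12))
                keep = ids[i] if ratios[0] >= ratios[1] else ids[j]
                entry["keep"] = keep
                entry["drop"] = ids[j] if keep == ids[i] else ids[i]
                entry["loading_ratios"] = {ids[i]: ratios[0], ids[j]: ratios[1]}
            flagged.append(entry)
    return UVAResult(wto=wto, flagged_pairs=flagged, threshold=threshold)


def ega(
    data: BinaryDataMatrix | None = None,
    corr: CorrelationMatrix | np.ndarray | None = None,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    steps: int = 4,
    col_ids: list[str] | None = None,
) -> EGAResult:
    """Full EGA pipeline: network estimation -> Walktrap -> loadings -> TEFI."""
    if corr is None:
        if data is None:
            raise EGAError("need data or a correlation matrix")
        corr = tetrachoric_matrix(data)
        n = data.n
        col_ids = data.col_ids
    if n is None:
        raise EGAError("sample size n is required with a precomputed matrix")
    net = estimate_network(corr, n=n, gamma=gamma, n_lambda=n_lambda, col_ids=col_ids)
    part = detect_communities(net, steps=steps)
    loads = network_loadings(net, part)
    r = corr.values if isinstance(corr, CorrelationMatrix) else np.asarray(corr)
    fit = tefi(r, part, col_ids=net.col_ids)
    return EGAResult(
        network=net, partition=part, network_loadings=loads,
        dims=sorted(set(part.labels.values())), tefi=fit,
    )


def _align_partitions(
    empirical: Partition, replicate: Partition, col_ids: list[str]
) -> dict[int, int]:
    """Map replicate community label -> empirical dimension by max Jaccard.

    Ties break by larger intersection, then lower empirical label.
    """
    mapping: dict[int, int] = {}
    emp_dims = sorted(set(empirical.labels.values()))
    for rc in sorted(set(replicate.labels.values())):
        rmem = {i for i in col_ids if replicate.labels[i] == rc}
        best = None
        for ed in emp_dims:
            emem = empirical.members(ed)
            inter = len(rmem & emem)
            union = len(rmem | emem)
            jac = inter / union if union else 0.0
            key = (jac, inter, -ed)
            if best is None or key > best[0]:
                best = (key, ed)
        mapping[rc] = best[1]
    return mapping


def boot_ega(
    data: BinaryDataMatrix,
    n_boot: int = 500,
    seed: int | np.random.Generator | None = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    steps: int = 4,
) -> BootEGAResult:
    """Parametric bootstrap EGA: item stability and structural consistency.

    Replicates are continuous multivariate-normal draws from the smoothed
    empirical tetrachoric correlation matrix, re-analyzed with Pearson
    correlations.  Replicate communities are aligned to the empirical
    partition by maximal Jaccard overlap; item stability is the proportion
    of replicates placing an item in its aligned empirical dimension, and
    structural consistency the proportion reproducing a dimension's item
    set exactly.
    """
    rng = np.random.default_rng(seed)
    emp_corr = tetrachoric_matrix(data)
    emp = ega(corr=emp_corr, n=data.n, gamma=gamma, n_lambda=n_lambda,
              steps=steps, col_ids=data.col_ids)
    col_ids = data.col_ids
    chol = np.linalg.cholesky(emp_corr.values + 1e-10 * np.eye(data.p))

    stab = {i: 0 for i in col_ids}
    cons = {d: 0 for d in emp.dims}
    dims_counts: dict[int, int] = {}
    failures = 0
    for _ in range(n_boot):
        z = rng.standard_normal((data.n, data.p)) @ chol.T
        r = np.corrcoef(z, rowvar=False)
        try:
            net = estimate_network(r, n=data.n, gamma=gamma,
                                   n_lambda=n_lambda, col_ids=col_ids)
            part = detect_communities(net, steps=steps)
        except EGAError:
            failures += 1
            continue
        k = part.n_dims
        dims_counts[k] = dims_counts.get(k, 0) + 1
        mapping = _align_partitions(emp.partition, part, col_ids)
        for i in col_ids:
            if mapping[part.labels[i]] == emp.partition.labels[i]:
                stab[i] += 1
        rep_sets = {
            rc: {i for i in col_ids if part.labels[i] == rc}
            for rc in set(part.labels.values())
        }
        for d in emp.dims:
            if emp.partition.members(d) in rep_sets.values():
                cons[d] += 1

    n_ok = n_boot - failures
    warnings = []
    if failures > 0.1 * n_boot:
        warnings.append(f"{failures}/{n_boot} bootstrap replicates failed")
    if n_ok == 0:
        raise EGAError("all bootstrap replicates failed")
    all_dims = np.repeat(
        list(dims_counts.keys()), list(dims_counts.values())
    ).astype(float)
    return BootEGAResult(
        n_dims_distribution=dict(sorted(dims_counts.items())),
        median_dims=float(np.median(all_dims)),
        ci=(float(np.quantile(all_dims, 0.025)), float(np.quantile(all_dims, 0.975))),
        item_stability={i: stab[i] / n_ok for i in col_ids},
        structural_consistency={d: cons[d] / n_ok for d in emp.dims},
        n_boot=n_boot, n_failures=failures, warnings=warnings,
    )


def von_neumann_entropy(mat: np.ndarray) -> float:
    """Entropy of the trace-normalized matrix: -sum lam log lam."""
    mat = np.asarray(mat, dtype=float)
    lam = np.linalg.eigvalsh(mat / np.trace(mat))
    lam = lam[lam > 1e-12]
    return float(-np.sum(lam * np.log(lam)))


def tefi(
    corr: np.ndarray | CorrelationMatrix,
    partition: Partition,
    col_ids: list[str] | None = None,
) -> float:
    """Total entropy fit index of a partition; lower = better fit.

    Combines the von Neumann entropies of the full correlation matrix and
    the per-dimension submatrices:
    TEFI = (mean(H_d) - H_total) + (H_total - sum(H_d)) * sqrt(K).
    """
    if isinstance(corr, CorrelationMatrix):
        if col_ids is None:
            col_ids = corr.col_ids
        r = corr.values
    else:
        r = np.asarray(corr, dtype=float)
    r, _ = smooth_to_pd(np.abs(r))
    p = r.shape[0]
    if col_ids is None:
        col_ids = [f"item_{j}" for j in range(p)]
    h_total = von_neumann_entropy(r)
    h_parts = []
    for d in sorted(set(partition.labels.values())):
        idx = [k for k, i in enumerate(col_ids) if partition.labels[i] == d]
        sub = r[np.ix_(idx, idx)]
        h_parts.append(von_neumann_entropy(sub))
    h_parts = np.asarray(h_parts)
    k = len(h_parts)
    return float(
        (h_parts.mean() - h_total) + (h_total - h_parts.sum()) * np.sqrt(k)
    )
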