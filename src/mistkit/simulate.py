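"""Synthetic respondents and item pools.

Respondents follow a higher-order two-factor 3PL model: a general veracity
discernment ability theta_V ~ N(0,1) drives correlated real-news and
fake-news detection abilities,

    theta_r = gamma_r * theta_V + sqrt(1 - gamma_r^2) * eps_r,

and each item is answered correctly with the 3PL probability at the
relevant first-order ability (guessing floor c = 0.5).  A response-bias
mixture overrides a fraction ``bias_tau`` of responses with a pure labeling
bias ("fake" with probability ``bias_pi``), producing distrust/naivete
patterns independent of ability.

Item pools with planted structure (good two- or four-factor items, junk
items, cross-loaded items, redundant pairs) are generated from a
thresholded common-factor model and serve as ground-truthed fixtures for
the selection and graph-analysis machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bank import Item, ItemBank
from .classical import BinaryDataMatrix
from .irt import icc_3pl
from .scoring import ResponseVector

__all__ = [
    "RespondentModel",
    "PoolSpec",
    "SimConfig",
    "SimulateError",
    "simulate_responses",
    "simulate_paired_responses",
    "simulate_item_pool",
    "responses_to_binary",
]

# Default generating ranges mirror the calibrated full-scale bank
# (a roughly 2-8.6, b roughly -1.3-0.53).
DEFAULT_A_RANGE = (2.0, 8.6)
DEFAULT_B_RANGE = (-1.3, 0.53)


class SimulateError(ValueError):
    pass


@dataclass
class RespondentModel:
    """Higher-order ability structure plus response-bias mixture."""

    gamma_r: float = 0.8
    gamma_f: float = 0.8
    bias_tau: float = 0.0
    bias_pi: float = 0.5
    bias_per_respondent: bool = False

    def __post_init__(self) -> None:
        for name in ("gamma_r", "gamma_f", "bias_tau", "bias_pi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulateError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PoolSpec:
    """Planted structure of a synthetic item pool."""

    n_factors: int = 2
    items_per_factor: int = 10
    n_junk: int = 0
    n_crossloaded: int = 0
    n_redundant_pairs: int = 0
    loading_range: tuple[float, float] = (0.55, 0.8)
    cross_loading: float = 0.45
    threshold_range: tuple[float, float] = (-0.8, 0.8)
    higher_order: bool = False
    factor_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.n_factors < 1 or self.items_per_factor < 1:
            raise SimulateError("spec-error: need at least one factor and item")
        if self.items_per_factor < 2:
            raise SimulateError("spec-error: factors need >= 2 items")


@dataclass
class SimConfig:
    n: int = 1000
    seed: int = 0
    id_prefix: str = "R"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulateError("n must be >= 1")


def simulate_responses(
    bank: ItemBank,
    model: RespondentModel,
    config: SimConfig,
    thetas: np.ndarray | None = None,
) -> tuple[list[ResponseVector], dict]:
    """Draw labeled responses from the higher-order two-factor 3PL model.

    Returns (responses, truth) where ``truth`` carries the generating
    theta_V / theta_r / theta_f arrays and the seed.  ``thetas`` may pin the
    general ability (one value per respondent) for deterministic scenarios.
    """
    for it in bank.items:
        if it.a is None or it.b is None:
            raise SimulateError(f"missing-parameter: item {it.id} lacks a/b")

    rng = np.random.default_rng(config.seed)
    n = config.n
    theta_v = (
        np.full(n, float(thetas)) if np.isscalar(thetas)
        else np.asarray(thetas, dtype=float) if thetas is not None
        else rng.standard_normal(n)
    )
    eps_r = rng.standard_normal(n)
    eps_f = rng.standard_normal(n)
    theta_r = model.gamma_r * theta_v + np.sqrt(1 - model.gamma_r**2) * eps_r
    theta_f = model.gamma_f * theta_v + np.sqrt(1 - model.gamma_f**2) * eps_f

    a = np.array([it.a for it in bank.items])
    b = np.array([it.b for it in bank.items])
    c = np.array([it.c if it.c is not None else 0.5 for it in bank.items])
    is_real = np.array([it.veracity == "real" for it in bank.items])
    theta_use = np.where(is_real[None, :], theta_r[:, None], theta_f[:, None])
    p_correct = icc_3pl(a[None, :], b[None, :], c[None, :], theta_use)

    correct = rng.random((n, bank.k)) < p_correct
    if model.bias_per_respondent:
        biased = (rng.random(n) < model.bias_tau)[:, None] & np.ones(
            (1, bank.k), dtype=bool
        )
    else:
        biased = rng.random((n, bank.k)) < model.bias_tau
    bias_fake = rng.random((n, bank.k)) < model.bias_pi

    responses = []
    for i in range(n):
        labels = {}
        for j, it in enumerate(bank.items):
            if biased[i, j]:
                labels[it.id] = "fake" if bias_fake[i, j] else "real"
            elif correct[i, j]:
                labels[it.id] = it.veracity
            else:
                labels[it.id] = "real" if it.veracity == "fake" else "fake"
        responses.append(
            ResponseVector(respondent_id=f"{config.id_prefix}{i:05d}", labels=labels)
        )
    truth = {
        "theta_V": theta_v, "theta_r": theta_r, "theta_f": theta_f,
        "seed": config.seed,
    }
    return responses, truth


def _draw_labels(bank, theta_r, theta_f, model, rng):
    n = theta_r.size
    a = np.array([it.a for it in bank.items])
    b = np.array([it.b for it in bank.items])
    c = np.array([it.c if it.c is not None else 0.5 for it in bank.items])
    is_real = np.array([it.veracity == "real" for it in bank.items])
    theta_use = np.where(is_real[None, :], theta_r[:, None], theta_f[:, None])
    p_correct = icc_3pl(a[None, :], b[None, :], c[None, :], theta_use)
    correct = rng.random((n, bank.k)) < p_correct
    biased = rng.random((n, bank.k)) < model.bias_tau
    bias_fake = rng.random((n, bank.k)) < model.bias_pi
    out = []
    for i in range(n):
        labels = {}
        for j, it in enumerate(bank.items):
            if biased[i, j]:
                labels[it.id] = "fake" if bias_fake[i, j] else "real"
            elif correct[i, j]:
                labels[it.id] = it.veracity
            else:
                labels[it.id] = "real" if it.veracity == "fake" else "fake"
        out.append(ResponseVector(respondent_id=f"R{i:05d}", labels=labels))
    return out


def simulate_paired_responses(
    bank: ItemBank,
    model: RespondentModel,
    config: SimConfig,
    delta_r: float = 0.0,
    delta_f: float = 0.0,
) -> tuple[list[ResponseVector], list[ResponseVector], dict]:
    """Pre/post responses for a within-subject intervention design.

    Each respondent keeps their pre-test abilities at post-test, shifted by
    ``delta_r`` / ``delta_f`` standard deviations on the real-news and
    fake-news detection abilities respectively (an intervention that trains
    one facet without the other leaves the untrained ability untouched).
    """
    for it in bank.items:
        if it.a is None or it.b is None:
            raise SimulateError(f"missing-parameter: item {it.id} lacks a/b")
    rng = np.random.default_rng(config.seed)
    n = config.n
    theta_v = rng.standard_normal(n)
    theta_r = model.gamma_r * theta_v + np.sqrt(1 - model.gamma_r**2) * rng.standard_normal(n)
    theta_f = model.gamma_f * theta_v + np.sqrt(1 - model.gamma_f**2) * rng.standard_normal(n)
    pre = _draw_labels(bank, theta_r, theta_f, model, rng)
    post = _draw_labels(bank, theta_r + delta_r, theta_f + delta_f, model, rng)
    truth = {"theta_V": theta_v, "theta_r": theta_r, "theta_f": theta_f,
             "delta_r": delta_r, "delta_f": delta_f, "seed": config.seed}
    return pre, post, truth


def responses_to_binary(bank: ItemBank, responses) -> BinaryDataMatrix:
    """Convert labeled responses to a scored 0/1 correctness matrix."""
    ids = bank.item_ids
    key = {it.id: it.veracity for it in bank.items}
    rows = []
    row_ids = []
    for resp in responses:
        rows.append([1 if resp.labels.get(i) == key[i] else 0 for i in ids])
        row_ids.append(resp.respondent_id)
    return BinaryDataMatrix(
        values=np.array(rows, dtype=int), row_ids=row_ids, col_ids=list(ids)
    )


def simulate_item_pool(
    spec: PoolSpec, config: SimConfig
) -> tuple[ItemBank, BinaryDataMatrix, dict]:
    """Binary item pool from a thresholded common-factor model.

    correct_i = 1 iff lambda_i * theta_F(i) (+ cross terms) + e_i > tau_i.
    Junk items are pure noise; redundant pairs share an extra minor factor.
    Returns (bank, data, truth) where ``truth`` labels every planted
    property (factor membership, junk, cross-loaded, redundant pairs,
    loadings, thresholds).
    """
    rng = np.random.default_rng(config.seed)
    f = spec.n_factors
    n_good = f * spec.items_per_factor
    p = n_good + spec.n_junk + spec.n_crossloaded + 2 * spec.n_redundant_pairs
    if p < f:
        raise SimulateError("spec-error: fewer items than factors")
    n = config.n

    if spec.higher_order:
        g = rng.standard_normal(n)
        gam = np.sqrt(max(spec.factor_corr, 0.0))
        factors = gam * g[:, None] + np.sqrt(1 - gam**2) * rng.standard_normal((n, f))
    elif spec.factor_corr > 0:
        phi = np.full((f, f), spec.factor_corr)
        np.fill_diagonal(phi, 1.0)
        factors = rng.standard_normal((n, f)) @ np.linalg.cholesky(phi).T
    else:
        factors = rng.standard_normal((n, f))

    loadings = np.zeros((p, f))
    kinds = []
    factor_of = np.full(p, -1)
    idx = 0
    for fac in range(f):
        for _ in range(spec.items_per_factor):
            loadings[idx, fac] = rng.uniform(*spec.loading_range)
            factor_of[idx] = fac
            kinds.append("good")
            idx += 1
    for _ in range(spec.n_junk):
        kinds.append("junk")
        idx += 1
    for j in range(spec.n_crossloaded):
        f1, f2 = j % f, (j + 1) % f
        loadings[idx, f1] = spec.cross_loading
        loadings[idx, f2] = spec.cross_loading
        factor_of[idx] = f1
        kinds.append("crossloaded")
        idx += 1
    redundant_pairs = []
    for j in range(spec.n_redundant_pairs):
        fac = j % f
        lam = rng.uniform(*spec.loading_range)
        for _ in range(2):
            loadings[idx, fac] = lam
            factor_of[idx] = fac
            kinds.append("redundant")
            idx += 1
        redundant_pairs.append((idx - 2, idx - 1))

    # shared minor factor for each redundant pair
    minor = rng.standard_normal((n, max(1, spec.n_redundant_pairs)))
    common = factors @ loadings.T
    unique_var = np.clip(1.0 - np.sum(loadings**2, axis=1), 0.05, 1.0)
    for j, (i1, i2) in enumerate(redundant_pairs):
        share = 0.8 * np.sqrt(unique_var[[i1, i2]])
        common[:, i1] += share[0] * minor[:, j]
        common[:, i2] += share[1] * minor[:, j]
        unique_var[[i1, i2]] *= 1 - 0.8**2

    noise = rng.standard_normal((n, p)) * np.sqrt(unique_var)[None, :]
    tau = rng.uniform(*spec.threshold_range, size=p)
    values = (common + noise > tau[None, :]).astype(int)

    # half real / half fake veracity labels, alternating per factor block
    items = []
    for j in range(p):
        veracity = "real" if (factor_of[j] % 2 == 0 and factor_of[j] >= 0) else "fake"
        items.append(Item(
            id=f"POOL_{j:03d}",
            headline=f"synthetic pool headline {j}",
            veracity=veracity,
        ))
    bank = ItemBank(name="custom", items=items, version=f"pool-seed{config.seed}")
    data = BinaryDataMatrix(
        values=values,
        row_ids=[f"{config.id_prefix}{i:05d}" for i in range(n)],
        col_ids=[it.id for it in items],
    )
    truth = {
        "kinds": kinds,
        "factor_of": factor_of,
        "loadings": loadings,
        "thresholds": tau,
        "redundant_pairs": [
            (items[i1].id, items[i2].id) for i1, i2 in redundant_pairs
        ],
        "junk_ids": [items[j].id for j in range(p) if kinds[j] == "junk"],
        "crossloaded_ids": [
            items[j].id for j in range(p) if kinds[j] == "crossloaded"
        ],
        "seed": config.seed,
    }
    return bank, data, truth
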