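"""Item-selection decision tree for building a balanced true/false scale.

The pipeline mirrors the standard scale-development sequence on a scored
0/1 matrix: (i) iterated two-factor EFA dropping items whose largest
loading falls below a floor, (ii) a cross-loading screen, (iii) a 3PL-based
communality filter (items calibrated per veracity class with the guessing
floor fixed at 0.5), (iv) Cronbach's-alpha pruning, (v) an optional DIF
screen, and finally a discrimination/difficulty-based selection of a
balanced item set.

The final selection formalizes "high discrimination over a wide range of
difficulties" as greedy binning: difficulties are split into equal-width
bins and the highest-discrimination item is taken per bin, falling back to
the nearest non-empty bin.  Content/topic diversity is not automated; the
trace carries a manual checklist instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bank import ItemBank
from .classical import (
    BinaryDataMatrix,
    alpha_if_deleted_prune,
    communalities_from_3pl,
    efa,
)
from .irt import IRTParams, calibrate_3pl_em, dif_likelihood_ratio

__all__ = [
    "SelectionCriteria",
    "SelectionTrace",
    "SelectionError",
    "run_decision_tree",
    "irt_final_selection",
]


class SelectionError(ValueError):
    pass


@dataclass
class SelectionCriteria:
    loading_min: float = 0.40
    crossloading_max: float = 0.30
    communality_min: float = 0.40
    alpha_delta: float = 0.001
    a_min: float = 2.00
    b_window: tuple[float, float] = (-0.50, 0.50)
    n_per_factor: int = 10

    def __post_init__(self) -> None:
        if self.n_per_factor < 1:
            raise SelectionError("n_per_factor must be >= 1")


@dataclass
class SelectionTrace:
    stages: list[dict] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)
    params: IRTParams | None = None
    checklist: list[str] = field(default_factory=list)

    def stage(self, name: str) -> dict:
        for st in self.stages:
            if st["stage"] == name:
                return st
        raise KeyError(name)


def _subset(data: BinaryDataMatrix, keep_ids: list[str]) -> BinaryDataMatrix:
    idx = [data.col_ids.index(i) for i in keep_ids]
    return BinaryDataMatrix(
        values=data.values[:, idx], row_ids=data.row_ids, col_ids=list(keep_ids)
    )


def run_decision_tree(
    data: BinaryDataMatrix,
    bank: ItemBank,
    criteria: SelectionCriteria = SelectionCriteria(),
    groups: dict[str, np.ndarray] | None = None,
    run_dif: bool | None = None,
) -> SelectionTrace:
    """Execute the staged selection pipeline, logging removals per stage.

    ``groups`` optionally maps a grouping name (e.g. "gender") to binary
    labels per respondent for the DIF screen; items are removed if flagged
    on any grouping.
    """
    trace = SelectionTrace()
    keep = list(data.col_ids)
    key = {it.id: it.veracity for it in bank.items}

    # (i) iterated two-factor EFA: drop items with max |loading| < floor
    removed_total, iterations = [], 0
    while True:
        iterations += 1
        sol = efa(_subset(data, keep), k=2, method="PAF", rotation="varimax")
        max_load = np.max(np.abs(sol.loadings), axis=1)
        drop = [keep[j] for j in np.where(max_load < criteria.loading_min)[0]]
        if not drop:
            break
        removed_total.extend(drop)
        keep = [i for i in keep if i not in drop]
        if len(keep) < 4:
            raise SelectionError("pool-exhausted during loading filter")
    trace.stages.append({
        "stage": "loading", "removed": removed_total,
        "iterations": iterations, "surviving": len(keep),
    })

    # (ii) cross-loading screen on the surviving two-factor solution
    sol = efa(_subset(data, keep), k=2, method="PAF", rotation="varimax")
    absload = np.abs(sol.loadings)
    secondary = np.sort(absload, axis=1)[:, -2]
    drop = [keep[j] for j in np.where(secondary > criteria.crossloading_max)[0]]
    keep = [i for i in keep if i not in drop]
    trace.stages.append({
        "stage": "crossloading", "removed": drop, "iterations": 1,
        "surviving": len(keep),
    })

    # (iii) 3PL communality filter, calibrated per veracity class, iterated
    removed_total, iterations = [], 0
    while True:
        iterations += 1
        params = _calibrate_per_class(data, keep, key)
        h2 = communalities_from_3pl(params)
        order = {iid: k for k, iid in enumerate(params.item_ids)}
        drop = [i for i in keep if h2[order[i]] < criteria.communality_min]
        if not drop:
            break
        removed_total.extend(drop)
        keep = [i for i in keep if i not in drop]
        if len(keep) < 4:
            raise SelectionError("pool-exhausted during communality filter")
    trace.stages.append({
        "stage": "communality", "removed": removed_total,
        "iterations": iterations, "surviving": len(keep),
    })

    # (iv) Cronbach's alpha pruning
    kept, prune_trace = alpha_if_deleted_prune(
        _subset(data, keep), delta=criteria.alpha_delta
    )
    drop = [i for i in keep if i not in kept]
    keep = kept
    trace.stages.append({
        "stage": "alpha", "removed": drop, "iterations": len(prune_trace) + 1,
        "surviving": len(keep), "detail": prune_trace,
    })

    # (v) DIF screen: remove items flagged on any grouping
    if run_dif is None:
        run_dif = bool(groups)
    if run_dif and groups:
        flagged: set[str] = set()
        sub = _subset(data, keep)
        for name, labels in groups.items():
            res = dif_likelihood_ratio(
                sub.values, np.asarray(labels), item_ids=keep
            )
            flagged |= {i for i, fl in zip(res.item_ids, res.flagged) if fl}
        drop = sorted(flagged)
        keep = [i for i in keep if i not in flagged]
        trace.stages.append({
            "stage": "dif", "removed": drop, "iterations": 1,
            "surviving": len(keep),
        })
    else:
        trace.stages.append({
            "stage": "dif", "removed": [], "iterations": 0,
            "surviving": len(keep), "skipped": not (run_dif and groups),
        })

    n_real = sum(key[i] == "real" for i in keep)
    n_fake = len(keep) - n_real
    if min(n_real, n_fake) < criteria.n_per_factor:
        raise SelectionError(
            f"pool-exhausted: {n_real} real / {n_fake} fake survivors cannot "
            f"fill {criteria.n_per_factor} per factor"
        )

    trace.survivors = keep
    trace.params = _calibrate_per_class(data, keep, key)
    trace.checklist = [
        "review surviving headlines for topical repetition",
        "confirm coverage across news areas (politics, science, health, economy)",
        "confirm no two selected items share near-identical wording",
    ]
    return trace


def _calibrate_per_class(
    data: BinaryDataMatrix, keep: list[str], key: dict[str, str]
) -> IRTParams:
    """Calibrate real and fake items as separate unidimensional 3PL models."""
    a = np.empty(len(keep))
    b = np.empty(len(keep))
    for veracity in ("real", "fake"):
        ids = [i for i in keep if key[i] == veracity]
        if not ids:
            continue
        sub = _subset(data, ids)
        res = calibrate_3pl_em(sub.values, item_ids=ids)
        for iid, aj, bj in zip(ids, res.params.a, res.params.b):
            j = keep.index(iid)
            a[j], b[j] = aj, bj
    return IRTParams(a=a, b=b, c=np.full(len(keep), 0.5), item_ids=list(keep))


def irt_final_selection(
    params: IRTParams,
    bank: ItemBank,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> dict:
    """Greedy difficulty-binned selection of a balanced high-a item set.

    Per veracity class: candidates with a >= a_min are ranked by a; the
    pooled difficulty range is split into ``n_per_factor`` equal-width bins
    and the highest-a candidate in each bin is chosen, falling back to the
    nearest unused candidate (by bin distance, then a) when a bin is empty.
    Returns the balanced set, per-bin rankings, and a warning when a class
    cannot be filled.
    """
    key = {it.id: it.veracity for it in bank.items}
    out: dict = {"selected": {}, "bins": {}, "warnings": [], "checklist": [
        "vet selected items for content diversity before fielding",
    ]}
    ids = params.item_ids or [f"item_{j}" for j in range(params.n_items)]
    b_all = params.b
    lo, hi = float(b_all.min()), float(b_all.max())
    if hi <= lo:
        hi = lo + 1e-6
    edges = np.linspace(lo, hi, criteria.n_per_factor + 1)

    for veracity in ("real", "fake"):
        cand = [
            (iid, float(params.a[j]), float(params.b[j]))
            for j, iid in enumerate(ids)
            if key.get(iid) == veracity and params.a[j] >= criteria.a_min
        ]
        bins: dict[int, list] = {k: [] for k in range(criteria.n_per_factor)}
        for iid, a_j, b_j in cand:
            k = int(np.clip(np.searchsorted(edges, b_j, side="right") - 1,
                            0, criteria.n_per_factor - 1))
            bins[k].append((iid, a_j, b_j))
        for k in bins:
            bins[k].sort(key=lambda t: -t[1])
        chosen: list[str] = []
        used: set[str] = set()
        for k in range(criteria.n_per_factor):
            pick = next((t for t in bins[k] if t[0] not in used), None)
            if pick is None:
                # nearest non-empty bin, then highest a
                fallback = sorted(
                    (t for kk in bins for t in bins[kk] if t[0] not in used),
                    key=lambda t: (abs(int(np.clip(
                        np.searchsorted(edges, t[2], side="right") - 1,
                        0, criteria.n_per_factor - 1)) - k), -t[1]),
                )
                pick = fallback[0] if fallback else None
            if pick is None:
                out["warnings"].append(
                    f"insufficient {veracity} items meeting a >= {criteria.a_min}; "
                    f"selected {len(chosen)} of {criteria.n_per_factor}"
                )
                break
            chosen.append(pick[0])
            used.add(pick[0])
        out["selected"][veracity] = chosen
        out["bins"][veracity] = bins
    out["balanced"] = (
        len(out["selected"]["real"]) == len(out["selected"]["fake"])
        == criteria.n_per_factor
    )
    return out
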