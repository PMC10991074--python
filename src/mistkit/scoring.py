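"""Verification-done scoring.

A respondent labels each headline ``real`` or ``fake``.  Five quantities
summarize the response vector against a bank's answer key:

* ``V`` — veracity discernment: total number of correct judgments,
* ``r`` — real-news detection: real items correctly labeled real,
* ``f`` — fake-news detection: fake items correctly labeled fake,
* ``d`` — distrust bias: excess of "fake" labels over the true number of
  fake items (over-skepticism),
* ``n`` — naivete bias: excess of "real" labels over the true number of
  real items (over-gullibility).

By construction ``V = r + f`` and at most one of ``d``/``n`` is nonzero for
complete responses; on a balanced bank ``d - n = f - r``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank, NormTable

__all__ = [
    "ResponseVector",
    "VerificationScores",
    "ScoringError",
    "score_responses",
    "score_matrix",
    "scores_to_frame",
    "read_responses_csv",
    "score_at_percentile",
    "percentile_rank",
    "cohort_norm_report",
]

MISSING = "missing"
LABELS = ("real", "fake")


class ScoringError(ValueError):
    """Raised for malformed or incomplete response data."""


@dataclass
class ResponseVector:
    """One respondent's labels, keyed by item id (``real``/``fake``/``missing``)."""

    respondent_id: str
    labels: dict[str, str]

    def __post_init__(self) -> None:
        for iid, lab in self.labels.items():
            if lab not in LABELS and lab != MISSING:
                raise ScoringError(
                    f"respondent {self.respondent_id!r}, item {iid!r}: label must be "
                    f"'real', 'fake' or 'missing', got {lab!r}"
                )


@dataclass
class VerificationScores:
    """The five Verification-done quantities for one respondent."""

    respondent_id: str
    V: int
    r: int
    f: int
    d: int
    n: int
    k: int
    k_real: int
    k_fake: int
    n_answered: int | None = None
    prorated_V: float | None = None

    def as_dict(self) -> dict:
        return {
            "respondent_id": self.respondent_id,
            "V": self.V, "r": self.r, "f": self.f, "d": self.d, "n": self.n,
        }


def score_responses(
    bank: ItemBank, responses: ResponseVector, allow_missing: bool = False
) -> VerificationScores:
    """Score one respondent on a bank.

    Strict by default: any missing label raises.  With ``allow_missing=True``
    only answered items are counted and a prorated V (``V * k / answered``)
    is attached; nothing is imputed.
    """
    bank_ids = set(bank.item_ids)
    unknown = set(responses.labels) - bank_ids
    if unknown:
        raise ScoringError(
            f"respondent {responses.respondent_id!r}: labels for unknown items "
            f"{sorted(unknown)[:5]}"
        )

    labels = {i: responses.labels.get(i, MISSING) for i in bank.item_ids}
    answered = {i: l for i, l in labels.items() if l != MISSING}
    if not answered:
        raise ScoringError(
            f"respondent {responses.respondent_id!r}: no non-missing labels"
        )
    if len(answered) < bank.k and not allow_missing:
        missing = [i for i, l in labels.items() if l == MISSING]
        raise ScoringError(
            f"respondent {responses.respondent_id!r}: {len(missing)} missing "
            f"labels (e.g. {missing[:3]}); pass allow_missing=True to score "
            "answered items only"
        )

    real_ids = [i for i in bank.real_ids if i in answered]
    fake_ids = [i for i in bank.fake_ids if i in answered]
    k_real, k_fake = len(real_ids), len(fake_ids)
    r = sum(answered[i] == "real" for i in real_ids)
    f = sum(answered[i] == "fake" for i in fake_ids)
    n_fake_labels = sum(l == "fake" for l in answered.values())
    n_real_labels = sum(l == "real" for l in answered.values())
    d = max(0, n_fake_labels - k_fake)
    n = max(0, n_real_labels - k_real)

    n_answered = len(answered)
    return VerificationScores(
        respondent_id=responses.respondent_id,
        V=r + f, r=r, f=f, d=d, n=n,
        k=bank.k, k_real=len(bank.real_ids), k_fake=len(bank.fake_ids),
        n_answered=n_answered,
        prorated_V=(r + f) * bank.k / n_answered if n_answered < bank.k else None,
    )


def score_matrix(
    bank: ItemBank,
    table: Iterable[ResponseVector],
    allow_missing: bool = False,
) -> tuple[list[VerificationScores], dict]:
    """Score many respondents; preserves row order and attaches a summary.

    Per-row errors are re-raised with the offending row index.
    """
    scores: list[VerificationScores] = []
    for idx, resp in enumerate(table):
        try:
            scores.append(score_responses(bank, resp, allow_missing=allow_missing))
        except ScoringError as exc:
            raise ScoringError(f"row {idx}: {exc}") from exc
    frame = scores_to_frame(scores)
    summary = {
        "n": len(scores),
        "mean": frame[["V", "r", "f", "d", "n"]].mean().to_dict(),
        "sd": frame[["V", "r", "f", "d", "n"]].std(ddof=1).to_dict(),
    }
    return scores, summary


def scores_to_frame(scores: Sequence[VerificationScores]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in scores]).set_index("respondent_id")


def read_responses_csv(path: str | Path) -> list[ResponseVector]:
    """Read wide responses CSV: respondent_id column then one column per item.

    Cell values are ``real``/``fake``/``NA`` (empty cells also count as NA).
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "respondent_id":
        raise ScoringError("first CSV column must be 'respondent_id'")
    out = []
    item_cols = list(df.columns[1:])
    for _, row in df.iterrows():
        labels = {}
        for col in item_cols:
            val = row[col]
            if pd.isna(val) or str(val).upper() == "NA":
                labels[col] = MISSING
            else:
                labels[col] = str(val).strip().lower()
        out.append(ResponseVector(respondent_id=str(row["respondent_id"]), labels=labels))
    return out


def score_at_percentile(norms: NormTable, percentile: int) -> int:
    """Exact read of the norm grid at a percentile on the 0-100-by-5 grid."""
    if not norms.grid:
        raise ScoringError(f"norm table for {norms.dimension} carries no grid")
    if percentile not in norms.grid:
        raise ScoringError(
            f"percentile {percentile} is off the 0-100-by-5 grid (no interpolation)"
        )
    return norms.grid[percentile]


def percentile_rank(norms: NormTable, score: int) -> int:
    """Largest grid percentile whose norm score is <= the observed score.

    The grid repeats scores across neighbouring percentiles; ties resolve to
    the largest qualifying percentile.  Returns 0 when the score falls below
    the entire grid.
    """
    if not norms.grid:
        raise ScoringError(f"norm table for {norms.dimension} carries no grid")
    _, hi = norms.score_range
    if score < 0 or score > hi:
        raise ScoringError(
            f"score {score} outside the {norms.dimension} range [0, {hi}]"
        )
    qualifying = [p for p, s in norms.grid.items() if s <= score]
    return max(qualifying) if qualifying else 0


def cohort_norm_report(
    scores: Sequence[VerificationScores],
    norms: Mapping[str, NormTable] | NormTable,
) -> dict:
    """Juxtapose a cohort's quartiles with population quartiles.

    Flags dimensions where the sample's first quartile exceeds the population
    first quartile (an "above-norm baseline", the pattern used to
    contextualize convenience samples before an intervention).
    """
    if len(scores) < 4:
        raise ScoringError("cohort_norm_report needs at least 4 respondents")
    if isinstance(norms, NormTable):
        norms = {norms.dimension: norms}
    frame = scores_to_frame(scores)

    report: dict = {"n": len(scores), "dimensions": {}, "flags": []}
    for dim in ("V", "r", "f", "d", "n"):
        col = frame[dim].to_numpy(dtype=float)
        sample = {
            "min": float(col.min()),
            "q1": float(np.percentile(col, 25)),
            "median": float(np.median(col)),
            "mean": float(col.mean()),
            "q3": float(np.percentile(col, 75)),
            "max": float(col.max()),
        }
        entry: dict = {"sample": sample}
        norm = norms.get(dim)
        if norm is not None and norm.quartiles:
            entry["population"] = dict(norm.quartiles)
            if sample["q1"] > norm.quartiles["q1"]:
                entry["above_norm_baseline"] = True
                report["flags"].append(
                    f"{dim}: above-norm baseline (sample Q1 {sample['q1']:g} > "
                    f"population Q1 {norm.quartiles['q1']:g})"
                )
        report["dimensions"][dim] = entry
    return report
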