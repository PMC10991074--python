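"""Item banks and norm fixtures.

An *item bank* is an ordered collection of news headlines, each with a
veracity key (``real`` or ``fake``) and, when calibrated, three-parameter
logistic (3PL) item parameters: discrimination ``a``, difficulty ``b`` and a
guessing floor ``c`` fixed at 0.5 (a two-option true/false judgment).

Three banks ship with the package:

* ``MIST-20`` — the full 20-item scale (10 real + 10 fake), with 3PL a/b.
* ``MIST-8``  — the 8-item short scale, a subset of MIST-20 (4 real + 4 fake).
* ``MIST-16`` — the 16-item scale selected via exploratory graph analysis,
  with four content dimensions of sizes 5/5/3/3 (8 real + 8 fake).

Norm fixtures map raw scores to population percentiles (US general
population, MIST-20) and provide quartile summaries for the US and UK on
both the MIST-8 and MIST-20.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Item",
    "ItemBank",
    "NormTable",
    "BankError",
    "builtin_bank",
    "load_bank",
    "write_bank",
    "validate_bank",
    "load_norms",
    "load_quartiles",
    "BUILTIN_BANKS",
]

BUILTIN_BANKS = ("MIST-20", "MIST-16", "MIST-8")

VERACITY_VALUES = ("real", "fake")


class BankError(ValueError):
    """Malformed bank definition (unknown name, schema violation, bad field)."""


@dataclass(frozen=True)
class Item:
    """One headline with its answer key and optional 3PL / dimension metadata."""

    id: str
    headline: str
    veracity: str
    a: float | None = None
    b: float | None = None
    c: float | None = None
    ega_dimension: int | None = None
    ega_loadings: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.veracity not in VERACITY_VALUES:
            raise BankError(
                f"item {self.id!r}: veracity must be one of {VERACITY_VALUES}, "
                f"got {self.veracity!r}"
            )
        if self.a is not None and not self.a > 0:
            raise BankError(f"item {self.id!r}: discrimination a must be > 0")
        if self.c is not None and not 0 <= self.c < 1:
            raise BankError(f"item {self.id!r}: guessing c must lie in [0, 1)")


@dataclass
class ItemBank:
    """Ordered collection of items forming one test version."""

    name: str
    items: list[Item]
    version: str = "custom"

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def real_ids(self) -> list[str]:
        return [it.id for it in self.items if it.veracity == "real"]

    @property
    def fake_ids(self) -> list[str]:
        return [it.id for it in self.items if it.veracity == "fake"]

    @property
    def k(self) -> int:
        return len(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, ids: Sequence[str], name: str = "custom") -> "ItemBank":
        lookup = {it.id: it for it in self.items}
        return ItemBank(name=name, items=[lookup[i] for i in ids], version=self.version)


@dataclass
class NormTable:
    """Percentile -> score grid plus quartile summary for one dimension.

    The grid covers percentiles 0..100 in steps of 5 and is read exactly
    (no interpolation); scores are non-decreasing in percentile.
    """

    country: str
    scale: str
    dimension: str
    grid: dict[int, int] = field(default_factory=dict)
    quartiles: dict[str, float] | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.grid:
            pcts = sorted(self.grid)
            if pcts != list(range(0, 101, 5)):
                raise BankError(
                    f"norm grid for {self.dimension} must cover 0-100 in steps of 5"
                )
            scores = [self.grid[p] for p in pcts]
            if any(b < a for a, b in zip(scores, scores[1:])):
                raise BankError(
                    f"norm grid for {self.dimension} must be non-decreasing"
                )

    @property
    def score_range(self) -> tuple[int, int]:
        if self.grid:
            return self.grid[0], self.grid[100]
        q = self.quartiles or {}
        return int(q.get("min", 0)), int(q.get("max", 0))


def _data_text(name: str) -> str:
    return (resources.files("mistkit.data") / name).read_text(encoding="utf-8")


def _registry() -> dict:
    return json.loads(_data_text("items.json"))


def _item_from_dict(d: Mapping, context: str = "bank") -> Item:
    allowed = {"id", "headline", "veracity", "a", "b", "c", "ega_dimension", "ega_loadings"}
    unknown = set(d) - allowed
    if unknown:
        raise BankError(f"{context}: unknown item fields {sorted(unknown)}")
    for req in ("id", "veracity"):
        if req not in d:
            raise BankError(f"{context}: item missing required field {req!r}")
    loadings = d.get("ega_loadings")
    return Item(
        id=str(d["id"]),
        headline=str(d.get("headline", "")),
        veracity=d["veracity"],
        a=d.get("a"),
        b=d.get("b"),
        c=d.get("c"),
        ega_dimension=d.get("ega_dimension"),
        ega_loadings=tuple(loadings) if loadings is not None else None,
    )


def builtin_bank(name: str) -> ItemBank:
    """Return a packaged bank (``MIST-20``, ``MIST-16`` or ``MIST-8``)."""
    reg = _registry()
    if name not in reg["banks"]:
        raise BankError(
            f"unknown builtin bank {name!r}; available: {sorted(reg['banks'])}"
        )
    by_id = {d["id"]: _item_from_dict(d, context=name) for d in reg["items"]}
    items = [by_id[i] for i in reg["banks"][name]]
    return ItemBank(name=name, items=items, version=reg.get("version", "1.0"))


def _check_duplicates(dicts: Iterable[Mapping]) -> None:
    seen: set[str] = set()
    for d in dicts:
        iid = d.get("id")
        if iid in seen:
            raise BankError(f"duplicate item id {iid!r}")
        seen.add(str(iid))


def load_bank(path: str | Path) -> ItemBank:
    """Load a bank from its JSON serialization and validate basic schema."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise BankError(f"malformed bank JSON at {path}: {exc}") from exc
    if not isinstance(payload, dict) or "items" not in payload:
        raise BankError(f"bank JSON at {path} must be an object with an 'items' list")
    _check_duplicates(payload["items"])
    items = [_item_from_dict(d) for d in payload["items"]]
    return ItemBank(
        name=payload.get("name", "custom"),
        items=items,
        version=payload.get("version", "custom"),
    )


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Serialize a bank to JSON (UTF-8, losslessly round-trippable)."""
    items = []
    for it in bank.items:
        d: dict = {"id": it.id, "headline": it.headline, "veracity": it.veracity}
        for key in ("a", "b", "c", "ega_dimension"):
            val = getattr(it, key)
            if val is not None:
                d[key] = val
        if it.ega_loadings is not None:
            d["ega_loadings"] = list(it.ega_loadings)
        items.append(d)
    payload = {"name": bank.name, "version": bank.version, "items": items}
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=2), encoding="utf-8"
    )


def validate_bank(bank: ItemBank) -> dict:
    """Check balance, parameter completeness and named-bank invariants.

    Returns a report dict with ``passed`` (bool), ``checks`` and ``warnings``;
    failures of named-bank invariants are recorded in ``failures``.
    """
    n_real = len(bank.real_ids)
    n_fake = len(bank.fake_ids)
    report: dict = {
        "name": bank.name,
        "n_items": bank.k,
        "balance": {"real": n_real, "fake": n_fake},
        "has_3pl": all(it.a is not None and it.b is not None for it in bank.items),
        "checks": [],
        "warnings": [],
        "failures": [],
    }

    ids = bank.item_ids
    if len(set(ids)) != len(ids):
        report["failures"].append("duplicate item ids")

    if n_real != n_fake:
        report["warnings"].append(
            f"unbalanced bank ({n_real} real vs {n_fake} fake); d/n bias scores "
            "remain defined but V interpretation differs from a balanced test"
        )
    else:
        report["checks"].append(f"balanced {n_real}:{n_fake}")

    expected = {"MIST-20": (10, 10), "MIST-8": (4, 4), "MIST-16": (8, 8)}
    if bank.name in expected:
        er, ef = expected[bank.name]
        if (n_real, n_fake) != (er, ef):
            report["failures"].append(
                f"{bank.name} must have {er} real + {ef} fake items"
            )
        else:
            report["checks"].append(f"{bank.name} composition {er} real + {ef} fake")

    if bank.name == "MIST-8":
        mist20 = set(builtin_bank("MIST-20").item_ids)
        if set(ids) <= mist20:
            report["checks"].append("MIST-8 is a subset of MIST-20")
        else:
            report["failures"].append("MIST-8 items must be a subset of MIST-20")

    if bank.name == "MIST-16":
        sizes = [0, 0, 0, 0]
        for it in bank.items:
            if it.ega_dimension is None:
                report["failures"].append(f"MIST-16 item {it.id} lacks a dimension")
            else:
                sizes[it.ega_dimension - 1] += 1
        if sorted(sizes, reverse=True) != [5, 5, 3, 3]:
            report["failures"].append(
                f"MIST-16 dimension sizes must be 5/5/3/3, got {sizes}"
            )
        else:
            report["checks"].append("MIST-16 dimensions sized 5/5/3/3")

    for it in bank.items:
        if it.c is not None and it.c != 0.5:
            report["failures"].append(f"item {it.id}: calibrated c must equal 0.5")

    report["passed"] = not report["failures"]
    return report


def load_norms(country: str = "US", scale: str = "MIST-20") -> dict[str, NormTable]:
    """Load percentile norm grids, keyed by dimension (``V``, ``f``, ``r``)."""
    if (country, scale) != ("US", "MIST-20"):
        raise BankError(
            f"no packaged percentile norms for ({country}, {scale}); "
            "packaged grids cover the US MIST-20"
        )
    payload = json.loads(_data_text("norms_us_mist20.json"))
    quart = {
        (t["country"], t["scale"]): t["quartiles"]
        for t in json.loads(_data_text("quartiles_us_uk.json"))["tables"]
    }
    out: dict[str, NormTable] = {}
    for dim, grid in payload["grids"].items():
        out[dim] = NormTable(
            country=country,
            scale=scale,
            dimension=dim,
            grid={int(p): int(s) for p, s in grid.items()},
            quartiles=quart.get((country, scale)) if dim == "V" else None,
            n=payload.get("n"),
        )
    return out


def load_quartiles(country: str, scale: str) -> NormTable:
    """Quartile summary (min/Q1/median/mean/Q3/max) of V for one country/scale."""
    payload = json.loads(_data_text("quartiles_us_uk.json"))
    for t in payload["tables"]:
        if t["country"] == country and t["scale"] == scale:
            return NormTable(
                country=country, scale=scale, dimension="V",
                quartiles=t["quartiles"],
            )
    raise BankError(f"no packaged quartiles for ({country}, {scale})")
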