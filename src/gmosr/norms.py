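"""Normative percentile tables: encoding, band lookup, and rebuilding.

Percentile anchors here are *unsmoothed*: a requested percentile P_k is the
smallest observed score v such that at least k% of the sample is <= v (the
left-continuous inverse of the empirical distribution function, evaluated on
observed values only — no interpolation and no decimals).  On heavily tied
ordinal data this makes low percentiles collapse toward the minimum, which
is intentional and matches how the published tables were computed.

A score is interpreted against an anchor set as a *band*: below the minimum,
exactly on one or more (tied) anchors, strictly between two adjacent
anchors, or above the maximum.  Bands are defined for finalized integer
totals only, since rounding precedes interpretation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .scoresheet import GMCategory, TOTAL_MAX
from .strata import NormStratum

__all__ = [
    "PercentileAnchors",
    "NormTable",
    "Band",
    "band_lookup",
    "empirical_anchors",
    "empirical_percentile",
    "build_norm_table",
    "load_norm_table",
    "MIN_N_FOR_ANCHORS",
]

# Anchor sets are published only for cells with at least this many records;
# smaller cells retain the observed range at most.
MIN_N_FOR_ANCHORS = 15

ANCHOR_ORDER = ["min", "p10", "p25", "p50", "p75", "p90", "max"]
_LEVEL_OF = {"p10": 10, "p25": 25, "p50": 50, "p75": 75, "p90": 90}


@dataclass(frozen=True)
class PercentileAnchors:
    """Seven-point summary {min, P10, P25, P50, P75, P90, max} of one cell.

    Anchors may be partially absent (``None``): the full-period tables omit
    P10/P90, and cells below the publication threshold carry no anchors at
    all.  ``below_threshold`` flags cells with n < 15.
    """

    min: Optional[int] = None
    p10: Optional[int] = None
    p25: Optional[int] = None
    p50: Optional[int] = None
    p75: Optional[int] = None
    p90: Optional[int] = None
    max: Optional[int] = None
    n: int = 0
    below_threshold: bool = False

    def __post_init__(self) -> None:
        present = self.present()
        for _, v in present:
            if not (0 <= v <= TOTAL_MAX):
                raise ValueError(f"anchor {v} outside 0..{TOTAL_MAX}")
        values = [v for _, v in present]
        if values != sorted(values):
            raise ValueError(f"anchors must be non-decreasing: {present}")

    def present(self) -> list[tuple[str, int]]:
        """Anchors that are defined, in min..max order."""
        return [(name, getattr(self, name)) for name in ANCHOR_ORDER
                if getattr(self, name) is not None]

    @property
    def complete(self) -> bool:
        return all(getattr(self, a) is not None for a in ANCHOR_ORDER)


@dataclass(frozen=True)
class Band:
    """Where a score sits relative to an anchor set.

    ``relation`` is one of ``below_min``, ``on_anchor``, ``between``,
    ``above_max``.  For ``on_anchor``, ``anchors`` lists every anchor name
    tied at that value (e.g. P10 may coincide with the minimum); for
    ``between``, ``lower``/``upper`` name the bracketing anchors.
    """

    relation: str
    score: int
    anchors: tuple[str, ...] = ()
    lower: Optional[str] = None
    upper: Optional[str] = None

    @property
    def percentile(self) -> Optional[int]:
        """Numeric rank of the matched percentile anchor, if any."""
        for name in self.anchors:
            if name in _LEVEL_OF:
                return _LEVEL_OF[name]
        return None

    def describe(self) -> str:
        def label(name: str) -> str:
            return {"min": "min", "max": "max"}.get(name, name.upper())

        if self.relation == "below_min":
            return f"score {self.score} is below the observed minimum"
        if self.relation == "above_max":
            return f"score {self.score} is above the observed maximum"
        if self.relation == "on_anchor":
            return f"score {self.score} is on " + " (= ".join(
                label(a) for a in self.anchors) + ")" * (len(self.anchors) - 1)
        return (f"score {self.score} is between {label(self.lower)} "
                f"and {label(self.upper)}")


@dataclass
class NormTable:
    """Mapping (stratum, GM category) -> percentile anchors."""

    entries: dict[tuple[NormStratum, GMCategory], PercentileAnchors]
    provenance: str = "custom"
    notes: str = ""

    def get(self, stratum: NormStratum, category: GMCategory) -> PercentileAnchors:
        try:
            return self.entries[(stratum, category)]
        except KeyError:
            raise KeyError(
                f"no normative cell for income band {stratum.income_band!r}, "
                f"period {stratum.period!r}, category {category.value!r} "
                f"in table {self.provenance!r}") from None

    @classmethod
    def from_dict(cls, d: dict) -> "NormTable":
        entries = {}
        for e in d["entries"]:
            stratum = NormStratum(e["income_band"], e["period"])
            cat = GMCategory(e["category"])
            anchors = PercentileAnchors(
                **{a: e[a] for a in ANCHOR_ORDER}, n=int(e["n"]),
                below_threshold=int(e["n"]) < MIN_N_FOR_ANCHORS)
            entries[(stratum, cat)] = anchors
        return cls(entries=entries, provenance=d.get("provenance", "custom"),
                   notes=d.get("notes", ""))

    @classmethod
    def from_json(cls, path) -> "NormTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        entries = []
        for (stratum, cat), a in sorted(
                self.entries.items(),
                key=lambda kv: (kv[0][0].income_band, kv[0][0].period, kv[0][1].value)):
            entries.append({
                "income_band": stratum.income_band, "period": stratum.period,
                "category": cat.value, "n": a.n,
                **{name: getattr(a, name) for name in ANCHOR_ORDER}})
        return {"provenance": self.provenance, "notes": self.notes,
                "entries": entries}


_TABLE_CACHE: dict[str, NormTable] = {}


def load_norm_table(which: str = "table4") -> NormTable:
    """Load a shipped normative table: ``table2`` (full period, per income
    band) or ``table4`` (age-specific, combined LMIC+UMIC vs HIC)."""
    if which not in ("table2", "table4"):
        raise ValueError("which must be 'table2' or 'table4'")
    if which not in _TABLE_CACHE:
        text = resources.files("gmosr.data").joinpath(f"norms_{which}.json").read_text()
        _TABLE_CACHE[which] = NormTable.from_dict(json.loads(text))
    return _TABLE_CACHE[which]


def band_lookup(score: int, category: GMCategory, stratum: NormStratum,
                table: NormTable) -> Band:
    """Locate an integer total score relative to a cell's anchors."""
    if not isinstance(score, (int,)) or isinstance(score, bool):
        raise ValueError("band queries accept finalized integer totals only")
    if not (0 <= score <= TOTAL_MAX):
        raise ValueError(f"score {score} outside 0..{TOTAL_MAX}")
    anchors = table.get(stratum, category)
    present = anchors.present()
    if not present:
        raise KeyError(
            f"cell (income band {stratum.income_band!r}, period "
            f"{stratum.period!r}, category {category.value!r}) has no "
            f"published anchors (n = {anchors.n})")
    tied = tuple(name for name, v in present if v == score)
    if tied:
        return Band("on_anchor", score, anchors=tied)
    if score < present[0][1]:
        return Band("below_min", score)
    if score > present[-1][1]:
        return Band("above_max", score)
    lower = max((nv for nv in present if nv[1] < score), key=lambda nv: nv[1])
    upper = min((nv for nv in present if nv[1] > score), key=lambda nv: nv[1])
    return Band("between", score, lower=lower[0], upper=upper[0])


def empirical_percentile(scores: Sequence[int], k: float) -> int:
    """Unsmoothed percentile: smallest observed value v with
    #(scores <= v) / n >= k/100."""
    if len(scores) == 0:
        raise ValueError("empty score list")
    counts = sorted(Counter(scores).items())
    n = len(scores)
    cum = 0
    for value, c in counts:
        cum += c
        if cum / n >= k / 100.0:
            return value
    return counts[-1][0]  # unreachable for k <= 100; defensive


def empirical_anchors(scores: Iterable[int],
                      levels: Sequence[int] = (10, 25, 50, 75, 90)
                      ) -> PercentileAnchors:
    """Build a seven-point anchor set from observed integer totals.

    Min and max are the observed extremes; each requested percentile level
    uses :func:`empirical_percentile`.  Cells with n < 15 are flagged
    ``below_threshold`` (callers publishing tables should then retain only
    min/max).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("empty score list")
    for s in scores:
        if not (0 <= s <= TOTAL_MAX):
            raise ValueError(f"score {s} outside 0..{TOTAL_MAX}")
    fields = {f"p{k}": empirical_percentile(scores, k) for k in levels}
    return PercentileAnchors(min=min(scores), max=max(scores), n=len(scores),
                             below_threshold=len(scores) < MIN_N_FOR_ANCHORS,
                             **fields)


def build_norm_table(scored: Iterable[tuple[NormStratum, GMCategory, int]],
                     provenance: str = "rebuilt") -> NormTable:
    """Rebuild a normative table from (stratum, category, total) triples.

    Cells with at least 15 records get full anchors; smaller non-empty cells
    retain only the observed min/max (mirroring the publication's
    not-available convention); empty cells are absent.
    """
    cells: dict[tuple[NormStratum, GMCategory], list[int]] = {}
    for stratum, category, total in scored:
        cells.setdefault((stratum, category), []).append(total)
    entries = {}
    for key, totals in cells.items():
        anchors = empirical_anchors(totals)
        if anchors.below_threshold:
            anchors = PercentileAnchors(min=min(totals), max=max(totals),
                                        n=len(totals), below_threshold=True)
        entries[key] = anchors
    return NormTable(entries=entries, provenance=provenance)
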