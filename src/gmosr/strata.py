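"""Stratification of recordings by postmenstrual age and country income group.

Recording age is expressed as postmenstrual age (PMA) in obstetric
``weeks^days`` notation (e.g. ``31^6`` = 31 completed weeks + 6 days) and is
partitioned into six contiguous periods spanning 22^0 to 45^6 weeks.
Countries are mapped to World Bank income groups (LMIC / UMIC / HIC) using a
frozen registry snapshot so that normative lookups stay reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

__all__ = [
    "WeeksDays",
    "AGE_PERIODS",
    "NORM_PERIODS",
    "NORM_PERIOD_FOR_AGE_PERIOD",
    "INCOME_BANDS",
    "NormStratum",
    "classify_age_period",
    "classify_income_group",
    "canonical_country",
    "pma_from_birth",
    "load_country_registry",
]


@dataclass(frozen=True, order=True)
class WeeksDays:
    """An age in completed weeks plus 0-6 extra days."""

    weeks: int
    days: int = 0

    def __post_init__(self) -> None:
        if self.weeks < 0 or self.days < 0:
            raise ValueError(f"negative age component: {self.weeks}^{self.days}")
        if self.days > 6:
            raise ValueError(f"days must be in 0..6, got {self.days}")

    @property
    def total_days(self) -> int:
        return 7 * self.weeks + self.days

    @classmethod
    def from_days(cls, total: int) -> "WeeksDays":
        if total < 0:
            raise ValueError(f"negative total days: {total}")
        return cls(total // 7, total % 7)

    def __add__(self, other: "WeeksDays") -> "WeeksDays":
        return WeeksDays.from_days(self.total_days + other.total_days)

    def __str__(self) -> str:
        return f"{self.weeks}^{self.days}"


# Recording-age periods: closed day-exact intervals, disjoint and contiguous
# from 22^0 to 45^6.
AGE_PERIODS: list[tuple[str, WeeksDays, WeeksDays]] = [
    ("extremely_preterm", WeeksDays(22, 0), WeeksDays(27, 6)),
    ("very_preterm", WeeksDays(28, 0), WeeksDays(31, 6)),
    ("moderate_preterm", WeeksDays(32, 0), WeeksDays(33, 6)),
    ("late_preterm", WeeksDays(34, 0), WeeksDays(36, 6)),
    ("term", WeeksDays(37, 0), WeeksDays(41, 6)),
    ("post_term", WeeksDays(42, 0), WeeksDays(45, 6)),
]

AGE_PERIOD_LABELS = [label for label, _, _ in AGE_PERIODS]

# Five-way grouping used by the age-specific norm tables: the extremely and
# very preterm periods are pooled into a single < 32-week block.
NORM_PERIODS = ["lt_32", "moderate_preterm", "late_preterm", "term", "post_term"]
NORM_PERIOD_FOR_AGE_PERIOD = {
    "extremely_preterm": "lt_32",
    "very_preterm": "lt_32",
    "moderate_preterm": "moderate_preterm",
    "late_preterm": "late_preterm",
    "term": "term",
    "post_term": "post_term",
}

INCOME_BANDS = ["LMIC", "UMIC", "HIC"]


@dataclass(frozen=True)
class NormStratum:
    """A cell of a normative table: income band x recording-age grouping.

    ``income_band`` is LMIC, UMIC, HIC or LMIC_UMIC (the combined
    middle-income stratum of the age-specific tables); ``period`` is ALL
    (full-period tables) or one of the five norm-period blocks.
    """

    income_band: str
    period: str = "ALL"

    def __post_init__(self) -> None:
        if self.income_band not in (*INCOME_BANDS, "LMIC_UMIC"):
            raise ValueError(f"unknown income band {self.income_band!r}")
        if self.period != "ALL" and self.period not in NORM_PERIODS:
            raise ValueError(f"unknown norm period {self.period!r}")


def classify_age_period(pma: WeeksDays) -> Optional[str]:
    """Return the recording-age period containing ``pma``.

    Returns ``None`` for a PMA outside 22^0-45^6 (out-of-range marker);
    malformed week/day components raise at :class:`WeeksDays` construction.
    """
    d = pma.total_days
    for label, lo, hi in AGE_PERIODS:
        if lo.total_days <= d <= hi.total_days:
            return label
    return None


def pma_from_birth(ga_at_birth: WeeksDays, postnatal_age: WeeksDays) -> WeeksDays:
    """Postmenstrual age = gestational age at birth + postnatal age, day-exact."""
    return ga_at_birth + postnatal_age


_REGISTRY_CACHE: Optional[dict] = None


def load_country_registry() -> dict:
    """Load the frozen country -> income-group registry (with alias map)."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        text = resources.files("gmosr.data").joinpath("countries.json").read_text()
        reg = json.loads(text)
        lookup: dict[str, str] = {}
        canon: dict[str, str] = {}
        for band, countries in reg["groups"].items():
            for c in countries:
                lookup[c.casefold()] = band
                canon[c.casefold()] = c
        for alias, target in reg["aliases"].items():
            lookup[alias.casefold()] = lookup[target.casefold()]
            canon[alias.casefold()] = target
        reg["_lookup"] = lookup
        reg["_canon"] = canon
        _REGISTRY_CACHE = reg
    return _REGISTRY_CACHE


def canonical_country(country: str) -> Optional[str]:
    """Resolve a country name or alias to its canonical registry name."""
    if not country or not country.strip():
        raise ValueError("empty country name")
    return load_country_registry()["_canon"].get(country.strip().casefold())


def classify_income_group(country: str) -> Optional[str]:
    """Map a country to LMIC / UMIC / HIC via the frozen registry.

    Lookup is case-insensitive and alias-normalized.  An unrecognized
    country returns ``None`` (explicit unknown), never a silent default;
    an empty string raises ``ValueError``.
    """
    if not country or not country.strip():
        raise ValueError("empty country name")
    return load_country_registry()["_lookup"].get(country.strip().casefold())
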