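"""GMOS-R scoresheet: schema, assessment records, validation and scoring.

The revised optimality score sums item scores over four regions —
UPPER_EXTREMITIES (8 items, max 16), LOWER_EXTREMITIES (8 items, max 16),
NECK_AND_TRUNK (2 items, max 4) and SEQUENCE (1 item, max 2) — for a total
of 0-38, higher meaning more optimal movement.  Detail items take values in
{0, 0.5, 1, 1.5, 2}; half points may push the raw sum off the integer grid,
in which case the final total is rounded *up* to the next integer (subscores
are reported unrounded).  The sequence item is not scored freely: it is
determined by the categorical GM classification (normal -> 2, poor
repertoire -> 1, cramped-synchronized or chaotic -> 0).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

from .strata import WeeksDays

__all__ = [
    "GMCategory",
    "ScoresheetSchema",
    "Assessment",
    "ScoreResult",
    "ValidationError",
    "sequence_from_category",
    "validate_assessment",
    "compute_score",
    "load_default_schema",
]

TOTAL_MAX = 38
SEQUENCE_REGION = "SEQUENCE"
SEQUENCE_ITEM = "SEQUENCE/sequence"


class ValidationError(ValueError):
    """Raised when a record violates the scoresheet contract."""


class GMCategory(str, enum.Enum):
    """Categorical general-movement classification (Gestalt assessment).

    Exactly four categories exist on the revised sheet; the historical
    'hypokinetic' category was dropped because the score cannot be applied
    when no general movements occur at all.
    """

    NORMAL = "normal"
    POOR_REPERTOIRE = "poor_repertoire"
    CRAMPED_SYNCHRONIZED = "cramped_synchronized"
    CHAOTIC = "chaotic"

    @classmethod
    def from_code(cls, code: str) -> "GMCategory":
        try:
            return _CATEGORY_CODES[code.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown GM category code {code!r}") from None

    @property
    def code(self) -> str:
        return {v: k for k, v in _CATEGORY_CODES.items()}[self]


_CATEGORY_CODES = {
    "N": GMCategory.NORMAL,
    "PR": GMCategory.POOR_REPERTOIRE,
    "CS": GMCategory.CRAMPED_SYNCHRONIZED,
    "CH": GMCategory.CHAOTIC,
}

_SEQUENCE_SCORE = {
    GMCategory.NORMAL: 2,
    GMCategory.POOR_REPERTOIRE: 1,
    GMCategory.CRAMPED_SYNCHRONIZED: 0,
    GMCategory.CHAOTIC: 0,
}


def sequence_from_category(category: GMCategory) -> int:
    """Sequence subscore implied by the GM category.

    2 (variable sequence) for normal GMs, 1 (monotonous / incomplete) for
    poor repertoire, 0 (synchronized or disorganized) for
    cramped-synchronized and chaotic GMs.
    """
    if not isinstance(category, GMCategory):
        raise ValidationError(f"unknown GM category {category!r}")
    return _SEQUENCE_SCORE[category]


@dataclass(frozen=True)
class ScoresheetSchema:
    """Region/item structure of the scoresheet with permitted values.

    ``regions`` maps region name to its ordered item list; item keys are
    qualified as ``REGION/item``.  Structural invariants (item counts,
    permitted value sets, subscore maxima summing to 38) are enforced at
    construction, so a mis-transcribed schema file fails at load time.
    """

    regions: tuple[tuple[str, tuple[str, ...]], ...]
    allowed_values: Mapping[str, frozenset]
    subscore_max: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        expected = {
            "UPPER_EXTREMITIES": (8, 16.0),
            "LOWER_EXTREMITIES": (8, 16.0),
            "NECK_AND_TRUNK": (2, 4.0),
            "SEQUENCE": (1, 2.0),
        }
        names = [r for r, _ in self.regions]
        if names != list(expected):
            raise ValidationError(f"regions must be {list(expected)}, got {names}")
        for region, items in self.regions:
            n_items, smax = expected[region]
            if len(items) != n_items:
                raise ValidationError(
                    f"{region} must have {n_items} items, got {len(items)}")
            if float(self.subscore_max[region]) != smax:
                raise ValidationError(f"{region} subscore max must be {smax}")
            want = frozenset({0, 1, 2}) if region == SEQUENCE_REGION \
                else frozenset({0, 0.5, 1, 1.5, 2})
            for item in items:
                if frozenset(self.allowed_values[self.key(region, item)]) != want:
                    raise ValidationError(
                        f"item {region}/{item} must permit {sorted(want)}")
        if sum(float(v) for v in self.subscore_max.values()) != float(TOTAL_MAX):
            raise ValidationError("subscore maxima must sum to 38")

    @staticmethod
    def key(region: str, item: str) -> str:
        return f"{region}/{item}"

    @property
    def item_keys(self) -> list[str]:
        return [self.key(r, i) for r, items in self.regions for i in items]

    @classmethod
    def from_dict(cls, d: dict) -> "ScoresheetSchema":
        regions = tuple((r["name"], tuple(r["items"])) for r in d["regions"])
        allowed: dict[str, frozenset] = {}
        smax: dict[str, float] = {}
        for r in d["regions"]:
            smax[r["name"]] = float(r["subscore_max"])
            for item in r["items"]:
                allowed[cls.key(r["name"], item)] = frozenset(
                    float(v) for v in r["allowed_values"])
        return cls(regions=regions, allowed_values=allowed, subscore_max=smax,
                   name=d.get("name", "custom"))

    @classmethod
    def from_json(cls, path) -> "ScoresheetSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


_DEFAULT_SCHEMA: Optional[ScoresheetSchema] = None


def load_default_schema() -> ScoresheetSchema:
    """Shipped default schema (structure authoritative, item names descriptive)."""
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        text = resources.files("gmosr.data").joinpath("default_schema.json").read_text()
        _DEFAULT_SCHEMA = ScoresheetSchema.from_dict(json.loads(text))
    return _DEFAULT_SCHEMA


MISSING = None  # explicit missing-item marker


@dataclass
class Assessment:
    """One scored recording of one infant.

    ``item_scores`` maps qualified item keys to values (``None`` marks a
    missing item).  If the sequence item is absent it is auto-derived from
    the GM category; a provided value that contradicts the category is a
    validation error (the coupling is a rule of the instrument, not a
    convention).  ``sex`` is ``F``/``M``/``ND`` and gestational age may be
    ``None`` when not disclosed.
    """

    infant_id: str
    category: GMCategory
    item_scores: dict[str, Optional[float]] = field(default_factory=dict)
    country: str = "ND"
    sex: str = "ND"
    ga_at_birth: Optional[WeeksDays] = None
    pma_at_recording: Optional[WeeksDays] = None

    def with_derived_sequence(self) -> "Assessment":
        if self.item_scores.get(SEQUENCE_ITEM) is None:
            scores = dict(self.item_scores)
            scores[SEQUENCE_ITEM] = float(sequence_from_category(self.category))
            return Assessment(self.infant_id, self.category, scores, self.country,
                              self.sex, self.ga_at_birth, self.pma_at_recording)
        return self


def validate_assessment(a: Assessment, schema: Optional[ScoresheetSchema] = None
                        ) -> list[str]:
    """Check a record against the schema; returns a list of violations.

    An empty list means the record conforms.  Checks: every schema item
    present (or explicitly missing -> violation, the instrument has no
    partial-score provision), values in the permitted set, no stray items,
    and sequence/category consistency.
    """
    schema = schema or load_default_schema()
    a = a.with_derived_sequence()
    problems: list[str] = []
    if not isinstance(a.category, GMCategory):
        problems.append(f"unknown GM category {a.category!r}")
        return problems
    for key in schema.item_keys:
        if key not in a.item_scores or a.item_scores[key] is None:
            problems.append(f"missing item {key}")
            continue
        v = a.item_scores[key]
        if v not in schema.allowed_values[key]:
            allowed = sorted(schema.allowed_values[key])
            problems.append(f"item {key}: value {v} not in {allowed}")
    for key in a.item_scores:
        if key not in schema.allowed_values:
            problems.append(f"unexpected item {key}")
    seq = a.item_scores.get(SEQUENCE_ITEM)
    expected = float(sequence_from_category(a.category))
    if seq is not None and seq in {0.0, 1.0, 2.0} and seq != expected:
        problems.append(
            f"sequence/category mismatch: category {a.category.value} requires "
            f"sequence {expected:g}, got {seq:g}")
    return problems


@dataclass(frozen=True)
class ScoreResult:
    """Per-region subscores (unrounded), their raw sum, and the final total.

    The ceiling applies to the final total only: ``total = ceil(raw_sum)``,
    an integer in 0..38.
    """

    subscores: Mapping[str, float]
    raw_sum: float
    total: int


def compute_score(a: Assessment, schema: Optional[ScoresheetSchema] = None
                  ) -> ScoreResult:
    """Score a conforming assessment.

    Raises :class:`ValidationError` naming the first violation if the record
    does not validate.
    """
    schema = schema or load_default_schema()
    problems = validate_assessment(a, schema)
    if problems:
        raise ValidationError(problems[0])
    a = a.with_derived_sequence()
    subscores: dict[str, float] = {}
    for region, items in schema.regions:
        subscores[region] = sum(a.item_scores[schema.key(region, i)] for i in items)
    raw = sum(subscores.values())
    return ScoreResult(subscores=subscores, raw_sum=raw, total=math.ceil(raw))
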