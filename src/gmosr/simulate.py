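"""Seeded synthetic assessment cohorts with the published sample's structure.

The generator reproduces the cohort's *statistical shape* so the scoring,
stratification, normative and comparison machinery can be exercised without
patient data: the joint distribution of income band x recording-age period
x GM category follows the published composition counts; total scores are
drawn through the piecewise-linear inverse CDF fitted through a cell's
percentile anchors (age-specific anchors where published, full-period
anchors otherwise, a uniform min-max draw where only a range is known);
item scores are then back-filled to reproduce the drawn total exactly under
the category-sequence coupling.  Sex and gestational-age missingness match
the published rates (23.9% sex not disclosed, 11.8% gestational age not
disclosed).

Totals are simulated at the cohort-summary level and items back-filled,
because only total-score distributions are published; item-level
correlation structure is deliberately not modelled.

Reproducibility: one root seed; each infant uses an independent substream
keyed by (seed, infant index), so any subset regenerates identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .norms import NormTable, PercentileAnchors, load_norm_table
from .scoresheet import (Assessment, GMCategory, ScoresheetSchema,
                         load_default_schema, sequence_from_category,
                         SEQUENCE_ITEM)
from .strata import (AGE_PERIODS, NORM_PERIOD_FOR_AGE_PERIOD, NormStratum,
                     WeeksDays, load_country_registry)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "sample_total",
    "sample_items",
    "simulate_cohort",
    "default_config",
]

_LEVELS = {"min": 0.0, "p10": 0.10, "p25": 0.25, "p50": 0.50,
           "p75": 0.75, "p90": 0.90, "max": 1.0}

# Published cohort rates used as generator defaults.
_SEX_PROBS = {"F": 636 / 1983, "M": 874 / 1983, "ND": 473 / 1983}
_GA_ND_RATE = 234 / 1983          # gestational age not disclosed / unknown
_TERM_BORN_RATE = 205 / 1749      # term-born among records with known GA


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated cohort.

    ``cell_counts`` gives the relative frequency of each (period,
    income_band, category) cell — by default the published composition
    counts, so simulated mixes match the study's.  Score anchors come from
    the age-specific table where published, falling back to full-period
    anchors or a min-max range.
    """

    n_infants: int = 1983
    seed: int = 0
    cell_counts: dict = field(default_factory=dict)   # period -> band -> [4 counts]
    categories: tuple[str, ...] = ("normal", "poor_repertoire",
                                   "cramped_synchronized", "chaotic")
    sex_probs: dict = field(default_factory=lambda: dict(_SEX_PROBS))
    ga_not_disclosed_rate: float = _GA_ND_RATE
    term_born_rate: float = _TERM_BORN_RATE


def default_config(n_infants: int = 1983, seed: int = 0) -> SimulationConfig:
    """Default config: cell frequencies from the published composition table."""
    text = resources.files("gmosr.data").joinpath("cohort_counts.json").read_text()
    d = json.loads(text)
    return SimulationConfig(n_infants=n_infants, seed=seed,
                            cell_counts=d["counts"],
                            categories=tuple(d["categories"]))


def _anchor_knots(anchors: PercentileAnchors) -> tuple[np.ndarray, np.ndarray]:
    present = anchors.present()
    u = np.array([_LEVELS[name] for name, _ in present])
    v = np.array([float(val) for _, val in present])
    return u, v


def sample_total(anchors: PercentileAnchors, rng: np.random.Generator,
                 size: Optional[int] = None) -> int | np.ndarray:
    """Draw integer totals through the anchors' piecewise-linear inverse CDF.

    u ~ Uniform(0,1) is mapped through the monotone interpolant joining
    (0, min), (0.10, P10), ..., (1, max) over whichever anchors are
    defined, rounded to the nearest integer and clamped to [min, max].
    With only min and max defined this degenerates to a uniform range draw;
    with a single defined value it is that constant.
    """
    knots_u, knots_v = _anchor_knots(anchors)
    if knots_u.size == 0:
        raise ValueError("anchors define no values to sample from")
    u = rng.random(size)
    x = np.interp(u, knots_u, knots_v)
    out = np.clip(np.floor(x + 0.5), knots_v[0], knots_v[-1]).astype(int)
    return int(out) if size is None else out


def sample_items(total: int, category: GMCategory,
                 schema: Optional[ScoresheetSchema] = None,
                 rng: Optional[np.random.Generator] = None,
                 ) -> dict[str, float]:
    """Back-fill an item-score vector whose total equals ``total``.

    The sequence item is fixed by the category; the remaining budget is
    distributed over the 18 detail items by visiting them in random order
    and drawing each value uniformly from the half-point grid values that
    keep the remainder feasible.  The emitted vector sums exactly to the
    integer total (so the ceiling rule returns it unchanged).
    """
    schema = schema or load_default_schema()
    rng = rng if rng is not None else np.random.default_rng()
    seq = sequence_from_category(category)
    budget = float(total) - seq
    detail = [k for k in schema.item_keys if k != SEQUENCE_ITEM]
    if not (0.0 <= budget <= 2.0 * len(detail)):
        raise ValueError(
            f"total {total} infeasible for category {category.value} "
            f"(sequence score {seq})")
    order = rng.permutation(len(detail))
    scores: dict[str, float] = {SEQUENCE_ITEM: float(seq)}
    remaining = budget
    grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
    for pos, idx in enumerate(order):
        slots_after = len(detail) - pos - 1
        lo = max(0.0, remaining - 2.0 * slots_after)
        feasible = grid[(grid >= lo - 1e-9) & (grid <= remaining + 1e-9)]
        v = float(rng.choice(feasible))
        scores[detail[idx]] = v
        remaining -= v
    assert abs(remaining) < 1e-9
    return scores


def _cell_anchors(income_band: str, period: str, category: GMCategory,
                  t4: NormTable, t2: NormTable
                  ) -> tuple[PercentileAnchors, str, NormStratum]:
    # Preference order: age-specific cell with published anchors, else the
    # full-period cell for the infant's own income band (min-max-only cells
    # yield a flagged uniform range draw).
    norm_band = "HIC" if income_band == "HIC" else "LMIC_UMIC"
    stratum4 = NormStratum(norm_band, NORM_PERIOD_FOR_AGE_PERIOD[period])
    try:
        anchors = t4.get(stratum4, category)
        if len(anchors.present()) >= 2:
            src = "table4" if anchors.complete else "table4_range"
            return anchors, src, stratum4
    except KeyError:
        pass
    stratum2 = NormStratum(income_band, "ALL")
    anchors = t2.get(stratum2, category)
    src = "table2" if anchors.p50 is not None else "table2_range"
    return anchors, src, stratum2


@dataclass
class SyntheticCohort:
    """Generated assessments plus the ground truth that produced them."""

    assessments: list[Assessment]
    ground_truth: "pd.DataFrame"  # noqa: F821 - imported lazily
    config: SimulationConfig


def _draw_ga(rng: np.random.Generator, pma: WeeksDays, term_born: bool,
             ) -> WeeksDays:
    """Gestational age at birth, consistent with the recording PMA.

    Preterm GA follows a clipped normal around 28.5 weeks (reproducing the
    published median 28, interquartile range 26-31, range 22-36); term GA is
    uniform on 37-41 weeks.  The draw is truncated so the implied postnatal
    age stays within the 1-23-week recording window where feasible.
    """
    lo_w, hi_w = 22, 41 if term_born else 36
    lo_w = max(lo_w, pma.weeks - 23)
    hi_w = min(hi_w, max(pma.weeks - 1, 22))
    if term_born and hi_w >= 37:
        w = int(rng.integers(37, hi_w + 1))
    else:
        w = int(round(float(rng.normal(28.5, 3.5))))
        w = min(max(w, lo_w), hi_w)
    return WeeksDays(w, int(rng.integers(0, 7)))


def simulate_cohort(cfg: Optional[SimulationConfig] = None,
                    schema: Optional[ScoresheetSchema] = None
                    ) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort under ``cfg``.

    Every emitted assessment validates against the schema and scores to its
    ground-truth total.  The same config (including seed) regenerates the
    identical cohort.
    """
    import pandas as pd

    cfg = cfg or default_config()
    if not cfg.cell_counts:
        cfg = default_config(n_infants=cfg.n_infants, seed=cfg.seed)
    schema = schema or load_default_schema()
    t4 = load_norm_table("table4")
    t2 = load_norm_table("table2")
    registry = load_country_registry()["groups"]
    period_bounds = {label: (lo.total_days, hi.total_days)
                     for label, lo, hi in AGE_PERIODS}

    cells: list[tuple[str, str, GMCategory]] = []
    weights: list[float] = []
    for period, bands in cfg.cell_counts.items():
        for band, counts in bands.items():
            for cat_name, count in zip(cfg.categories, counts):
                if count > 0:
                    cells.append((period, band, GMCategory(cat_name)))
                    weights.append(float(count))
    probs = np.asarray(weights) / np.sum(weights)

    sex_labels = list(cfg.sex_probs)
    sex_probs = np.asarray([cfg.sex_probs[s] for s in sex_labels])
    sex_probs = sex_probs / sex_probs.sum()

    assessments: list[Assessment] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_infants):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, i)))
        period, band, category = cells[int(rng.choice(len(cells), p=probs))]
        lo_d, hi_d = period_bounds[period]
        pma = WeeksDays.from_days(int(rng.integers(lo_d, hi_d + 1)))
        anchors, source, stratum = _cell_anchors(band, period, category, t4, t2)
        total = int(sample_total(anchors, rng))
        items = sample_items(total, category, schema, rng)
        sex = sex_labels[int(rng.choice(len(sex_labels), p=sex_probs))]
        ga: Optional[WeeksDays] = None
        if rng.random() >= cfg.ga_not_disclosed_rate:
            ga = _draw_ga(rng, pma, term_born=rng.random() < cfg.term_born_rate)
        country = str(rng.choice(registry[band]))
        a = Assessment(infant_id=f"SIM{i:05d}", category=category,
                       item_scores=items, country=country, sex=sex,
                       ga_at_birth=ga, pma_at_recording=pma)
        assessments.append(a)
        truth_rows.append({
            "infant_id": a.infant_id, "income_band": band, "period": period,
            "category": category.value, "total": total,
            "anchor_source": source, "norm_income_band": stratum.income_band,
            "norm_period": stratum.period,
            "range_only": source.endswith("_range")})
    return SyntheticCohort(assessments=assessments,
                           ground_truth=pd.DataFrame(truth_rows), config=cfg)
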