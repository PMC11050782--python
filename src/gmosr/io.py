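"""Reading, writing and summarising assessment cohorts.

Assessment files are plain CSV, one row per recording: metadata columns
(``infant_id``, ``country``, ``sex`` as F/M/ND, gestational age and
recording PMA as week+day pairs, ``category`` as N/PR/CS/CH) followed by
one column per schema item (qualified ``REGION/item`` names).  ``ND``
marks not-disclosed metadata.  Reading is forgiving at the row level:
malformed rows are collected into an error report with line numbers while
well-formed rows load.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .scoresheet import (Assessment, GMCategory, ScoresheetSchema,
                         compute_score, load_default_schema)
from .strata import (AGE_PERIOD_LABELS, INCOME_BANDS, WeeksDays,
                     classify_age_period, classify_income_group)

__all__ = [
    "ReadReport",
    "Report",
    "read_assessments",
    "write_assessments",
    "summarize_cohort",
    "summarize_counts",
    "load_published_counts",
    "round_half_up",
]

_META_COLS = ["infant_id", "country", "sex", "ga_weeks", "ga_days",
              "pma_weeks", "pma_days", "category"]
_CATEGORIES = ["normal", "poor_repertoire", "cramped_synchronized", "chaotic"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the published tables;
    banker's rounding would print 58% for 1175/1983)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def _fmt_score(v: Optional[float]) -> str:
    if v is None:
        return ""
    return str(int(v)) if float(v).is_integer() else f"{v:.1f}"


def write_assessments(path, assessments: Iterable[Assessment],
                      schema: Optional[ScoresheetSchema] = None) -> None:
    """Write assessments as CSV (lossless for half points and ND markers)."""
    schema = schema or load_default_schema()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_META_COLS + schema.item_keys)
        for a in assessments:
            ga_w, ga_d = (("ND", "ND") if a.ga_at_birth is None
                          else (a.ga_at_birth.weeks, a.ga_at_birth.days))
            pma_w, pma_d = (("ND", "ND") if a.pma_at_recording is None
                            else (a.pma_at_recording.weeks, a.pma_at_recording.days))
            row = [a.infant_id, a.country, a.sex, ga_w, ga_d, pma_w, pma_d,
                   a.category.code]
            row += [_fmt_score(a.item_scores.get(k)) for k in schema.item_keys]
            w.writerow(row)


@dataclass
class ReadReport:
    """Result of loading an assessment file: typed records plus row errors."""

    assessments: list[Assessment]
    errors: list[tuple[int, str]] = field(default_factory=list)  # (line, message)

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_weeksdays(w: str, d: str, what: str) -> Optional[WeeksDays]:
    if w.strip().upper() == "ND" or w.strip() == "":
        return None
    return WeeksDays(int(w), int(d) if d.strip() not in ("", "ND") else 0)


def read_assessments(path, schema: Optional[ScoresheetSchema] = None
                     ) -> ReadReport:
    """Load an assessment CSV.

    A missing mandatory column is a hard error (``ValueError``); malformed
    rows (unknown category code, unparseable values) are reported with
    their line number and skipped, the rest load.
    """
    schema = schema or load_default_schema()
    report = ReadReport(assessments=[])
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _META_COLS + schema.item_keys if c not in header]
        if missing:
            raise ValueError(f"missing mandatory column(s): {missing}")
        for line_no, row in enumerate(reader, start=2):
            try:
                category = GMCategory.from_code(row["category"])
                ga = _parse_weeksdays(row["ga_weeks"], row["ga_days"], "GA")
                pma = _parse_weeksdays(row["pma_weeks"], row["pma_days"], "PMA")
                items: dict[str, Optional[float]] = {}
                for key in schema.item_keys:
                    raw = row[key].strip()
                    items[key] = float(raw) if raw != "" else None
                report.assessments.append(Assessment(
                    infant_id=row["infant_id"], category=category,
                    item_scores=items, country=row["country"],
                    sex=row["sex"].strip().upper() or "ND",
                    ga_at_birth=ga, pma_at_recording=pma))
            except (ValueError, KeyError) as exc:
                report.errors.append((line_no, str(exc)))
    return report


@dataclass
class Report:
    """Cohort summary: composition counts/percentages and score summaries.

    ``counts`` is a long-form frame (period, income_band, category, n);
    ``period_percentages`` gives the integer category mix within each
    recording-age period; ``score_summaries`` (when totals are available)
    gives median / quartiles / range per GM category.
    """

    counts: pd.DataFrame
    n_total: int
    period_percentages: pd.DataFrame
    income_shares: dict[str, float]
    period_shares: dict[str, float]
    category_shares: dict[str, int]
    score_summaries: Optional[pd.DataFrame] = None

    def category_share_in_period(self, period: str, category: str) -> int:
        """Integer % of the period's recordings in one GM category."""
        sub = self.period_percentages
        row = sub[(sub["period"] == period) & (sub["category"] == category)]
        return int(row["percent"].iloc[0]) if len(row) else 0

    def period_share_of_category(self, category: str, period: str) -> int:
        """Integer % of one GM category's recordings falling in a period."""
        c = self.counts
        cat_total = c[c["category"] == category]["n"].sum()
        in_period = c[(c["category"] == category)
                      & (c["period"] == period)]["n"].sum()
        if cat_total == 0:
            return 0
        return int(round_half_up(100.0 * in_period / cat_total))

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "category_shares_percent": self.category_shares,
            "income_shares_percent": self.income_shares,
            "period_shares_percent": self.period_shares,
            "period_category_percent": self.period_percentages.to_dict("records"),
            "counts": self.counts.to_dict("records"),
        }
        if self.score_summaries is not None:
            d["score_summaries"] = self.score_summaries.to_dict("records")
        return d

    def to_text(self) -> str:
        lines = [f"Cohort summary ({self.n_total} recordings)"]
        lines.append("Category mix: " + ", ".join(
            f"{c} {p}%" for c, p in self.category_shares.items()))
        lines.append("Income bands: " + ", ".join(
            f"{b} {s}%" for b, s in self.income_shares.items()))
        lines.append("Recording-age periods: " + ", ".join(
            f"{p} {s}%" for p, s in self.period_shares.items()))
        if self.score_summaries is not None:
            lines.append("Score summaries (median [P25-P75], min-max):")
            for _, r in self.score_summaries.iterrows():
                lines.append(
                    f"  {r['category']}: {r['median']:g} "
                    f"[{r['p25']:g}-{r['p75']:g}], {r['min']:g}-{r['max']:g} "
                    f"(n={int(r['n'])})")
        return "\n".join(lines)


def load_published_counts() -> pd.DataFrame:
    """Published composition counts as a long-form frame
    (period, income_band, category, n)."""
    text = resources.files("gmosr.data").joinpath("cohort_counts.json").read_text()
    d = json.loads(text)
    rows = []
    for period, bands in d["counts"].items():
        for band, counts in bands.items():
            for cat, n in zip(d["categories"], counts):
                rows.append({"period": period, "income_band": band,
                             "category": cat, "n": int(n)})
    return pd.DataFrame(rows)


def summarize_counts(counts: pd.DataFrame,
                     totals: Optional[pd.DataFrame] = None) -> Report:
    """Build a cohort report from a long-form count table.

    ``totals`` (optional) is a frame with columns category/total used for
    the per-category score summaries.
    """
    n_total = int(counts["n"].sum())
    period_rows = []
    for period, sub in counts.groupby("period", sort=False):
        period_n = sub["n"].sum()
        for cat in _CATEGORIES:
            cat_n = sub[sub["category"] == cat]["n"].sum()
            if period_n > 0:
                period_rows.append({
                    "period": period, "category": cat, "n": int(cat_n),
                    "percent": int(round_half_up(100.0 * cat_n / period_n))})
    period_pct = pd.DataFrame(period_rows)
    income_shares = {
        band: round_half_up(100.0 * counts[counts["income_band"] == band]["n"].sum()
                            / n_total, 1)
        for band in INCOME_BANDS}
    period_shares = {
        period: round_half_up(
            100.0 * counts[counts["period"] == period]["n"].sum() / n_total, 1)
        for period in AGE_PERIOD_LABELS
        if (counts["period"] == period).any()}
    category_shares = {
        cat: int(round_half_up(
            100.0 * counts[counts["category"] == cat]["n"].sum() / n_total))
        for cat in _CATEGORIES}
    summaries = None
    if totals is not None and len(totals):
        rows = []
        for cat in _CATEGORIES:
            vals = totals[totals["category"] == cat]["total"]
            if len(vals):
                rows.append({"category": cat, "n": len(vals),
                             "median": float(vals.median()),
                             "p25": float(vals.quantile(0.25)),
                             "p75": float(vals.quantile(0.75)),
                             "min": float(vals.min()),
                             "max": float(vals.max())})
        summaries = pd.DataFrame(rows)
    return Report(counts=counts, n_total=n_total, period_percentages=period_pct,
                  income_shares=income_shares, period_shares=period_shares,
                  category_shares=category_shares, score_summaries=summaries)


def summarize_cohort(assessments: Sequence[Assessment],
                     schema: Optional[ScoresheetSchema] = None) -> Report:
    """Classify, score and summarise a list of assessments."""
    schema = schema or load_default_schema()
    rows = []
    totals = []
    for a in assessments:
        period = (classify_age_period(a.pma_at_recording)
                  if a.pma_at_recording else None)
        band = classify_income_group(a.country) if a.country not in ("", "ND") \
            else None
        rows.append({"period": period or "out_of_range",
                     "income_band": band or "unknown",
                     "category": a.category.value, "n": 1})
        totals.append({"category": a.category.value,
                       "total": compute_score(a, schema).total})
    counts = (pd.DataFrame(rows)
              .groupby(["period", "income_band", "category"], sort=False,
                       as_index=False)["n"].sum())
    return summarize_counts(counts, pd.DataFrame(totals))


def plot_score_distributions(assessments: Sequence[Assessment], path,
                             schema: Optional[ScoresheetSchema] = None) -> bool:
    """Box-whisker plot of totals per income band x GM category.

    Optional and additive: returns False (without failing) when matplotlib
    is unavailable.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return False
    schema = schema or load_default_schema()
    data: dict[tuple[str, str], list[int]] = {}
    for a in assessments:
        band = classify_income_group(a.country) if a.country not in ("", "ND") \
            else None
        if band is None:
            continue
        total = compute_score(a, schema).total
        data.setdefault((band, a.category.value), []).append(total)
    keys = sorted(data)
    fig, ax = plt.subplots(figsize=(max(6, len(keys)), 4))
    ax.boxplot([data[k] for k in keys], tick_labels=[f"{b}\n{c}" for b, c in keys],
               whis=(0, 100))
    ax.set_ylabel("GMOS-R total")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return True
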