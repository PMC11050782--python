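# gmosr

A toolkit for the **General Movement Optimality Score – Revised (GMOS-R)**,
the detailed 0–38 optimality score applied to infants' general movements
(GMs) alongside the categorical Prechtl general movement assessment.  It is
aimed at clinicians and researchers who already have item-level GMOS-R
scoresheets and GM category calls and need to validate, total, and interpret
them against normative percentile ranks — and at methodologists who need a
reproducible synthetic cohort to exercise that pipeline without patient
data.

## What it computes

**Scoring.**  The GMOS-R sums item scores over four regions — upper
extremities (8 items, max 16), lower extremities (8 items, max 16), neck and
trunk (2 items, max 4), and sequence (1 item, max 2) — for a total

```
GMOS-R = ⌈ Σ_regions Σ_items s_i ⌉ ,   s_i ∈ {0, 0.5, 1, 1.5, 2},   0 ≤ GMOS-R ≤ 38,
```

where half points may be given on any detail item and the final total is
rounded *up* to an integer.  The sequence item is not free: it is fixed by
the GM category (normal → 2, poor repertoire → 1, cramped-synchronized or
chaotic → 0), and the validator enforces that coupling.

**Normative interpretation.**  Percentile ranks are *unsmoothed*: the k-th
percentile P_k of a reference cell is the smallest observed score v with
F̂(v) ≥ k/100, the left-continuous inverse of the empirical CDF on observed
ordinal scores — no interpolation, so heavy ties can pull P10 down onto the
minimum.  Shipped tables give the published anchors {min, P10, P25, P50,
P75, P90, max} per GM category, stratified by World Bank country income
group (LMIC / UMIC / HIC over all recording ages, or combined LMIC+UMIC vs
HIC per recording-age block), and a total score is placed *below the
minimum*, *on* one or more tied anchors, *between* two anchors, or *above
the maximum*.  Anchors are published only for cells with n ≥ 15.

**Comparison and agreement statistics.**  Mann–Whitney U (tie-corrected
normal approximation, signed Z), Kruskal–Wallis H (tie-corrected, χ²
p-value), Pearson 2×2 χ², pairwise ICC(A,1) (two-way random effects,
absolute agreement, single measure), within-Δ agreement (default Δ = 2
points, the instrument's clinical equivalence margin) and Cohen's kappa,
with the two-tier significance rule p < 0.05 (single comparison) / p < 0.017
(three-comparison family).

**Synthetic cohorts.**  A seeded generator reproduces the reference
cohort's joint composition (recording-age period × income band × GM
category), draws totals through the piecewise-linear inverse CDF of the
normative anchors, and back-fills item scores consistent with the total and
the category — so every downstream module is testable end to end.

## Worked example

```bash
$ gmosr percentile --score 35 --category N --income-band UMIC
score 35 is on P75
anchors: min=28, p25=31, p50=33, p75=35, max=38 (n=78)

$ gmosr percentile --score 14 --category PR --income-band LMIC_UMIC --period lt_32
score 14 is on P50
anchors: min=8, p10=8, p25=12, p50=14, p75=19, p90=23, max=24 (n=17)

$ gmosr percentile --score 14 --category PR --income-band HIC --period lt_32
score 14 is between min and P10
anchors: min=9, p10=15, p25=18, p50=23, p75=28, p90=31, max=32 (n=137)
```

The same total of 14 for an infant with poor-repertoire GMs recorded before
32 weeks sits on the median in lower- and upper-middle-income countries but
below the 10th percentile in high-income countries — the kind of
stratification-dependent reading the toolkit is built to make explicit.

A full synthetic pipeline:

```bash
gmosr simulate --n 1983 --seed 1 --out cohort.csv   # seeded synthetic cohort
gmosr score cohort.csv --json | head                # validate + total each record
gmosr summarize cohort.csv                          # composition + score summaries
gmosr compare cohort.csv --by income-band --category PR --test kw
gmosr build-norms cohort.csv --combine-middle-income --out rebuilt_norms.json
```

`summarize` prints the period × income × category composition with integer
percentages and per-category medians/quartiles/ranges; `build-norms`
rebuilds unsmoothed anchor tables from any scored cohort, publishing full
anchors only for cells with n ≥ 15.

## Layout

- `gmosr.scoresheet` — schema, validation, scoring (sum + ceiling)
- `gmosr.strata` — PMA arithmetic, recording-age periods, income registry
- `gmosr.norms` — anchor tables, band lookup, unsmoothed percentile engine
- `gmosr.stats` — rank tests, χ², ICC, kappa, significance policy
- `gmosr.simulate` — seeded synthetic cohorts with ground truth
- `gmosr.io` / `gmosr.cli` — CSV round trips, cohort reports, CLI

See `docs/methods.md` for the modelling and numerical choices.
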