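# Methods

This note records the scientific and numerical choices behind `gmosr`: what
the score and its normative tables are, how the percentile and comparison
machinery is defined, what the synthetic cohort does and does not emulate,
and where the design was genuinely open.

## The instrument

The GMOS-R is an optimality score for infant general movements: each
criterion earns full (2), partial (1), or no (0) credit, with half points
(0.5, 1.5) allowed on detail items when a performance falls between two
descriptors.  Four regions contribute — upper extremities (8 items, max
16), lower extremities (8 items, max 16), neck and trunk (2 items, max 4),
and sequence (1 item, max 2) — giving a total of 0–38.  Scoring is
two-step: the categorical GM classification (normal, poor repertoire,
cramped-synchronized, chaotic) is decided first by Gestalt assessment, and
that category *determines* the sequence subscore (2/1/0/0 respectively).
The toolkit treats the coupling as a hard rule: an absent sequence value is
derived from the category, and a contradictory one is a validation error.

Rounding: the ceiling applies to the **final total only** — subscores are
reported unrounded, and `total = ⌈raw_sum⌉`.  Tying the rounding to the
final score keeps the total monotone in every item (raising any item by 0.5
can never lower the total) and reproduces the instrument's integer range.

Half points on the neck/trunk items are permitted under the same rule as
all other detail items; the instrument states no separate restriction.

The shipped schema enforces the authoritative structure (item counts,
permitted values, subscore maxima summing to 38).  The *names* of the
extremity items are reconstructed from the instrument's running description
(amplitude, speed, spatial range, rotations, beginning, end, stiffness,
plus overall variability); the official scoresheet's exact wording lives in
a figure distributed as a PDF, so deployments that transcribe it can point
`--schema` at their own JSON.  Nothing in the scoring logic depends on the
names, only on the structure.

Records with missing item values are unscorable by design: the instrument
has no partial-scoring provision, and imputing optimality scores would
fabricate clinical content.

## Stratification

Recording age is the postmenstrual age (PMA) at video, in week^day
notation, partitioned into six closed, contiguous, day-exact intervals:
<28^0 (extremely preterm), 28^0–31^6 (very preterm), 32^0–33^6 (moderate
preterm), 34^0–36^6 (late preterm), 37^0–41^6 (term), 42^0–45^6
(post-term).  PMA outside 22^0–45^6 is flagged out-of-range rather than
clamped.  The age-specific norm tables pool the two earliest periods into a
single <32-week block; both the six-way classification and the five-way
norms grouping are exposed (`classify_age_period`,
`NORM_PERIOD_FOR_AGE_PERIOD`), since which one is "the" analysis grouping
depends on the question.

Country income bands follow the World Bank classification **as a frozen
snapshot** shipped with the package, not a live feed: the normative tables
were built under a specific assignment, and reclassifying a country later
(e.g. a LMIC promoted to UMIC) must not silently move infants across norm
strata.  Lookup is case-insensitive with an alias map (USA/United States,
Korea/South Korea, Czechia/Czech Republic, Türkiye/Turkey, The
Netherlands/Netherlands, UK/United Kingdom).  Unknown countries return an
explicit unknown, never a default band.

## Percentile ranks and bands

Percentiles are computed **without smoothing** on the observed ordinal
scores: P_k is the smallest observed value v such that the fraction of
scores ≤ v is at least k/100 (the left-continuous inverse of the empirical
CDF).  There is no interpolation and no decimal percentile: every anchor is
a score someone actually obtained.  A consequence embraced rather than
corrected: with heavy ties, low percentiles collapse toward the minimum
(P10 of fifty 5s and fifty 20s is 5).  Anchors are therefore non-decreasing
in k by construction, which the loader re-validates for every shipped cell.

Rebuilt tables publish full anchors only for cells with **n ≥ 15**; smaller
non-empty cells retain the observed min/max only, and empty cells are
absent.  The shipped age-specific table mirrors its source exactly,
including cells printed entirely as not-available.

Band lookup accepts **finalized integer totals only** (rounding precedes
interpretation).  A score equal to one or more tied anchors reports *all*
tied names ("on P10 (= min)") instead of picking one arbitrarily; otherwise
the result is below-min, between two named anchors, or above-max.  The
full-period tables publish five anchors (min, P25, P50, P75, max), so
"above P75" surfaces as *between P75 and max* there.

Known transcription caveats, recorded in the data files' notes rather than
silently resolved: the source's running text places a normal-GM score of 35
on P50 in HICs while its typeset full-period table prints a median of 33
(the table value is shipped); and one cell's n differs by 1 between the
composition table (205) and the anchor table (204).

## Comparison statistics

The score is ordinal, so group comparisons are rank-based, implemented
natively with midranks:

- **Mann–Whitney.**  U from midranks; Z = (U₁ − n₁n₂/2)/σ with the
  tie-corrected variance σ² = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]; p
  two-tailed from the normal law, no continuity correction.  Z is signed by
  the first group's rank sum, so "group 1 scores lower" gives negative Z.
- **Kruskal–Wallis.**  H with the tie-correction divisor
  1 − Σ(t³−t)/(N³−N); p from χ² with k−1 df.  For two tie-free groups
  H = Z² exactly (asserted to 1e−9 in the tests).
- **Pearson 2×2 χ²** N(ad−bc)²/(r₁r₂c₁c₂), 1 df, continuity correction off
  by default and available as a flag (the convention used when the
  reference comparisons were reported is not recoverable, so the plain
  statistic is the default).
- Degenerate inputs (every observation identical) return an explicit
  undefined marker with p = 1 instead of raising: a pipeline summarizing
  many small cells must not die on a constant one.

Large-sample approximations are the API; exact enumeration exists only in
the test oracles.  The asymptotic two-sided p agrees with exact permutation
enumeration (mid-p convention) within 0.05 for group sizes 5–7 — verified
exhaustively over every achievable U — while smaller groups carry an
irreducible discretization gap (up to ≈0.23 at n=2 per group) that no
implementation choice can remove; below ~5 per group the asymptotic p
should be treated as indicative only.

**Agreement.**  The interrater ICC is fixed to ICC(A,1): two-way random
effects, absolute agreement, single measure — the form that penalizes
systematic scorer offsets, appropriate when both raters' raw totals are
used interchangeably.  Within-Δ agreement (default Δ = 2, the margin below
which a scorer difference is not clinically relevant) is a plain fraction;
its chance-corrected companion `within_delta_kappa` uses a permutation
chance model over re-pairings and is explicitly labelled non-standard.
Cohen's kappa operates on categorical labels with the usual marginal chance
model and returns an undefined marker when chance agreement saturates.

**Significance policy.**  Two-tailed p < 0.05 for a single comparison;
p < 0.017 (strict) for each of the three pairwise comparisons within a
three-group family; other family sizes fall back to Bonferroni 0.05/m with
a warning, since the policy defines no threshold for them.

## Synthetic cohorts

The generator emulates the *distributional shape* of the reference cohort
(1983 recordings), at the default sizes and rates that cohort reports:

- the joint frequency of (recording-age period × income band × GM
  category) equals the published composition counts — overall: 59% poor
  repertoire, 24% normal, 15% cramped-synchronized, 1% chaotic; 74.3% HIC /
  17.8% UMIC / 7.9% LMIC;
- totals are drawn by mapping u ~ Uniform(0,1) through the piecewise-linear
  inverse CDF joining (0, min), (0.10, P10), (0.25, P25), (0.50, P50),
  (0.75, P75), (0.90, P90), (1, max) of the cell's anchors, rounding to the
  nearest integer and clamping to [min, max].  Cells without age-specific
  anchors fall back to the full-period anchors for the infant's own income
  band; cells with only a published range (chaotic GMs in middle-income
  bands) use a uniform min–max draw and are flagged `range_only` in the
  ground truth;
- item scores are back-filled to reproduce the drawn total exactly: the
  sequence item is fixed by the category and the residual budget is spread
  over the 18 detail items, visited in random order, each drawn uniformly
  from the half-point values that keep the remainder feasible;
- sex is F/M/ND with probabilities 636/874/473 out of 1983 (23.9% not
  disclosed); gestational age is missing with probability 234/1983; when
  present it is drawn from a clipped normal (mean 28.5 w, sd 3.5 w,
  range 22–36) for preterm-born infants — reproducing the reported median
  28 and interquartile range 26–31 — or uniform 37–41 w for the term-born
  (205 of 1749 known-GA records), truncated so the implied postnatal age
  stays within the 1–23-week recording window where feasible.

Seed policy: one root seed; infant i uses the substream
`SeedSequence((seed, i))`, so the first k infants of a run are identical
regardless of the total n, and regeneration is byte-identical.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: item-level correlation structure (items
are exchangeable given the total; real scoresheets are not), developmental
trajectories across repeated recordings of one infant, any association
between metadata (sex, GA) and scores (the reference analyses found none,
and the generator builds none in), within-band country differences, and the
convenience-sampling biases of the reference cohort itself.  Round-trip
recovery of anchors (±1 point at P10–P90 with 50,000 draws per cell) shows
the inverse-CDF sampling and the percentile engine are mutually consistent,
not that the anchors describe any new population.

## Problem sizes in the checked guarantees

The test suite exercises: 10,000 random conforming score vectors against an
exact-rational sum-and-ceil oracle; 1,000 random multisets (sizes 15–500)
against a sort-and-scan percentile oracle; exhaustive U-enumeration for
Mann–Whitney groups of 5–7; 50,000 inverse-CDF draws per fully-anchored
normative cell; and a 20,000-infant cohort for composition checks (3σ
binomial bounds).  These sizes make the binomial tolerances meaningful
while keeping the default run fast on a single CPU.

## Known limitations

- The shipped extremity item names are reconstructions (see above); the
  structure, not the wording, is normative here.
- The real cohort's inferential results (Z statistics between income bands,
  the 0.915–0.993 ICC range, the 0.69–0.98 kappa range) depend on the
  original ratings, which are not redistributable; the toolkit asserts the
  *properties* of those statistics (identities, oracle agreement,
  perfect-agreement limits) rather than the historical values.
- Band queries outside a cell with published anchors fail loudly; there is
  no borrowing across strata.
- No smoothing, growth-curve (LMS/GAMLSS) modelling, continuous-age
  centiles, or outcome prediction: the toolkit interprets a score against
  its reference distribution and stops there.
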