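"""Nonparametric comparison and interrater-agreement statistics.

Group comparisons on the ordinal total score use the Mann-Whitney U test
(two groups) and the Kruskal-Wallis H test (three or more), both with
midranks and the standard tie-corrected variance, reporting large-sample
normal / chi-square p-values.  Interrater agreement on the numeric total
uses the pairwise two-way random-effects, absolute-agreement, single-measure
intraclass correlation (ICC(A,1)) and the fraction of rating pairs within a
fixed score difference (default <= 2 points, the instrument's clinical
equivalence margin); categorical agreement uses Cohen's kappa.

Decision rule: two-tailed p < 0.05 for a single comparison; p < 0.017 for
the three pairwise comparisons within a three-group family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "AgreementResult",
    "SignificancePolicy",
    "mann_whitney",
    "kruskal_wallis",
    "chi_square_2x2",
    "icc_pairwise",
    "within_delta_agreement",
    "cohen_kappa",
    "within_delta_kappa",
    "agreement_summary",
    "flag_significance",
]


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a rank-based or chi-square group comparison.

    ``statistic`` is NaN with ``undefined=True`` when the sampling variance
    degenerates (e.g. every observation identical), in which case the
    p-value is reported as 1 (no evidence of a difference).
    """

    statistic_name: str
    statistic: float
    p_two_tailed: float
    n_per_group: tuple[int, ...]
    ties_corrected: bool = True
    undefined: bool = False


@dataclass(frozen=True)
class SignificancePolicy:
    alpha_univariate: float = 0.05
    alpha_three_group_pairwise: float = 0.017


def _tie_term(all_values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    Z is signed by the direction of the first group's rank sum: negative
    when group 1 tends to score lower than group 2.  Two-tailed p from the
    normal law; no continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = _tie_term(combined)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return RankTestResult("Z", float("nan"), 1.0, (n1, n2), undefined=True)
    z = (u1 - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult("Z", z, min(p, 1.0), (n1, n2))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square, k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    sizes = [a.size for a in arrays]
    n = sum(sizes)
    combined = np.concatenate(arrays)
    ranks = sps.rankdata(combined)
    h = 0.0
    start = 0
    for sz in sizes:
        h += ranks[start:start + sz].sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(combined) / (n ** 3 - n)
    if correction <= 0:  # all observations identical
        return RankTestResult("H", float("nan"), 1.0, tuple(sizes), undefined=True)
    h /= correction
    p = sps.chi2.sf(h, df=len(arrays) - 1)
    return RankTestResult("H", h, float(p), tuple(sizes))


def chi_square_2x2(table: Sequence[Sequence[float]],
                   continuity_correction: bool = False) -> RankTestResult:
    """Pearson chi-square on a 2x2 count table, 1 df.

    chi2 = N(ad - bc)^2 / (r1 r2 c1 c2); the Yates continuity correction is
    off by default and available as a flag.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin in 2x2 table")
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff ** 2 / (r1 * r2 * c1 * c2)
    p = sps.chi2.sf(chi2, df=1)
    return RankTestResult("chi2", float(chi2), float(p),
                          (int(r1), int(r2)), ties_corrected=False)


def icc_pairwise(ratings: Sequence[Sequence[float]]) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_videos, n_raters) matrix, typically two raters.
    Computed from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN when the denominator degenerates (no variance at all).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 videos and >= 2 raters")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)     # between videos
    ssc = n * np.sum((col_means - grand) ** 2)     # between raters
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def within_delta_agreement(a: Sequence[float], b: Sequence[float],
                           delta: float = 2.0) -> float:
    """Fraction of rating pairs whose total scores differ by <= delta points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need two aligned non-empty rating lists")
    return float(np.mean(np.abs(a - b) <= delta))


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa on two aligned categorical label lists.

    kappa = (p_o - p_e) / (1 - p_e) with the usual marginal chance model.
    Returns NaN when p_e = 1 (both raters constant and equal: chance
    agreement saturates and kappa is undefined).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b) or not a:
        raise ValueError("need two aligned non-empty label lists")
    n = len(a)
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for la, lb in zip(a, b):
        table[idx[la], idx[lb]] += 1
    p = table / n
    po = np.trace(p)
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if pe == 1.0:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def within_delta_kappa(a: Sequence[float], b: Sequence[float],
                       delta: float = 2.0, n_perm: int = 2000,
                       seed: int = 0) -> float:
    """Chance-corrected within-delta agreement (non-standard construction).

    The observed rate of |a - b| <= delta is corrected against a
    permutation chance model (rate under random re-pairing of the two
    raters' scores): kappa = (p_o - p_e) / (1 - p_e).  This dichotomy-based
    coefficient is *not* classical Cohen's kappa; it is provided because
    within-2-points agreement is the instrument's clinical margin.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need two aligned non-empty rating lists")
    po = float(np.mean(np.abs(a - b) <= delta))
    rng = np.random.default_rng(seed)
    pe_samples = np.empty(n_perm)
    for i in range(n_perm):
        pe_samples[i] = np.mean(np.abs(a - rng.permutation(b)) <= delta)
    pe = float(pe_samples.mean())
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class AgreementResult:
    icc_pairwise: float
    kappa: float
    within_delta_rate: float
    delta: float = 2.0


def agreement_summary(score_pairs: Sequence[Sequence[float]],
                      labels_a: Optional[Sequence] = None,
                      labels_b: Optional[Sequence] = None,
                      delta: float = 2.0) -> AgreementResult:
    """Bundle the interrater measures for one rater pair.

    ``score_pairs`` is an (n, 2) matrix of total scores; categorical kappa
    is computed on the label lists when given, otherwise on the
    within-delta dichotomy against the permutation chance model.
    """
    m = np.asarray(score_pairs, dtype=float)
    icc = icc_pairwise(m)
    rate = within_delta_agreement(m[:, 0], m[:, 1], delta)
    if labels_a is not None and labels_b is not None:
        kappa = cohen_kappa(labels_a, labels_b)
    else:
        kappa = within_delta_kappa(m[:, 0], m[:, 1], delta)
    return AgreementResult(icc_pairwise=icc, kappa=kappa,
                           within_delta_rate=rate, delta=delta)


def flag_significance(p: float, family_size: int = 1,
                      policy: SignificancePolicy = SignificancePolicy()) -> bool:
    """Apply the decision rule: p < 0.05 for a single comparison, p < 0.017
    within a three-comparison family (strict inequalities).

    Other family sizes fall back to Bonferroni 0.05/m with a warning.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0,1], got {p}")
    if family_size == 1:
        return p < policy.alpha_univariate
    if family_size == 3:
        return p < policy.alpha_three_group_pairwise
    warnings.warn(
        f"no stated threshold for family size {family_size}; "
        f"using Bonferroni {policy.alpha_univariate}/{family_size}",
        stacklevel=2)
    return p < policy.alpha_univariate / family_size
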