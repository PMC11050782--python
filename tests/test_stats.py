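"""Rank tests, chi-square, and interrater agreement measures.

Independent oracles: exact rank-permutation enumeration (Mann-Whitney),
scipy's own implementations (tie handling), pingouin's ICC decomposition
and scikit-learn's kappa, and hand ANOVA in exact rational arithmetic.
"""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from gmosr.stats import (chi_square_2x2, cohen_kappa, flag_significance,
                         icc_pairwise, kruskal_wallis, mann_whitney,
                         within_delta_agreement, within_delta_kappa)


def exact_mw_midp(u_obs, n1, n2):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data),
    mid-p convention: P(|U-mu| > |u-mu|) + P(|U-mu| = |u-mu|)/2."""
    total = math.comb(n1 + n2, n1)
    mu = n1 * n2 / 2
    gt = eq = 0
    for c in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(c) - n1 * (n1 + 1) // 2
        if abs(u - mu) > abs(u_obs - mu) + 1e-9:
            gt += 1
        elif abs(abs(u - mu) - abs(u_obs - mu)) <= 1e-9:
            eq += 1
    return (gt + eq / 2) / total


class TestMannWhitney:
    def test_identical_groups(self):
        r = mann_whitney([3, 5, 5, 8], [3, 5, 5, 8])
        assert r.statistic == 0 and r.p_two_tailed == 1

    def test_complete_separation_small(self):
        """x={1,2}, y={3,4}: U=0; normal-approximation p differs from the
        enumerated exact p only by the known small-sample gap."""
        r = mann_whitney([1, 2], [3, 4])
        # U1 = rank-sum(x) - n1(n1+1)/2 = 3 - 3 = 0 -> Z negative
        assert r.statistic < 0
        exact = 2 / 6  # P(U in {0, 4}) over all 6 assignments
        assert abs(r.p_two_tailed - exact) < 0.25

    @staticmethod
    def _tie_free_data_with_u(u, n1, n2):
        """Distinct-valued groups whose Mann-Whitney U1 equals ``u``."""
        y = [10.0 * (j + 1) for j in range(n2)]
        q, r = divmod(u, n2)
        x = [10.0 * n2 + 100.0 + i for i in range(q)]       # above all y
        if r:
            x.append(10.0 * r + 5.0)                        # above r of the y
        x += [-1.0 - i for i in range(n1 - len(x))]         # below all y
        return x, y

    def test_asymptotic_close_to_exact_for_moderate_groups(self):
        """Exhaustive over every achievable U for 5 <= n1 <= n2 <= 7: the
        normal-approximation p is within 0.05 of exact enumeration (mid-p)."""
        for n1 in range(5, 8):
            for n2 in range(n1, 8):
                for u in range(n1 * n2 + 1):
                    x, y = self._tie_free_data_with_u(u, n1, n2)
                    p_asym = mann_whitney(x, y).p_two_tailed
                    assert abs(p_asym - exact_mw_midp(u, n1, n2)) < 0.05

    def test_matches_scipy_asymptotic(self, rng):
        for _ in range(20):
            x = rng.integers(0, 39, size=int(rng.integers(5, 40)))
            y = rng.integers(0, 39, size=int(rng.integers(5, 40)))
            r = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, method="asymptotic",
                                   use_continuity=False)
            assert r.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tie_correction_shrinks_variance(self):
        """Closed-form check: ties {1,1,2} vs {1,2,2} reduce the variance
        below the tie-free formula, so |Z| grows."""
        x, y = [1, 1, 2], [1, 2, 2]
        n1 = n2 = 3
        n = 6
        tie_free_var = n1 * n2 * (n + 1) / 12
        # tie groups: three 1s and three 2s
        tie_term = 2 * (3 ** 3 - 3)
        corrected = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        assert corrected < tie_free_var
        r = mann_whitney(x, y)
        # reproduce Z from the closed form independently
        ranks_x = [2, 2, 5]  # midranks
        u1 = sum(ranks_x) - n1 * (n1 + 1) / 2
        z = (u1 - n1 * n2 / 2) / math.sqrt(corrected)
        assert r.statistic == pytest.approx(z, abs=1e-12)

    def test_all_identical_undefined(self):
        r = mann_whitney([4, 4, 4], [4, 4])
        assert r.undefined and math.isnan(r.statistic)
        assert r.p_two_tailed == 1

    def test_swap_negates_z(self, rng):
        x = rng.integers(0, 39, size=15)
        y = rng.integers(0, 39, size=20)
        a, b = mann_whitney(x, y), mann_whitney(y, x)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p_two_tailed == b.p_two_tailed

    def test_direction_of_z(self):
        # group 1 scoring lower -> negative Z (rank-sum direction)
        assert mann_whitney([1, 2, 3], [10, 11, 12]).statistic < 0


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert r.p_two_tailed > 0.99

    def test_h_equals_z_squared_two_groups(self, rng):
        """Tie-free two-group identity H = Z^2 to 1e-9."""
        for _ in range(50):
            xs = rng.choice(np.arange(300), size=27, replace=False)
            x, y = xs[:12].astype(float), xs[12:].astype(float)
            z = mann_whitney(x, y).statistic
            h = kruskal_wallis([x, y]).statistic
            assert h == pytest.approx(z ** 2, abs=1e-9)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            groups = [rng.integers(0, 15, size=int(rng.integers(5, 30)))
                      for _ in range(3)]
            r = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_identical_undefined(self):
        r = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert r.undefined and r.p_two_tailed == 1


class TestChiSquare:
    def test_no_association(self):
        r = chi_square_2x2([[10, 10], [10, 10]])
        assert r.statistic == 0 and r.p_two_tailed == 1

    def test_closed_form(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 60*300^2/30^4
        r = chi_square_2x2([[20, 10], [10, 20]])
        assert r.statistic == pytest.approx(60 * 300 ** 2 / 30 ** 4, abs=1e-12)
        ref = sps.chi2_contingency([[20, 10], [10, 20]], correction=False)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_statistic_linear_in_n(self):
        base = chi_square_2x2([[20, 10], [10, 20]]).statistic
        doubled = chi_square_2x2([[40, 20], [20, 40]]).statistic
        assert doubled == pytest.approx(2 * base, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_continuity_correction_flag(self):
        plain = chi_square_2x2([[20, 10], [10, 20]])
        corr = chi_square_2x2([[20, 10], [10, 20]], continuity_correction=True)
        assert corr.statistic < plain.statistic
        ref = sps.chi2_contingency([[20, 10], [10, 20]], correction=True)
        assert corr.statistic == pytest.approx(ref.statistic, abs=1e-12)


def hand_anova_icc(matrix):
    """ICC(A,1) via two-way ANOVA in exact rational arithmetic."""
    m = [[Fraction(v) for v in row] for row in matrix]
    n, k = len(m), len(m[0])
    grand = sum(sum(r) for r in m) / (n * k)
    rm = [sum(r) / k for r in m]
    cm = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((x - grand) ** 2 for x in rm) / (n - 1)
    msc = n * sum((x - grand) ** 2 for x in cm) / (k - 1)
    mse = sum((m[i][j] - rm[i] - cm[j] + grand) ** 2
              for i in range(n) for j in range(k)) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


FIXTURE_5X2 = [[30, 32], [20, 21], [10, 12], [35, 34], [25, 27]]


class TestICC:
    def test_perfect_duplicates(self):
        assert icc_pairwise([[10, 10], [20, 20], [30, 30]]) == \
            pytest.approx(1.0, abs=1e-12)

    def test_hand_anova_fixture(self):
        expected = hand_anova_icc(FIXTURE_5X2)
        assert expected == Fraction(1705, 1733)  # frozen from the oracle
        assert icc_pairwise(FIXTURE_5X2) == pytest.approx(float(expected),
                                                          abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        m = np.array(FIXTURE_5X2, float)
        df = pd.DataFrame({"t": np.repeat(range(5), 2),
                           "r": list("ab") * 5, "y": m.ravel()})
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_a1 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc_pairwise(m) == pytest.approx(ref_a1, abs=1e-9)

    def test_large_noise_drags_icc_below_half(self, rng):
        """Second rater = first + noise at twice the signal sd: population
        ICC(A,1) = 1/3, so the estimate sits below 0.5."""
        a = rng.normal(20, 1, size=400)
        b = a + rng.normal(0, 2, size=400)
        assert icc_pairwise(np.column_stack([a, b])) < 0.5

    def test_no_variance_undefined(self):
        assert math.isnan(icc_pairwise([[5, 5], [5, 5], [5, 5]]))

    def test_invariant_under_video_permutation(self, rng):
        m = rng.integers(0, 39, size=(12, 2)).astype(float)
        perm = rng.permutation(12)
        assert icc_pairwise(m) == pytest.approx(icc_pairwise(m[perm]),
                                                abs=1e-12)


class TestAgreement:
    def test_within_two_points_counted(self):
        assert within_delta_agreement([10], [12], delta=2) == 1.0
        assert within_delta_agreement([10], [13], delta=2) == 0.0
        assert within_delta_agreement([10, 10, 10], [12, 13, 10]) == \
            pytest.approx(2 / 3)

    def test_kappa_perfect_agreement(self):
        labels = ["N", "PR", "CS", "PR", "N", "CH"]
        assert cohen_kappa(labels, labels) == pytest.approx(1.0)

    def test_kappa_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        a = rng.choice(["N", "PR", "CS"], size=200).tolist()
        b = rng.choice(["N", "PR", "CS"], size=200).tolist()
        assert cohen_kappa(a, b) == pytest.approx(
            sk.cohen_kappa_score(a, b), abs=1e-12)

    def test_kappa_independent_labels_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.choice(["N", "PR", "CS", "CH"], size=10_000).tolist()
        b = rng.choice(["N", "PR", "CS", "CH"], size=10_000).tolist()
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_kappa_undefined_when_chance_saturates(self):
        assert math.isnan(cohen_kappa(["N", "N"], ["N", "N"]))

    def test_kappa_invariant_under_pair_permutation(self, rng):
        a = rng.choice(["N", "PR"], size=50)
        b = rng.choice(["N", "PR"], size=50)
        perm = rng.permutation(50)
        assert cohen_kappa(a.tolist(), b.tolist()) == pytest.approx(
            cohen_kappa(a[perm].tolist(), b[perm].tolist()), abs=1e-12)

    def test_within_delta_kappa_positive_for_real_agreement(self, rng):
        a = rng.integers(5, 35, size=80).astype(float)
        b = a + rng.integers(-1, 2, size=80)
        k = within_delta_kappa(a, b, seed=0)
        assert k > 0.5


class TestSignificancePolicy:
    @pytest.mark.parametrize("p,family,expected", [
        (0.03, 1, True),
        (0.03, 3, False),
        (0.016, 3, True),
        (0.017, 3, False),   # strict inequality at the boundary
        (0.05, 1, False),
    ])
    def test_thresholds(self, p, family, expected):
        assert flag_significance(p, family) is expected

    def test_unsupported_family_falls_back_bonferroni(self):
        with pytest.warns(UserWarning):
            assert flag_significance(0.009, 5) is True
        with pytest.warns(UserWarning):
            assert flag_significance(0.011, 5) is False

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            flag_significance(1.2, 1)
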