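"""Tests for the hypothesis-test engine, cross-checked against scipy,
pingouin and exact enumeration oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import modrer as m
from modrer.stats import skewness

groups = st.lists(st.floats(-50, 50), min_size=2, max_size=25)
small_counts = st.integers(0, 12)


class TestStudentT:
    def test_identical_groups(self):
        res = m.student_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_zero_variance_limits(self):
        assert m.student_t_two_sample([0, 0], [1, 1]).p == 0.0
        assert m.student_t_two_sample([2, 2], [2, 2]).p == 1.0

    @given(groups, groups)
    def test_matches_scipy_pooled(self, g1, g2):
        res = m.student_t_two_sample(g1, g2)
        ref = sps.ttest_ind(g1, g2, equal_var=True)
        if math.isfinite(res.statistic) and ref.pvalue == ref.pvalue:
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_type_i_error_near_nominal(self, rng):
        """Equal-mean normal groups sized like the study cohort reject at
        about the nominal 5% rate."""
        rejections = 0
        reps = 2000
        for _ in range(reps):
            rejections += (
                m.student_t_two_sample(rng.normal(0, 1, 32), rng.normal(0, 1, 39)).p
                < 0.05
            )
        assert rejections / reps == pytest.approx(0.05, abs=0.015)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = m.mann_whitney_u([1, 2, 3], [10, 11, 12, 13])
        assert res.statistic == 0.0  # U1 counts pairs where group1 is larger

    def test_identical_values_p_one(self):
        assert m.mann_whitney_u([5, 5, 5], [5, 5]).p == 1.0

    @given(groups, groups)
    def test_matches_scipy_asymptotic(self, g1, g2):
        res = m.mann_whitney_u(g1, g2)
        if res.p == 1.0 and len(set(g1) | set(g2)) == 1:
            return
        ref = sps.mannwhitneyu(
            g1, g2, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=15),
        st.lists(st.integers(0, 8), min_size=1, max_size=15),
    )
    def test_u_over_pairs_equals_auc(self, g1, g2):
        """U1/(n1*n2) is exactly the empirical AUC of group membership,
        ties included."""
        res = m.mann_whitney_u(g1, g2)
        scores = np.array(list(g1) + list(g2), dtype=float)
        labels = np.array([1] * len(g1) + [0] * len(g2))
        if labels.min() == labels.max():
            return
        auc, _, _ = m.auc_delong(scores, labels)
        assert res.statistic / (len(g1) * len(g2)) == pytest.approx(auc, abs=1e-12)


class TestChi2:
    @pytest.mark.parametrize(
        "table,expected_p",
        [
            ((17, 24, 15, 15), 0.475),  # sex by outcome
            ((13, 3, 19, 36), 0.001),  # death by outcome
            ((15, 10, 17, 29), 0.062),  # chronic respiratory failure
            ((15, 9, 17, 30), 0.035),  # ICU-acquired weakness
        ],
    )
    def test_reference_cohort_counts(self, table, expected_p):
        res = m.pearson_chi2_2x2(m.TwoByTwo(*table))
        assert res.p == pytest.approx(expected_p, abs=5e-4)

    def test_proportional_table_is_null(self):
        res = m.pearson_chi2_2x2(m.TwoByTwo(10, 20, 5, 10))
        assert res.statistic == pytest.approx(0.0, abs=1e-12) and res.p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            m.pearson_chi2_2x2(m.TwoByTwo(0, 0, 5, 5))

    @given(small_counts, small_counts, small_counts, small_counts)
    def test_transposition_and_label_swap_invariance(self, a, b, c, d):
        try:
            base = m.pearson_chi2_2x2(m.TwoByTwo(a, b, c, d))
        except ValueError:
            return
        transposed = m.pearson_chi2_2x2(m.TwoByTwo(a, c, b, d))
        swapped = m.pearson_chi2_2x2(m.TwoByTwo(d, c, b, a))
        assert base.statistic == pytest.approx(transposed.statistic, abs=1e-10)
        assert base.statistic == pytest.approx(swapped.statistic, abs=1e-10)

    @given(small_counts, small_counts, small_counts, small_counts)
    def test_matches_scipy_uncorrected(self, a, b, c, d):
        try:
            res = m.pearson_chi2_2x2(m.TwoByTwo(a, b, c, d))
        except ValueError:
            return
        chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
        assert res.statistic == pytest.approx(chi2, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational two-sided Fisher p by enumerating all tables with the
    observed margins (probability-mass rule)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


class TestFisher:
    def test_reference_dementia_table(self):
        assert m.fisher_exact_2x2(m.TwoByTwo(6, 1, 26, 38)) == pytest.approx(
            0.041, abs=5e-4
        )

    def test_zero_exposure_row(self):
        assert m.fisher_exact_2x2(m.TwoByTwo(0, 0, 5, 7)) == 1.0

    @given(small_counts, small_counts, small_counts, small_counts)
    def test_matches_exact_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = m.fisher_exact_2x2(m.TwoByTwo(a, b, c, d))
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-9)

    @given(small_counts, small_counts, small_counts, small_counts)
    def test_matches_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = m.fisher_exact_2x2(m.TwoByTwo(a, b, c, d))
        assert p == pytest.approx(sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-9)


class TestRmAnova:
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=20),
        st.lists(st.floats(-10, 10), min_size=3, max_size=20),
        st.data(),
    )
    def test_interaction_equals_t_on_change_scores(self, base1, base2, data):
        n1, n2 = len(base1), len(base2)
        post1 = data.draw(st.lists(st.floats(-10, 10), min_size=n1, max_size=n1))
        post2 = data.draw(st.lists(st.floats(-10, 10), min_size=n2, max_size=n2))
        res = m.rm_anova_2x2(base1, post1, base2, post2)
        t = m.student_t_two_sample(
            np.subtract(post1, base1), np.subtract(post2, base2)
        )
        assert res.interaction_p == pytest.approx(t.p, abs=1e-10)

    def test_all_constant_gives_null_time_effect(self):
        res = m.rm_anova_2x2([3, 3, 3], [3, 3, 3], [3, 3], [3, 3])
        assert res.time_p == 1.0 and res.interaction_p == 1.0

    def test_matches_pingouin_mixed_anova(self, rng):
        import pandas as pd
        import pingouin as pg

        n1, n2 = 12, 15
        pre1, post1 = rng.normal(0, 1, n1), rng.normal(0.8, 1, n1)
        pre2, post2 = rng.normal(0, 1, n2), rng.normal(0.1, 1, n2)
        res = m.rm_anova_2x2(pre1, post1, pre2, post2)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n1 + n2), 2),
                "group": np.repeat(["a"] * n1 + ["b"] * n2, 2),
                "time": ["pre", "post"] * (n1 + n2),
                "y": np.column_stack(
                    [np.concatenate([pre1, pre2]), np.concatenate([post1, post2])]
                ).ravel(),
            }
        )
        ref = pg.mixed_anova(
            df, dv="y", within="time", between="group", subject="subject"
        ).set_index("Source")
        assert res.interaction_p == pytest.approx(
            ref.loc["Interaction", "p_unc"], abs=1e-8
        )
        assert res.group_p == pytest.approx(ref.loc["group", "p_unc"], abs=1e-8)

    def test_null_interaction_p_uniform(self, rng):
        """Under identical change distributions the interaction p-value is
        uniform on [0, 1] (KS check over simulated nulls)."""
        ps = []
        for _ in range(400):
            res = m.rm_anova_2x2(
                rng.normal(0, 1, 32), rng.normal(0.5, 1, 32),
                rng.normal(0, 1, 39), rng.normal(0.5, 1, 39),
            )
            ps.append(res.interaction_p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            m.rm_anova_2x2([1.0], [2.0], [1, 2, 3], [1, 2, 3])


class TestSkewness:
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30))
    def test_matches_scipy_bias_corrected(self, values):
        ours = skewness(values)
        ref = sps.skew(np.asarray(values), bias=False)
        if math.isnan(ref):
            assert ours == 0.0
        else:
            assert ours == pytest.approx(ref, abs=1e-8)
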