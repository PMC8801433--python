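"""Descriptive statistics: chi-square, rates, pooled t, scale scoring, alpha."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relapsetrack import datasets
from relapsetrack.descriptives import (
    GroupSummary,
    baseline_table,
    chi_square,
    cronbach_alpha,
    hads_scores,
    pooled_t,
    relapse_rate_table,
    socrates_total,
)
from relapsetrack.errors import ValidationError


def chi_square_oracle(table):
    """From-scratch O/E double loop."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / total
            stat += (t[i, j] - e) ** 2 / e
    return stat


class TestChiSquare:
    def test_relapse_rate_2x2(self):
        stat, df, p = chi_square([[112, 41], [155, 202]])
        assert stat == pytest.approx(38.090, abs=0.01)
        assert df == 1 and p < 0.001

    def test_timing_6x2(self):
        stat, df, _ = chi_square([[17, 163], [6, 9], [7, 11], [8, 13], [2, 5], [1, 1]])
        assert stat == pytest.approx(28.014, abs=0.01)
        assert df == 5

    def test_identical_rows_give_zero(self):
        stat, _, p = chi_square([[30, 70], [60, 140]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [5, 7]])

    @given(st.lists(st.lists(st.integers(1, 200), min_size=2, max_size=4), min_size=2, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_matches_loop_oracle(self, rows):
        width = min(len(r) for r in rows)
        table = [r[:width] for r in rows]
        stat, _, _ = chi_square(table)
        assert stat == pytest.approx(chi_square_oracle(table), abs=1e-9)


class TestRelapseRates:
    def test_printed_rates(self):
        outcomes, groups = datasets.published_outcomes()
        table = relapse_rate_table(outcomes, groups)
        assert table.loc["overall", "relapse_n"] == 243
        assert table.loc["overall", "relapse_pct"] == 47.6
        assert table.loc["experimental", "relapse_pct"] == 26.8
        assert table.loc["control", "relapse_pct"] == 56.6
        assert table.attrs["chi2"] == pytest.approx(38.090, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            relapse_rate_table([], [])


class TestPooledT:
    def test_printed_age_comparison(self):
        t, df = pooled_t(GroupSummary(34.79, 8.039, 139), GroupSummary(33.66, 6.564, 347))
        assert t == pytest.approx(1.602, abs=0.01)
        assert df == 484

    def test_identical_groups_zero(self):
        t, _ = pooled_t(GroupSummary(10, 2, 50), GroupSummary(10, 2, 60))
        assert t == 0.0

    def test_antisymmetric(self):
        a, b = GroupSummary(12.3, 3.1, 40), GroupSummary(11.1, 2.7, 55)
        assert pooled_t(a, b)[0] == pytest.approx(-pooled_t(b, a)[0], abs=1e-12)

    def test_agrees_with_raw_sample_t(self):
        # Oracle: scipy's equal-variance t from the exact same summaries.
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.normal(5, 2, 80)
        y = rng.normal(4.5, 2.2, 120)
        t_ours, _ = pooled_t(
            GroupSummary(x.mean(), x.std(ddof=1), len(x)),
            GroupSummary(y.mean(), y.std(ddof=1), len(y)),
        )
        t_ref, _ = stats.ttest_ind(x, y, equal_var=True)
        assert t_ours == pytest.approx(t_ref, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pooled_t(GroupSummary(5, 0, 10), GroupSummary(5, 0, 10))


class TestScaleScoring:
    def test_socrates_extremes_and_midpoint(self):
        assert socrates_total([1] * 19) == 19
        assert socrates_total([5] * 19) == 95
        assert socrates_total([3] * 19) == 57

    @given(st.lists(st.integers(1, 5), min_size=19, max_size=19))
    @settings(max_examples=50, deadline=None)
    def test_socrates_equals_sum(self, items):
        assert socrates_total(items) == sum(items)

    def test_socrates_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            socrates_total([1] * 18 + [6])

    def test_hads_all_zero(self):
        s = hads_scores([0] * 14)
        assert s == (0, 0, 0, False, False)

    def test_hads_threshold_flags_positive(self):
        items = [0] * 14
        for i in (0, 2, 4, 6):
            items[i] = 2
        s = hads_scores(items)
        assert s.anxiety == 8 and s.anxiety_positive and not s.depression_positive

    def test_hads_reverse_coding(self):
        items = [3] * 14
        s = hads_scores(items, reverse_mask=range(14))
        assert s.total == 0

    @given(
        st.lists(st.integers(0, 3), min_size=14, max_size=14),
        st.sets(st.integers(0, 13), max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_hads_matches_brute_force(self, items, rev):
        s = hads_scores(items, reverse_mask=sorted(rev))
        scored = [3 - x if i in rev else x for i, x in enumerate(items)]
        anx = sum(scored[i] for i in (0, 2, 4, 6, 8, 10, 12))
        assert s.anxiety == anx
        assert s.total == sum(scored)
        assert s.depression_positive == (s.depression >= 8)


class TestCronbachAlpha:
    def test_parallel_items_give_one(self):
        col = np.random.default_rng(0).normal(size=50)
        X = np.column_stack([col, col, col])
        assert cronbach_alpha(X) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20000, 5))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_hand_computed_small_matrix(self):
        X = np.array([[1, 2, 1], [2, 3, 3], [3, 4, 4], [4, 6, 5]], dtype=float)
        # Pencil-and-paper: item variances 5/3, 35/12, 35/12; totals (4, 8, 11, 15)
        # have variance 65/3, so alpha = 3/2 * (1 - (90/12)/(260/12)) = 51/52.
        k = 3
        expected = k / (k - 1) * (1 - (5 / 3 + 35 / 12 + 35 / 12) / (65 / 3))
        assert expected == pytest.approx(51 / 52)
        assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(2)
        base = rng.normal(size=(200, 1))
        X = base + rng.normal(scale=0.8, size=(200, 6))
        ours = cronbach_alpha(X)
        theirs = pg.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_shift_invariant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 4))
        assert cronbach_alpha(X) == pytest.approx(cronbach_alpha(X + 7.5), abs=1e-10)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValidationError):
            cronbach_alpha(np.ones((10, 3)))


def test_baseline_table_shapes_and_stats():
    from tests.conftest import make_recovery_dataset
    from relapsetrack.cohort import cohort_to_frame

    cohort, _, _ = make_recovery_dataset(n=240, seed=5)
    table = baseline_table(cohort_to_frame(cohort))
    assert {"age", "marital", "socrates_total"} <= set(table["variable"])
    t_rows = table[table["kind"] == "t"]
    assert np.isfinite(t_rows["statistic"]).all()
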