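import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from condlab import (
    ConditioningTable,
    cohen_d_from_t,
    descriptives,
    independent_ttest,
    paired_ttest,
    run_frequentist,
    select_test,
)


class TestSelectTest:
    def test_paired_without_group(self, small_table):
        assert select_test(small_table) == "paired"

    def test_independent_with_group(self, grouped_table):
        assert select_test(grouped_table) == "independent"
        res = run_frequentist(grouped_table)
        assert res.test_name == "independent"
        assert res.nu == grouped_table.n - 2


class TestDescriptives:
    def test_hand_values(self):
        t = ConditioningTable(cs1=[2.0, 4, 6], cs2=[5.0, 5, 5])
        d = descriptives(t).set_index("stimulus")
        assert d.loc["cs1", "mean"] == 4
        assert d.loc["cs1", "sd"] == pytest.approx(2.0)
        assert d.loc["cs1", "se"] == pytest.approx(2 / np.sqrt(3))
        assert d.loc["cs2", "sd"] == 0  # constant column

    def test_grouped_blocks(self, grouped_table):
        d = descriptives(grouped_table)
        # one block per group per stimulus
        assert len(d) == 4
        assert set(d["group"]) == {"g1", "g2"}
        assert (d["n"] == 20).all()


class TestPairedTTest:
    def test_hand_example(self, small_table):
        # diffs [2, 3, 1]: t = 2/(1/sqrt(3)), nu = 2, d = 2
        res = paired_ttest(small_table)
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.nu == 2
        assert res.cohen_d == pytest.approx(2.0, rel=1e-12)
        assert res.mean_diff == pytest.approx(2.0)

    def test_zero_variance_diffs_error(self):
        t = ConditioningTable(cs1=[1.0, 2, 4], cs2=[1.0, 2, 4])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_ttest(t)

    def test_printed_p_value(self):
        # t = 2.92 on 39 df gives the two-sided p printed as .006
        p = 2 * stats.t.sf(2.92, 39)
        assert round(p, 3) == 0.006

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(3, 12)
            cs1 = rng.normal(size=n)
            cs2 = rng.normal(size=n)
            res = paired_ttest(ConditioningTable(cs1=cs1, cs2=cs2))
            ref = stats.ttest_rel(cs1, cs2)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)
            assert res.nu == n - 1

    def test_ci_covers_mean_diff(self, acq_like_table):
        res = paired_ttest(acq_like_table)
        lo, hi = res.ci95
        assert lo < res.mean_diff < hi

    @given(
        st.lists(
            st.floats(-50, 50).filter(lambda x: abs(x) > 1e-6),
            min_size=3,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_cohen_d_consistency(self, diffs):
        cs2 = np.zeros(len(diffs))
        d = np.asarray(diffs)
        if np.std(d, ddof=1) < 1e-9:
            return
        res = paired_ttest(ConditioningTable(cs1=d, cs2=cs2))
        assert res.cohen_d == pytest.approx(
            cohen_d_from_t(res.t, len(d)), abs=1e-12, rel=1e-12
        )
        assert np.sign(res.cohen_d) == np.sign(res.t)


class TestIndependentTTest:
    def test_identical_groups_t_zero(self):
        res = independent_ttest([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == 0
        assert res.cohen_d == 0

    def test_hand_example(self):
        # means 3 vs 1, pooled sd sqrt(2), t = 2/(sqrt(2)*1) = sqrt(2)
        res = independent_ttest([2.0, 4.0], [0.0, 2.0])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.t == pytest.approx(np.sqrt(2), rel=1e-12)
        assert res.nu == 2

    def test_p_is_two_sided_central_t(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x1, x2 = rng.normal(size=8), rng.normal(0.5, 1, size=6)
            res = independent_ttest(x1, x2)
            assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), res.nu), rel=1e-12)
            ref = stats.ttest_ind(x1, x2, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError, match="zero pooled"):
            independent_ttest([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="at least 2"):
            independent_ttest([1.0], [1.0, 2.0])


class TestCohenDFromT:
    @pytest.mark.parametrize(
        "t, n1, n2, expected",
        [
            (2.92, 40, None, 0.46),  # acquisition-phase paired effect
            (2.185, 40, None, 0.35),  # reinstatement-phase paired effect
            (0.0, 17, None, 0.0),
            (0.0, 10, 12, 0.0),
        ],
    )
    def test_examples(self, t, n1, n2, expected):
        assert round(cohen_d_from_t(t, n1, n2), 2) == expected

    def test_independent_formula(self):
        assert cohen_d_from_t(2.0, 10, 40) == pytest.approx(2 * np.sqrt(1 / 10 + 1 / 40))
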