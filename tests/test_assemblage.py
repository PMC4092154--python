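import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from zicpue.assemblage import (
    kruskal_wallis,
    kw_posthoc,
    length_ttest,
    reconstruct_counts,
    sex_by_period_test,
    sex_ratio_gof,
)
from zicpue.errors import ReconstructionError, UndefinedTestError
from zicpue.published import SEX_RATIO_REPORTS


class TestSexRatio:
    def test_blacknose_worked_value(self):
        res = sex_ratio_gof(53, 69)
        assert round(res.statistic, 3) == 2.098
        assert res.df == 1

    def test_nurse_worked_value(self):
        res = sex_ratio_gof(51, 65)
        assert round(res.statistic, 4) == 1.6897

    def test_perfect_balance(self):
        res = sex_ratio_gof(61, 61)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_label_swap_invariance_and_two_cell_identity(self):
        a = sex_ratio_gof(40, 25)
        b = sex_ratio_gof(25, 40)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.statistic == pytest.approx((40 - 25) ** 2 / 65)

    def test_empty_errors(self):
        with pytest.raises(UndefinedTestError):
            sex_ratio_gof(0, 0)


class TestReconstructCounts:
    def test_published_ratios_recover_unique_splits(self):
        rep = SEX_RATIO_REPORTS["carcharhinus acronotus"]
        assert reconstruct_counts(rep["ratio"], rep["n_sexed"]) == (53, 69)
        rep = SEX_RATIO_REPORTS["ginglymostoma cirratum"]
        assert reconstruct_counts(rep["ratio"], rep["n_sexed"]) == (51, 65)

    def test_trivial_even_split(self):
        assert reconstruct_counts(1.00, 2) == (1, 1)

    def test_inconsistent_printed_ratio_rejected(self):
        # the published tiger-shark line (0.69:1 of 56) has no integer split
        with pytest.raises(ReconstructionError):
            reconstruct_counts(0.69, 56)


class TestSexByPeriod:
    def test_identical_columns_zero(self):
        res = sex_by_period_test(np.array([[10, 10, 10], [20, 20, 20]]))
        assert res.statistic == pytest.approx(0.0)

    def test_two_by_two_hand_value(self):
        res = sex_by_period_test(np.array([[10, 20], [20, 10]]))
        assert round(res.statistic, 3) == 6.667
        assert res.df == 1

    def test_zero_margin_errors(self):
        with pytest.raises(UndefinedTestError):
            sex_by_period_test(np.array([[0, 0], [5, 5]]))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            # independent margins: P(row) x P(col) cell probabilities
            table = rng.multinomial(500, [0.125, 0.25, 0.125, 0.125, 0.25, 0.125])
            table = table.reshape(2, 3)
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            if sex_by_period_test(table).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.08


class TestLengthTtest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        res = length_ttest(a, a)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_welch_value(self):
        res = length_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert round(res.statistic, 3) == -3.674

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            length_ttest(rng.normal(size=20), rng.normal(size=25)).p < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rejections / 2000 <= 0.07


def _kw_h(groups):
    """Rank-based H with tie correction, straight from the definition."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start: start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_all_constant(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0

    def test_hand_rank_value(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert round(res.statistic, 1) == 7.2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=6), rng.normal(size=7)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_empty_group_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = kruskal_wallis([[1.0, 2.0], [], [3.0, 4.0]])
        assert res.df == 1

    def test_against_exhaustive_permutation(self):
        # brute-force oracle on three groups of 3 distinct values
        data = [1.0, 5.0, 9.0, 2.0, 6.0, 7.0, 3.0, 4.0, 8.0]
        groups = [data[:3], data[3:6], data[6:]]
        h_obs = kruskal_wallis(groups).statistic
        p_obs = kruskal_wallis(groups).p
        count = 0
        total = 0
        for combo in itertools.combinations(range(9), 3):
            rest = [i for i in range(9) if i not in combo]
            for combo2 in itertools.combinations(rest, 3):
                g1 = [data[i] for i in combo]
                g2 = [data[i] for i in combo2]
                g3 = [data[i] for i in rest if i not in combo2]
                total += 1
                if _kw_h([g1, g2, g3]) >= h_obs - 1e-12:
                    count += 1
        p_perm = count / total
        assert total == 1680
        assert abs(p_obs - p_perm) < 0.02


class TestPosthoc:
    def test_critical_difference_formula(self):
        # 3 groups of 3, alpha 0.05: z_{1-0.05/6} * sqrt(9*10/12 * 2/3)
        res = kw_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]], alpha=0.05)
        for _, _, _, crit, _ in res.pairs:
            assert round(crit, 3) == 5.353

    def test_identical_groups_nothing_significant(self):
        res = kw_posthoc([[1.0, 2.0, 3.0]] * 3)
        assert res.significant_pairs() == []

    def test_single_shifted_group_detected(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(0, 0.1, 15)
        g2 = rng.normal(0, 0.1, 15)
        g3 = rng.normal(50, 0.1, 15)
        res = kw_posthoc([g1, g2, g3], labels=["a", "b", "c"])
        assert set(res.significant_pairs()) == {("a", "c"), ("b", "c")}

    @given(alpha=st.sampled_from([0.10, 0.05, 0.01, 0.001]))
    @settings(max_examples=10, deadline=None)
    def test_crit_increases_as_alpha_decreases(self, alpha):
        groups = [[1.0, 2.0, 5.0], [3.0, 4.0, 6.0]]
        crit = kw_posthoc(groups, alpha=alpha).pairs[0][3]
        crit_tighter = kw_posthoc(groups, alpha=alpha / 10).pairs[0][3]
        assert crit_tighter > crit
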