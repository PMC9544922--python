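"""ANOVA designs, post-hocs, sphericity correction, exact Mann-Whitney.

Each implemented test is checked against an independent route: hand-coded
sums of squares, scipy reference distributions/tests, statsmodels Tukey,
scipy Dunnett, pingouin mixed ANOVA, and brute-force enumeration for the
exact Mann-Whitney p-value.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from mepkit.stats import (
    gg_epsilon,
    mann_whitney_exact,
    one_way_anova,
    pairwise_posthoc,
    rm_anova_split_plot,
)

# fixed 3x5 fixture used across oracle comparisons
FIXTURE_GROUPS = [
    np.array([12.1, 14.3, 13.8, 12.9, 13.4]),
    np.array([15.2, 16.1, 14.9, 15.8, 16.4]),
    np.array([13.0, 12.2, 13.7, 12.5, 13.1]),
]


def _oneway_f_oracle(groups):
    """Brute-force between/within sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((v - g.mean()) ** 2) for g in groups for v in g)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    return (ssb / df1) / (ssw / df2)


class TestOneWayAnova:
    def test_matches_sums_of_squares_oracle_and_scipy(self):
        res = one_way_anova(FIXTURE_GROUPS)
        assert res.statistic == pytest.approx(_oneway_f_oracle(FIXTURE_GROUPS), abs=1e-10)
        ref = sstats.f_oneway(*FIXTURE_GROUPS)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_means_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        res = one_way_anova([g, g + 0.0, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(size=8), rng.normal(loc=0.7, size=11)
        res = one_way_anova([x, y])
        t = sstats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_degenerate_no_variance_equal_means(self):
        res = one_way_anova([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert res.p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([np.array([1.0, 2.0])])

    def test_null_p_values_are_uniform(self, rng):
        pvals = [
            one_way_anova([rng.normal(size=6) for _ in range(3)]).p for _ in range(2000)
        ]
        assert sstats.kstest(pvals, "uniform").pvalue > 0.01


class TestPosthoc:
    def test_bonferroni_single_comparison_equals_raw_t(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        (pair, p_adj), = pairwise_posthoc([x, y], method="bonferroni")
        t = sstats.ttest_ind(x, y)
        assert p_adj == pytest.approx(t.pvalue, rel=1e-10)

    def test_identical_groups_all_adjusted_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        for method in ("tukey", "bonferroni"):
            for _, p in pairwise_posthoc([g.copy(), g.copy(), g.copy()], method=method):
                assert p == pytest.approx(1.0)

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(FIXTURE_GROUPS)
        labels = np.repeat(["a", "b", "c"], [len(g) for g in FIXTURE_GROUPS])
        ref = pairwise_tukeyhsd(values, labels)
        ours = dict(pairwise_posthoc(FIXTURE_GROUPS, method="tukey"))
        for (i, j), p_ref in zip(combinations(range(3), 2), ref.pvalues):
            assert ours[(i, j)] == pytest.approx(p_ref, abs=1e-4)

    def test_dunnett_matches_scipy_within_mc_error(self):
        ref = sstats.dunnett(
            FIXTURE_GROUPS[1], FIXTURE_GROUPS[2], control=FIXTURE_GROUPS[0]
        )
        ours = dict(
            pairwise_posthoc(FIXTURE_GROUPS, method="dunnett_mc", control=0, seed=99)
        )
        for idx, p_ref in zip((1, 2), ref.pvalue):
            assert ours[(idx, 0)] == pytest.approx(p_ref, abs=0.01)

    def test_dunnett_requires_control_and_seed(self):
        with pytest.raises(ValueError):
            pairwise_posthoc(FIXTURE_GROUPS, method="dunnett_mc", seed=1)
        with pytest.raises(ValueError):
            pairwise_posthoc(FIXTURE_GROUPS, method="dunnett_mc", control=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            pairwise_posthoc(FIXTURE_GROUPS, method="scheffe")


def _panel(y, groups):
    """subjects x weeks matrix plus group labels -> tidy longitudinal table."""
    n, k = y.shape
    rows = [
        (f"s{i}", groups[i], w, "m", y[i, w]) for i in range(n) for w in range(k)
    ]
    return pd.DataFrame(rows, columns=["animal_id", "group", "week", "measure", "value"])


class TestSplitPlotRM:
    def _fixture(self):
        rng = np.random.default_rng(42)
        n_per, k, g = 4, 5, 3
        subj = rng.normal(0, 1.0, size=n_per * g)[:, None]
        week_eff = np.linspace(0, 2, k)[None, :]
        group_eff = np.repeat([0.0, 1.0, 2.5], n_per)[:, None]
        y = 10 + subj + week_eff + group_eff + rng.normal(0, 0.5, size=(n_per * g, k))
        groups = np.repeat(["a", "b", "c"], n_per)
        return y, groups

    def test_f_terms_match_pingouin(self):
        import pingouin as pg

        y, groups = self._fixture()
        table = _panel(y, groups)
        res = rm_anova_split_plot(table)
        ref = pg.mixed_anova(
            table.rename(columns={"animal_id": "subj", "group": "grp", "week": "wk"}),
            dv="value", within="wk", subject="subj", between="grp",
        ).set_index("Source")
        assert res.effect_terms["treatment"][0] == pytest.approx(ref.loc["grp", "F"], abs=1e-8)
        assert res.effect_terms["time"][0] == pytest.approx(ref.loc["wk", "F"], abs=1e-8)
        assert res.effect_terms["interaction"][0] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8
        )

    def test_uncorrected_dfs_follow_split_plot_design(self):
        y, groups = self._fixture()
        res = rm_anova_split_plot(_panel(y, groups), gg_correction=False)
        n, k, g = 12, 5, 3
        assert res.effect_terms["treatment"][1] == (g - 1, n - g)
        assert res.effect_terms["time"][1] == (k - 1, (k - 1) * (n - g))
        assert res.effect_terms["interaction"][1] == ((g - 1) * (k - 1), (k - 1) * (n - g))

    def test_gg_correction_scales_within_dfs_by_epsilon(self):
        y, groups = self._fixture()
        res = rm_anova_split_plot(_panel(y, groups), gg_correction=True)
        eps = res.extra["epsilon"]
        k, n, g = 5, 12, 3
        assert res.effect_terms["time"][1][0] == pytest.approx(eps * (k - 1))
        assert res.effect_terms["time"][1][1] == pytest.approx(eps * (k - 1) * (n - g))
        assert 1.0 / (k - 1) <= eps <= 1.0

    def test_unbalanced_panel_rejected(self):
        y, groups = self._fixture()
        table = _panel(y, groups).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_split_plot(table)

    def test_compound_symmetry_epsilon_near_one_at_large_n(self):
        # exchangeable covariance satisfies sphericity: epsilon -> 1
        rng = np.random.default_rng(7)
        n, k = 200, 6
        shared = rng.normal(size=(n, 1))
        y = shared + rng.normal(size=(n, k))
        eps = gg_epsilon(np.cov(y, rowvar=False))
        assert eps == pytest.approx(1.0, abs=0.05)

    def test_epsilon_matches_pingouin_on_single_group(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        y = rng.normal(size=(12, 5)) + rng.normal(size=(12, 1))
        ours = gg_epsilon(np.cov(y, rowvar=False))
        ref = pg.epsilon(pd.DataFrame(y), correction="gg")
        assert ours == pytest.approx(ref, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_epsilon_bounds_hold_for_random_covariances(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        a = rng.normal(size=(k + 3, k))
        eps = gg_epsilon(a.T @ a)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


def _mw_bruteforce_p(x, y):
    """Independent oracle: U by pairwise comparison counts, p by enumeration."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        return sum(
            1.0 if ai > bj else (0.5 if ai == bj else 0.0) for ai in a for bj in b
        )

    mean_u = n1 * (len(pooled) - n1) / 2.0
    observed = abs(u_stat(range(n1)) - mean_u)
    assignments = list(combinations(range(len(pooled)), n1))
    hits = sum(1 for idx in assignments if abs(u_stat(idx) - mean_u) >= observed - 1e-9)
    return hits / len(assignments)


class TestMannWhitneyExact:
    def test_reference_five_vs_three_example(self):
        # motor-neuron counts at one spinal level: 44 of 56 assignments as extreme
        res = mann_whitney_exact([29, 9, 58, 18, 2], [11, 38, 25])
        assert res.p == pytest.approx(44 / 56)
        assert res.extra["n_assignments"] == 56

    def test_two_vs_two_enumeration(self):
        res = mann_whitney_exact([1.0, 2.0], [3.0, 4.0])
        assert res.p == pytest.approx(2 / 6)

    def test_symmetric_in_sample_order(self, rng):
        for _ in range(5):
            x = rng.integers(0, 20, size=4).astype(float)
            y = rng.integers(0, 20, size=5).astype(float)
            assert mann_whitney_exact(x, y).p == pytest.approx(mann_whitney_exact(y, x).p)

    def test_matches_bruteforce_oracle_on_random_small_instances(self, rng):
        for _ in range(30):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            # integer draws make ties common, exercising mid-ranks
            x = rng.integers(0, 8, size=n1).astype(float)
            y = rng.integers(0, 8, size=n2).astype(float)
            assert mann_whitney_exact(x, y).p == pytest.approx(_mw_bruteforce_p(x, y))

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=4)
        ref = sstats.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert mann_whitney_exact(x, y).p == pytest.approx(ref.pvalue)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="guard"):
            mann_whitney_exact(np.arange(30.0), np.arange(30.0))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_null_rejection_rate_is_conservative(self, rng):
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x, y = rng.normal(size=4), rng.normal(size=4)
            rejections += mann_whitney_exact(x, y).p < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 2 * se
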