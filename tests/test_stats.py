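"""Descriptives, t tests, ANOVA, bin exclusion and relative expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from isletquant import (
    anova_oneway,
    anova_twoway,
    delta_delta_ct,
    exclude_sparse_bins,
    summarize,
    t_test_unpaired,
)


class TestSummarize:
    def test_constant_group(self):
        (s,) = summarize({"a": np.array([2.0, 2.0, 2.0])})
        assert (s.n, s.mean, s.sd, s.sem) == (3, 2.0, 0.0, 0.0)

    def test_closed_form(self):
        (s,) = summarize({"a": np.array([1.0, 2.0, 3.0])})
        assert s.mean == 2.0
        assert s.sd == pytest.approx(1.0)
        assert s.sem == pytest.approx(1.0 / np.sqrt(3.0))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize({"a": np.array([])})

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10.0, 3.0, size=40)
        (s,) = summarize({"g": values})
        assert s.mean == pytest.approx(values.sum() / 40)
        assert s.sd == pytest.approx(np.sqrt(((values - values.mean()) ** 2).sum() / 39))


class TestTTest:
    def test_identical_groups(self):
        r = t_test_unpaired(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert r.statistic == 0.0 and r.p == 1.0

    @pytest.mark.parametrize("na, nb, df", [(126, 130, 254), (8, 8, 14), (11, 11, 20)])
    def test_pooled_degrees_of_freedom(self, na, nb, df):
        rng = np.random.default_rng(1)
        r = t_test_unpaired(rng.normal(size=na), rng.normal(size=nb))
        assert r.df == (float(df),)

    def test_zero_variance_with_unequal_means_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            t_test_unpaired(np.array([1.0, 1.0]), np.array([2.0, 2.0]))

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(0.5, 1.2, size=15)
        ours = t_test_unpaired(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_bonferroni_adjustment_caps_at_one(self):
        rng = np.random.default_rng(3)
        r = t_test_unpaired(rng.normal(size=10), rng.normal(size=10), family_size=50)
        assert r.p_adjusted == min(1.0, 50 * r.p)
        assert r.p_adjusted >= r.p


class TestOneWayAnova:
    def test_hand_computed_three_group_example(self):
        groups = {
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([2.0, 3.0, 4.0]),
            "c": np.array([6.0, 7.0, 8.0]),
        }
        # grand mean 4; SSB = 3(4+1+9) = 42, SSW = 6; F = (42/2)/(6/6) = 21
        omnibus, posthoc = anova_oneway(groups)
        assert omnibus.statistic == pytest.approx(21.0, abs=1e-9)
        assert omnibus.df == (2.0, 6.0)
        ref = sps.f_oneway(*groups.values())
        assert omnibus.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert len(posthoc) == 3 and all(r.family_size == 3 for r in posthoc)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        omnibus, _ = anova_oneway({"a": a, "b": b})
        t = t_test_unpaired(a, b)
        assert omnibus.statistic == pytest.approx(t.statistic**2, abs=1e-9)

    def test_all_identical_constant_groups(self):
        omnibus, _ = anova_oneway({"a": np.ones(3), "b": np.ones(4)})
        assert omnibus.statistic == 0.0 and omnibus.p == 1.0

    def test_declared_comparison_family_sets_m(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(size=6) for g in "abcd"}
        _, posthoc = anova_oneway(groups, comparisons=[("a", "b"), ("a", "c")])
        assert len(posthoc) == 2 and all(r.family_size == 2 for r in posthoc)


class TestTwoWayAnova:
    @staticmethod
    def _balanced(seed=0, effect_a=0.0, interaction=0.0, n=8):
        rng = np.random.default_rng(seed)
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                mu = effect_a * a + 0.7 * b + interaction * a * b
                for y in rng.normal(mu, 1.0, size=n):
                    rows.append((y, a, b))
        arr = np.array(rows)
        return arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(int)

    def test_purely_additive_construction_has_zero_interaction(self):
        # exactly additive cell means, duplicated replicates: interaction SS = 0
        y, a, b = [], [], []
        for fa in (0, 1):
            for fb in (0, 1):
                for rep in (-0.5, 0.5):
                    y.append(1.0 * fa + 2.0 * fb + rep)
                    a.append(fa)
                    b.append(fb)
        res = anova_twoway(np.array(y), np.array(a), np.array(b))
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_balanced_marginal_equals_sequential_sums_of_squares(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        y, a, b = self._balanced(seed=6, effect_a=0.4, interaction=0.2)
        res = anova_twoway(y, a, b)
        df = pd.DataFrame({"y": y, "A": pd.Categorical(a), "B": pd.Categorical(b)})
        seq = sm.stats.anova_lm(smf.ols("y ~ C(A) * C(B)", data=df).fit(), typ=1)
        assert res["factor_a"].statistic == pytest.approx(seq.loc["C(A)", "F"], rel=1e-9)
        assert res["factor_b"].statistic == pytest.approx(seq.loc["C(B)", "F"], rel=1e-9)

    def test_known_main_effect_is_detected_in_most_simulations(self):
        """Power check: a 0.5 SD main effect at n=50/cell is found (p<0.05)
        in at least 80% of 200 simulated designs."""
        hits = 0
        for seed in range(200):
            y, a, b = self._balanced(seed=seed, effect_a=0.5, n=50)
            res = anova_twoway(y, a, b)
            hits += res["factor_a"].p < 0.05
        assert hits / 200 >= 0.80

    def test_empty_cell_raises_instructing_exclusion(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 1.0])
        a = np.array([0, 0, 1, 1, 0, 0])
        b = np.array([0, 1, 0, 0, 0, 1])  # cell (a=1, b=1) empty
        with pytest.raises(ValueError, match="exclusion"):
            anova_twoway(y, a, b)


class TestExcludeSparseBins:
    @staticmethod
    def _table(spec):
        rows = [
            {"group": g, "size_bin": b}
            for g, bins in spec.items()
            for b, n in bins.items()
            for _ in range(n)
        ]
        return pd.DataFrame(rows)

    def test_bin_dropped_when_any_group_is_sparse(self):
        table = self._table({"A": {0: 10, 1: 4}, "B": {0: 7, 1: 9}})
        kept, dropped = exclude_sparse_bins(table, "group")
        assert dropped == [1]
        assert set(kept["size_bin"]) == {0}
        assert len(kept) == 17

    def test_identity_when_all_bins_are_populated(self):
        table = self._table({"A": {0: 5, 1: 6}, "B": {0: 9, 1: 5}})
        kept, dropped = exclude_sparse_bins(table, "group")
        assert dropped == [] and len(kept) == len(table)

    def test_bin_absent_from_one_group_counts_as_zero(self):
        table = self._table({"A": {0: 8}, "B": {0: 8, 2: 6}})
        kept, dropped = exclude_sparse_bins(table, "group")
        assert dropped == [2]

    def test_matches_brute_force_recount_on_a_random_cohort(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {
                "group": rng.choice(["a", "b", "c"], size=3000),
                "size_bin": rng.geometric(0.35, size=3000) - 1,
            }
        )
        kept, dropped = exclude_sparse_bins(table, "group")
        for b in sorted(table["size_bin"].unique()):
            sparse = any(
                ((table["group"] == g) & (table["size_bin"] == b)).sum() < 5
                for g in ("a", "b", "c")
            )
            assert (b in dropped) == sparse
            assert ((kept["size_bin"] == b).any()) == (not sparse)


class TestDeltaDeltaCt:
    @staticmethod
    def _samples(rows):
        return pd.DataFrame(
            rows, columns=["condition", "ct_target", "ct_ref1", "ct_ref2", "ct_ref3", "ct_ref4"]
        )

    def test_control_fold_is_one(self):
        s = self._samples([("ctrl", 25.0, 20, 21, 22, 23), ("ctrl2", 25.0, 20, 21, 22, 23)])
        out = delta_delta_ct(s, "ctrl")
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)
        assert out.loc[1, "fold_change"] == pytest.approx(1.0)

    def test_reference_mean_normalisation(self):
        s = self._samples([("ctrl", 25.0, 20, 21, 22, 23)])
        out = delta_delta_ct(s, "ctrl")
        assert out.loc[0, "delta_ct"] == pytest.approx(3.5)  # 25 - mean(20..23)

    def test_two_cycle_difference_is_fourfold(self):
        s = self._samples([("ctrl", 25.0, 20, 20, 20, 20), ("cyt", 23.0, 20, 20, 20, 20)])
        out = delta_delta_ct(s, "ctrl")
        assert out.loc[1, "fold_change"] == pytest.approx(4.0)

    def test_missing_reference_is_an_error(self):
        s = self._samples([("ctrl", 25.0, 20, 21, 22, np.nan)])
        with pytest.raises(ValueError, match="missing Ct"):
            delta_delta_ct(s, "ctrl")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(min_value=-5.0, max_value=5.0))
    def test_fold_changes_are_invariant_to_a_global_ct_shift(self, shift):
        base = self._samples(
            [("ctrl", 25.0, 20, 21, 22, 23), ("cyt", 22.0, 19.5, 21, 22.5, 23)]
        )
        shifted = base.copy()
        for col in ("ct_target", "ct_ref1", "ct_ref2", "ct_ref3", "ct_ref4"):
            shifted[col] += shift
        a = delta_delta_ct(base, "ctrl")["fold_change"]
        b = delta_delta_ct(shifted, "ctrl")["fold_change"]
        np.testing.assert_allclose(a, b, rtol=1e-9)
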