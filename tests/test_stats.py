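"""t-tests, ANOVA partitions, post hocs, Fisher's exact test, regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from fearlfp.stats import (StatResult, bonferroni, f_pvalue, fisher_exact,
                           linregress, one_way_rm_anova, t_pvalue, t_test,
                           tukey_posthoc, two_way_mixed_anova,
                           two_way_rm_anova)


class TestTailProbabilities:
    def test_t_zero_gives_p_one(self):
        assert t_pvalue(0.0, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("t, df, printed", [
        (3.26, 27, 0.003),   # group difference on cell counts
        (2.59, 27, 0.015),
        (2.45, 27, 0.021),
        (0.71, 27, 0.484),
    ])
    def test_t_triplets_reproduce_printed_p(self, t, df, printed):
        assert t_pvalue(t, df) == pytest.approx(printed, abs=5e-4)

    @pytest.mark.parametrize("F, df1, df2, printed", [
        (5.44, 5, 20, 0.003),    # freezing across conditioning trials
        (9.664, 2, 10, 0.0046),
        (8.66, 1, 27, 0.007),
        (7.376, 1, 6, 0.035),
        (7.233, 1, 6, 0.036),
        (9.70, 1, 20, 0.0055),
        (10.61, 1, 20, 0.004),
    ])
    def test_f_triplets_reproduce_printed_p(self, F, df1, df2, printed):
        assert f_pvalue(F, df1, df2) == pytest.approx(printed, abs=5e-4)

    def test_f_of_one_df_equals_squared_t(self):
        for t, df in [(1.3, 5), (2.7, 12), (0.4, 30)]:
            assert f_pvalue(t * t, 1, df) == pytest.approx(t_pvalue(t, df))

    def test_tails_monotone_in_statistic(self):
        ts = np.linspace(0.1, 5.0, 20)
        ps = [t_pvalue(t, 9) for t in ts]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestTTest:
    def test_identical_paired_samples_give_t_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        r = t_test(x, x, paired=True)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_unpaired_uses_pooled_df(self):
        x, y = np.arange(14.0), np.arange(14.0) + 2.0
        r = t_test(x, y)
        assert r.df == (26,)

    def test_matches_hand_arithmetic(self):
        # pooled-variance formula by hand on a tiny fixed sample
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 6.0])
        sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / 3.0
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 2))
        r = t_test(x, y)
        assert r.statistic == pytest.approx(t_hand)
        assert r.p == pytest.approx(t_pvalue(t_hand, 3))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0, 1.0], [2.0, 2.0])


class TestRmAnova:
    def test_two_level_factor_equals_paired_t_squared(self):
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(rng.standard_normal((8, 2)), columns=["a", "b"])
        table = one_way_rm_anova(wide)
        F = table.effect("condition")
        t = t_test(wide["a"].to_numpy(), wide["b"].to_numpy(), paired=True)
        assert F.statistic == pytest.approx(t.statistic ** 2)
        assert F.p == pytest.approx(t.p)

    def test_matches_brute_force_ss_partition(self):
        # 3 subjects x 3 conditions, sums of squares enumerated directly
        y = np.array([[4.0, 6.0, 8.0],
                      [3.0, 5.0, 9.0],
                      [5.0, 8.0, 10.0]])
        grand = y.mean()
        ss_cond = 3 * sum((y[:, j].mean() - grand) ** 2 for j in range(3))
        ss_subj = 3 * sum((y[i].mean() - grand) ** 2 for i in range(3))
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        F_hand = (ss_cond / 2) / (ss_err / 4)
        table = one_way_rm_anova(pd.DataFrame(y))
        eff = table.effect("condition")
        assert eff.statistic == pytest.approx(F_hand)
        assert eff.df == (2, 4)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        n, k = 10, 4
        wide = pd.DataFrame(rng.standard_normal((n, k)) + np.arange(k),
                            columns=list("abcd"))
        ours = one_way_rm_anova(wide).effect("condition")
        long = wide.reset_index().melt(id_vars="index", var_name="cond")
        ref = pingouin.rm_anova(data=long, dv="value", within="cond",
                                subject="index")
        assert ours.statistic == pytest.approx(ref["F"][0], rel=1e-9)
        assert ours.p == pytest.approx(ref["p_unc"][0], rel=1e-9)

    def test_condition_permutation_invariance(self):
        rng = np.random.default_rng(2)
        wide = pd.DataFrame(rng.standard_normal((6, 3)))
        f1 = one_way_rm_anova(wide).effect("condition").statistic
        f2 = one_way_rm_anova(wide[[2, 0, 1]]).effect("condition").statistic
        assert f1 == pytest.approx(f2)

    def test_missing_cells_rejected(self):
        wide = pd.DataFrame([[1.0, 2.0], [3.0, np.nan]])
        with pytest.raises(ValueError):
            one_way_rm_anova(wide)


class TestMixedAnova:
    def make_long(self, rng, g=2, n=6, k=3):
        rows = []
        for gi in range(g):
            for si in range(n):
                for ki in range(k):
                    rows.append({"group": f"g{gi}", "subject": f"g{gi}s{si}",
                                 "condition": f"c{ki}",
                                 "value": rng.standard_normal()
                                 + 0.5 * gi * ki})
        return pd.DataFrame(rows)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        data = self.make_long(np.random.default_rng(3))
        ours = two_way_mixed_anova(data)
        ref = pingouin.mixed_anova(data=data, dv="value", within="condition",
                                   subject="subject", between="group")
        ref = ref.set_index("Source")
        for src, ref_name in [("group", "group"), ("condition", "condition"),
                              ("group x condition", "Interaction")]:
            eff = ours.effect(src)
            assert eff.statistic == pytest.approx(ref.loc[ref_name, "F"], rel=1e-9)
            assert eff.p == pytest.approx(ref.loc[ref_name, "p_unc"], rel=1e-9)

    def test_unbalanced_groups_rejected(self):
        data = self.make_long(np.random.default_rng(4))
        data = data[data["subject"] != "g0s0"]
        with pytest.raises(ValueError):
            two_way_mixed_anova(data)


class TestTwoWayRm:
    def test_interaction_f_matches_manual_partition(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((6, 2, 2))
        table = two_way_rm_anova(y)
        # for a 2x2 within design, the interaction F equals the paired t^2
        # on the difference-of-differences contrast
        contrast = (y[:, 1, 1] - y[:, 1, 0]) - (y[:, 0, 1] - y[:, 0, 0])
        t = contrast.mean() / (contrast.std(ddof=1) / np.sqrt(6))
        eff = table.effect("A x B")
        assert eff.statistic == pytest.approx(t ** 2)
        assert eff.p == pytest.approx(t_pvalue(t, 5))


class TestPosthoc:
    def test_two_groups_tukey_equals_unadjusted_t(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(8), rng.standard_normal(8) + 1.0
        res = tukey_posthoc({"a": x, "b": y})[0]
        t = t_test(x, y)
        assert res.p == pytest.approx(t.p, rel=1e-6)

    def test_three_groups_match_reference_studentized_range(self):
        rng = np.random.default_rng(7)
        groups = {f"g{i}": rng.standard_normal(6) + 0.8 * i for i in range(3)}
        ours = {r.effect_label: r.p for r in tukey_posthoc(groups)}
        ref = sst.tukey_hsd(*groups.values())
        pairs = {("g0 vs g1"): ref.pvalue[0, 1], ("g0 vs g2"): ref.pvalue[0, 2],
                 ("g1 vs g2"): ref.pvalue[1, 2]}
        for label, p_ref in pairs.items():
            assert ours[label] == pytest.approx(p_ref, abs=1e-4)

    def test_bonferroni_caps_at_one(self):
        adj = bonferroni([0.4, 0.01], m=3)
        np.testing.assert_allclose(adj, [1.0, 0.03])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_posthoc({"only": np.arange(5.0)})


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]).p == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        # margins (5,5)/(5,5): only the two diagonal tables are as extreme,
        # each with probability 1/C(10,5) -> p = 2/252
        assert fisher_exact([[5, 0], [0, 5]]).p == pytest.approx(2.0 / 252.0)

    def test_probability_rule_matches_hypergeometric_enumeration(self):
        # independent oracle: enumerate all tables with the observed margins
        table = np.array([[7, 1], [0, 8]])
        r1, c1, n = table[0].sum(), table[:, 0].sum(), table.sum()
        obs_p = sst.hypergeom.pmf(table[0, 0], n, r1, c1)
        p_hand = sum(sst.hypergeom.pmf(a, n, r1, c1)
                     for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
                     if sst.hypergeom.pmf(a, n, r1, c1) <= obs_p * (1 + 1e-9))
        assert fisher_exact(table).p == pytest.approx(p_hand, rel=1e-9)

    def test_label_symmetry(self):
        t = np.array([[7, 1], [0, 8]])
        p0 = fisher_exact(t).p
        assert fisher_exact(t.T).p == pytest.approx(p0)
        assert fisher_exact(t[::-1]).p == pytest.approx(p0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        r = linregress(x, 2.0 * x + 1.0)
        assert r.slope == pytest.approx(2.0) and r.r2 == pytest.approx(1.0)

    def test_f_from_r2_identity(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(8)
        y = 0.5 * x + rng.standard_normal(8)
        r = linregress(x, y)
        assert r.F == pytest.approx(r.r2 * 6 / (1 - r.r2))
        assert r.p == pytest.approx(f_pvalue(r.F, 1, 6))

    def test_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            x = rng.uniform(0, 10, 30)
            y = 1.5 * x + rng.standard_normal(30)
            r = linregress(x, y)
            resid = y - (r.slope * x + r.intercept)
            se = np.sqrt((resid ** 2).sum() / 28 / ((x - x.mean()) ** 2).sum())
            hits += abs(r.slope - 1.5) < 2 * se
        assert hits >= 90

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linregress(np.ones(5), np.arange(5.0))


class TestNullCalibration:
    @pytest.mark.parametrize("test", ["t", "anova"])
    def test_rejection_rate_near_alpha(self, test):
        rng = np.random.default_rng(10)
        n_rep, rej = 2000, 0
        for _ in range(n_rep):
            if test == "t":
                p = t_test(rng.standard_normal(8), rng.standard_normal(8)).p
            else:
                wide = pd.DataFrame(rng.standard_normal((6, 3)))
                p = one_way_rm_anova(wide).effect("condition").p
            rej += p < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.012)

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = t_test(rng.standard_normal(5), rng.standard_normal(5)).p
            assert 0.0 < p <= 1.0
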