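import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varivent.stats import (
    PowerSpec,
    bonferroni_alpha,
    holm_sidak,
    kruskal_dunn,
    one_way_anova,
    paired_t,
    percent_change_table,
    power_two_sample_t,
    required_n_two_sample_t,
    rm_anova_two_way,
    spearman,
)


def make_cohort(rng, groups=("A", "B", "C"), n=7, group_shift=0.0, time_shift=0.0, sd=1.0):
    rows = []
    for gi, g in enumerate(groups):
        for i in range(n):
            animal = f"{g}-{i}"
            subj = rng.normal(0, sd)
            base = 10.0 + gi * group_shift + subj + rng.normal(0, sd)
            end = 10.0 + gi * group_shift + time_shift + subj + rng.normal(0, sd)
            rows.append((animal, g, "BASELINE", "E", base))
            rows.append((animal, g, "END", "E", end))
    return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "variable", "value"])


class TestBonferroni:
    def test_study_value(self):
        assert round(bonferroni_alpha(0.05, 6), 3) == 0.008

    def test_identity(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_division(self):
        assert bonferroni_alpha(0.01, 4) == pytest.approx(0.0025)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestPower:
    def test_study_sample_size(self):
        spec = PowerSpec(effect_size_d=2.21, alpha=0.05, n_comparisons=6, target_power=0.8)
        assert required_n_two_sample_t(spec) == 7

    def test_unadjusted_level_gives_smaller_n(self):
        # the family-wise 0.05 level without adjustment would need only n = 5,
        # so the Bonferroni-adjusted level is what reproduces n = 7
        spec = PowerSpec(effect_size_d=2.21, alpha_star=0.05, target_power=0.8)
        assert required_n_two_sample_t(spec) == 5

    def test_huge_effect_saturates_at_two(self):
        spec = PowerSpec(effect_size_d=50.0, alpha_star=0.008)
        assert required_n_two_sample_t(spec) == 2

    def test_n7_meets_power_but_n6_does_not(self):
        assert power_two_sample_t(7, 2.21, 0.008) >= 0.8
        assert power_two_sample_t(6, 2.21, 0.008) < 0.8

    def test_monte_carlo_power_oracle(self, rng):
        # simulate 2e4 two-sample t-tests at n = 7, d = 2.21, alpha = 0.008
        from scipy import stats as sps

        n, d, alpha, reps = 7, 2.21, 0.008, 20_000
        x = rng.normal(0.0, 1.0, size=(reps, n))
        y = rng.normal(d, 1.0, size=(reps, n))
        t, p = sps.ttest_ind(y, x, axis=1)
        mc_power = float((p < alpha).mean())
        assert mc_power == pytest.approx(power_two_sample_t(n, d, alpha), abs=0.01)

    def test_required_n_monotone_in_d(self):
        ns = [
            required_n_two_sample_t(PowerSpec(effect_size_d=d, alpha_star=0.008))
            for d in (1.0, 1.5, 2.21, 3.0)
        ]
        assert ns == sorted(ns, reverse=True)

    def test_required_n_monotone_in_alpha(self):
        n_loose = required_n_two_sample_t(PowerSpec(effect_size_d=2.21, alpha_star=0.05))
        n_tight = required_n_two_sample_t(PowerSpec(effect_size_d=2.21, alpha_star=0.001))
        assert n_tight >= n_loose


class TestHolmSidak:
    def test_hand_computed_pair(self):
        res = holm_sidak([0.01, 0.04])
        assert res[0].adjusted_p == pytest.approx(1 - 0.99**2)
        assert res[1].adjusted_p == pytest.approx(0.04)

    def test_single_p_unchanged(self):
        assert holm_sidak([0.03])[0].adjusted_p == pytest.approx(0.03)

    def test_all_zero(self):
        assert all(r.adjusted_p == 0.0 for r in holm_sidak([0.0, 0.0, 0.0]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        res = holm_sidak(ps)
        for r in res:
            assert r.adjusted_p >= r.raw_p - 1e-12
            assert r.adjusted_p <= 1.0
        ordered = sorted(res, key=lambda r: r.raw_p)
        adj = [r.adjusted_p for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_rejection_monotone(self, rng):
        ps = rng.uniform(0, 0.2, size=8)
        res = holm_sidak(ps, alpha=0.05)
        ordered = sorted(res, key=lambda r: r.raw_p)
        rejects = [r.extra["reject"] for r in ordered]
        # once a test fails to reject, all later ones fail too
        assert all(a or not b for a, b in zip(rejects, rejects[1:])) or not any(rejects)


class TestPairedT:
    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_large_t_small_p(self, rng):
        before = rng.normal(0, 0.001, 10)
        after = before + 1.0 + rng.normal(0, 0.001, 10)
        res = paired_t(before, after)
        assert res.statistic > 100
        assert res.raw_p < 1e-10

    def test_matches_scipy(self, rng):
        from scipy import stats as sps

        a, b = rng.normal(size=9), rng.normal(size=9)
        res = paired_t(a, b)
        t, p = sps.ttest_rel(b, a)
        assert res.statistic == pytest.approx(t)
        assert res.raw_p == pytest.approx(p)


class TestSpearman:
    def test_perfect_increasing(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfect_decreasing(self):
        rho, _ = spearman([1, 2, 3, 4], [5, 4, 3, 2])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_oracle(self):
        # ranks d = (-1, 1, -1, 1, 0), sum d^2 = 4: 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        res = kruskal_dunn([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res["H"] == 0.0
        assert res["p"] == 1.0

    def test_mean_rank_ordering(self):
        res = kruskal_dunn([[1, 2, 3], [10, 20, 30], [100, 200, 300]], labels=["a", "b", "c"])
        # every higher group dominates: all pairwise z share the ordering sign
        zs = {r.contrast: r.statistic for r in res["pairwise"]}
        assert zs["a vs b"] < 0 and zs["b vs c"] < 0 and zs["a vs c"] < 0

    def test_null_rejection_rate(self, rng):
        # three groups of 7 from one distribution: KW rejects ~ alpha
        reps, alpha = 4000, 0.05
        from scipy import stats as sps

        rejections = 0
        for _ in range(reps):
            g = rng.normal(size=(3, 7))
            _, p = sps.kruskal(*g)
            rejections += p < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3 * se + 0.01

    def test_adjustment_methods(self):
        groups = [[1, 2, 3, 4], [3, 4, 5, 6], [6, 7, 8, 9]]
        hs = kruskal_dunn(groups, adjust="holm-sidak")
        bf = kruskal_dunn(groups, adjust="bonferroni")
        for a, b in zip(hs["pairwise"], bf["pairwise"]):
            assert a.raw_p == pytest.approx(b.raw_p)
            assert a.adjusted_p <= b.adjusted_p + 1e-12

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_dunn([[1.0, 2.0]])


class TestOneWayAnova:
    def test_matches_scipy_f(self, rng):
        from scipy import stats as sps

        groups = [rng.normal(loc, 1, 7) for loc in (0, 0.5, 2.0)]
        res = one_way_anova(groups)
        F, p = sps.f_oneway(*groups)
        assert res["F"] == pytest.approx(F)
        assert res["p"] == pytest.approx(p)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])


class TestRmAnova:
    def test_matches_known_split_plot(self, rng):
        """Oracle: split-plot sums of squares computed independently by
        direct enumeration of the decomposition on a tiny balanced design."""
        table = make_cohort(rng, groups=("A", "B"), n=3, group_shift=1.0, time_shift=0.5)
        res = rm_anova_two_way(table, "E", posthoc=False)
        wide = table.pivot(index=["animal_id", "group"], columns="timepoint", values="value")
        y = wide.to_numpy()
        groups = wide.index.get_level_values("group")
        gm = y.mean()
        subj = y.mean(axis=1)
        ss_b_subj = 2 * ((subj - gm) ** 2).sum()
        gmeans = np.array([subj[groups == g].mean() for g in ("A", "B")])
        ss_group = 3 * 2 * ((gmeans - gm) ** 2).sum()
        ms_group = ss_group / 1
        ms_subj = (ss_b_subj - ss_group) / (2 * (3 - 1))
        assert res["anova"]["group"]["F"] == pytest.approx(ms_group / ms_subj)

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        table = make_cohort(rng, groups=("A", "B", "C"), n=7, group_shift=0.7, time_shift=0.4)
        res = rm_anova_two_way(table, "E", posthoc=False)
        df = table[table["variable"] == "E"].rename(columns={"value": "y"})
        pga = pg.mixed_anova(
            data=df, dv="y", within="timepoint", between="group", subject="animal_id"
        ).set_index("Source")
        assert res["anova"]["group"]["F"] == pytest.approx(pga.loc["group", "F"], rel=1e-6)
        assert res["anova"]["time"]["F"] == pytest.approx(pga.loc["timepoint", "F"], rel=1e-6)
        assert res["anova"]["interaction"]["F"] == pytest.approx(pga.loc["Interaction", "F"], rel=1e-6)

    def test_additive_time_shift_interaction_near_one(self, rng):
        # with a pure additive time effect the interaction F averages ~ 1
        fs = []
        for _ in range(300):
            table = make_cohort(rng, groups=("A", "B"), n=7, time_shift=2.0)
            fs.append(rm_anova_two_way(table, "E", posthoc=False)["anova"]["interaction"]["F"])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_unbalanced_rejected(self, rng):
        table = make_cohort(rng, groups=("A", "B"), n=4)
        table = table[table["animal_id"] != "A-0"]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_two_way(table, "E")

    def test_missing_cell_rejected(self, rng):
        table = make_cohort(rng, groups=("A", "B"), n=4)
        table = table.drop(table[(table["animal_id"] == "A-0") & (table["timepoint"] == "END")].index)
        with pytest.raises(ValueError, match="A-0"):
            rm_anova_two_way(table, "E")

    def test_identical_values_rejected(self):
        rows = []
        for g in ("A", "B"):
            for i in range(3):
                for tp in ("BASELINE", "END"):
                    rows.append((f"{g}-{i}", g, tp, "E", 5.0))
        table = pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "variable", "value"])
        with pytest.raises(ValueError, match="zero"):
            rm_anova_two_way(table, "E")

    def test_posthoc_family(self, rng):
        table = make_cohort(rng, groups=("A", "B", "C"), n=7, group_shift=1.0)
        res = rm_anova_two_way(table, "E")
        contrasts = [c.contrast for c in res["posthoc"]]
        # 3 pairs x 2 timepoints + 3 within-group time changes
        assert len(contrasts) == 9
        assert "A vs B @ BASELINE" in contrasts
        assert "END vs BASELINE @ C" in contrasts


class TestPercentChange:
    def _table(self, baselines, ends, group="A"):
        rows = []
        for i, (b, e) in enumerate(zip(baselines, ends)):
            rows.append((f"{group}-{i}", group, "BASELINE", "E", b))
            rows.append((f"{group}-{i}", group, "END", "E", e))
        return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "variable", "value"])

    def test_single_animal(self):
        out = percent_change_table(self._table([2.0], [3.0]))
        assert out.loc["E", "A"] == pytest.approx(50.0)

    def test_unchanged_is_zero(self):
        out = percent_change_table(self._table([2.0, 3.0], [2.0, 3.0]))
        assert out.loc["E", "A"] == pytest.approx(0.0)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        baselines, ends = [1.0, 4.0], [2.0, 5.0]
        out = percent_change_table(self._table(baselines, ends))
        mean_of_ratios = np.mean([100 * (2 - 1) / 1, 100 * (5 - 4) / 4])  # 62.5
        ratio_of_means = 100 * (3.5 - 2.5) / 2.5  # 40.0
        assert out.loc["E", "A"] == pytest.approx(mean_of_ratios)
        assert out.loc["E", "A"] != pytest.approx(ratio_of_means)

    def test_zero_baseline_rejected(self):
        table = self._table([0.0, 2.0], [1.0, 3.0])
        table.loc[table["value"] == 0.0, "value"] = 0.0
        with pytest.raises(ValueError, match="zero baseline"):
            percent_change_table(table)
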