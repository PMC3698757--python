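import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from telebp.errors import DataError
from telebp.stats import (
    bonferroni_t_posthoc,
    factorial_anova,
    kruskal_wallis,
    paired_compare,
    route,
    steel_dwass,
    tukey_posthoc,
)


def long_table(groups: dict, factor="g"):
    rows = [(k, v) for k, vals in groups.items() for v in vals]
    return pd.DataFrame(rows, columns=[factor, "value"])


class TestRoute:
    def test_normal_equal_variance_goes_parametric(self):
        rng = np.random.default_rng(2)
        t = long_table({k: rng.normal(0, 1, 20) for k in "abc"})
        trace = route(t, ["g"])
        assert trace.route == "parametric"
        assert all(p > 0.05 for p in trace.shapiro_p.values())

    def test_lognormal_group_goes_nonparametric(self):
        rng = np.random.default_rng(4)
        t = long_table(
            {"a": rng.normal(0, 1, 30), "b": rng.lognormal(0, 1.0, 30)}
        )
        assert route(t, ["g"]).route == "nonparametric"

    def test_unequal_variances_go_nonparametric(self):
        rng = np.random.default_rng(5)
        t = long_table({"a": rng.normal(0, 1, 40), "b": rng.normal(0, 6, 40)})
        trace = route(t, ["g"])
        assert trace.route == "nonparametric"
        assert "variance homogeneity rejected" in trace.reason

    def test_constant_groups_degenerate(self):
        t = long_table({"a": [1.0] * 5, "b": [1.0] * 5})
        trace = route(t, ["g"])
        assert trace.route == "nonparametric"
        assert "zero variance" in trace.reason

    def test_tiny_groups_forced_nonparametric(self):
        t = long_table({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert route(t, ["g"]).route == "nonparametric"


class TestFactorialAnova:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(6)
        t = long_table({"a": rng.normal(0, 1, 12), "b": rng.normal(0.8, 1, 12)})
        res = factorial_anova(t, ["g"], posthoc=None)
        tt = sps.ttest_ind(
            t.loc[t.g == "a", "value"], t.loc[t.g == "b", "value"]
        )
        assert res.statistic == pytest.approx(tt.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(tt.pvalue, rel=1e-9)

    def test_balanced_2x2_against_hand_decomposition(self):
        # closed-form oracle: balanced two-way SS from cell means
        rng = np.random.default_rng(7)
        levels_a, levels_b, r = ["a1", "a2"], ["b1", "b2"], 6
        rows = []
        effects = {("a1", "b1"): 0.0, ("a1", "b2"): 1.0, ("a2", "b1"): 2.0, ("a2", "b2"): 5.0}
        for (la, lb), mu in effects.items():
            for _ in range(r):
                rows.append((la, lb, mu + rng.normal(0, 1)))
        t = pd.DataFrame(rows, columns=["A", "B", "value"])

        y = t["value"].to_numpy()
        grand = y.mean()
        ss_a = 2 * r * sum((t.groupby("A")["value"].mean() - grand) ** 2)
        ss_b = 2 * r * sum((t.groupby("B")["value"].mean() - grand) ** 2)
        cell = t.groupby(["A", "B"])["value"].mean()
        ss_cells = r * sum((cell - grand) ** 2)
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ((y - t.groupby(["A", "B"])["value"].transform("mean")) ** 2).sum()

        res = factorial_anova(t, ["A", "B"], posthoc=None)
        tab = res.table.set_index("effect")
        df_err = 4 * (r - 1)
        assert tab.loc["A", "F"] == pytest.approx((ss_a / 1) / (ss_err / df_err), rel=1e-9)
        assert tab.loc["B", "F"] == pytest.approx((ss_b / 1) / (ss_err / df_err), rel=1e-9)
        assert tab.loc["A x B", "F"] == pytest.approx((ss_ab / 1) / (ss_err / df_err), rel=1e-9)

    def test_mixed_anova_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        rows = []
        for g, goff in (("ctl", 0.0), ("trt", 1.0)):
            for s in range(8):
                base = rng.normal(0, 1)
                for w, woff in (("pre", 0.0), ("post", 0.7)):
                    rows.append((g, f"{g}{s}", w, goff + woff + base + rng.normal(0, 0.5)))
        t = pd.DataFrame(rows, columns=["grp", "animal", "time", "value"])
        res = factorial_anova(t, ["grp", "time"], repeated_on=["time"], posthoc=None)
        tab = res.table.set_index("effect")
        ref = pg.mixed_anova(
            data=t, dv="value", within="time", between="grp", subject="animal"
        ).set_index("Source")
        assert tab.loc["grp", "F"] == pytest.approx(ref.loc["grp", "F"], rel=1e-6)
        assert tab.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert tab.loc["grp x time", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )
        assert tab.loc["time", "p"] == pytest.approx(ref.loc["time", "p_unc"], rel=1e-6)

    def test_pure_within_matches_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(9)
        rows = []
        for s in range(10):
            base = rng.normal(0, 1)
            for w, off in (("w1", 0.0), ("w2", 0.5), ("w3", 1.1)):
                rows.append((f"s{s}", w, base + off + rng.normal(0, 0.4)))
        t = pd.DataFrame(rows, columns=["animal", "cond", "value"])
        res = factorial_anova(t, ["cond"], repeated_on=["cond"], posthoc=None)
        ref = AnovaRM(t, "value", "animal", within=["cond"]).fit()
        assert res.statistic == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-6
        )

    def test_three_factor_split_plot_runs_and_uses_bonferroni(self):
        rng = np.random.default_rng(10)
        rows = []
        for strain in ("W", "S"):
            for s in range(4):
                subj = f"{strain}{s}"
                base = rng.normal(0, 0.5)
                for period in ("dark", "light"):
                    for wk in ("w0", "w1", "w2"):
                        rows.append(
                            (strain, subj, period, wk, base + rng.normal(0, 0.5))
                        )
        t = pd.DataFrame(rows, columns=["strain", "animal", "period", "week", "value"])
        res = factorial_anova(t, ["strain", "period", "week"],
                              repeated_on=["period", "week"])
        effects = set(res.table["effect"])
        assert {"strain", "period", "week", "strain x period",
                "strain x week", "period x week", "strain x period x week"} <= effects
        assert (res.table["p"].between(0, 1)).all()
        assert len(res.pairwise) == 66  # C(12,2) cells, Bonferroni family
        # Greenhouse-Geisser reported for within effects
        within = res.table.set_index("effect").loc["week"]
        assert 0.5 <= within["gg_eps"] <= 1.0

    def test_unbalanced_repeated_rejected(self):
        t = pd.DataFrame(
            {
                "g": ["a"] * 3 + ["b"] * 2,
                "animal": ["s1", "s1", "s2", "s3", "s3"],
                "w": ["x", "y", "x", "x", "y"],
                "value": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        with pytest.raises(DataError):
            factorial_anova(t, ["g", "w"], repeated_on=["w"], posthoc=None)


class TestNonparametric:
    def test_kruskal_toy_table_h(self):
        t = long_table({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        res = kruskal_wallis(t, ["g"])
        assert res.statistic == pytest.approx(7.2, abs=1e-12)

    def test_kruskal_identical_groups(self):
        t = long_table({"a": [5.0] * 4, "b": [5.0] * 4})
        with pytest.warns(UserWarning):
            res = kruskal_wallis(t, ["g"])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_steel_dwass_identical_groups_near_one(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, 10)
        t = long_table({k: base + rng.normal(0, 1e-3, 10) for k in "abc"})
        res = steel_dwass(t, ["g"])
        assert (res.pairwise["p_adj"] > 0.5).all()

    def test_steel_dwass_flags_only_shifted_group(self):
        rng = np.random.default_rng(12)
        t = long_table(
            {
                "a": rng.normal(0, 1, 10),
                "b": rng.normal(0, 1, 10),
                "c": rng.normal(5.0, 1, 10),  # 5 SD shift
            }
        )
        res = steel_dwass(t, ["g"])
        p = res.pairwise.set_index("comparison")["p_adj"]
        assert p["a vs c"] < 0.05 and p["b vs c"] < 0.05
        assert p["a vs b"] > 0.05

    def test_steel_dwass_pair_agrees_with_ranksum_z(self):
        # Each pairwise statistic must be the tie-corrected rank-sum z of the
        # two groups alone; with k=2 the studentized-range reference equals
        # the two-sided normal rank-sum p.
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 12), rng.normal(1.0, 1, 12)
        c = rng.normal(10.0, 1, 12)
        res = steel_dwass(long_table({"a": a, "b": b, "c": c}), ["g"])
        row = res.pairwise.set_index("comparison").loc["a vs b"]
        ranks = sps.rankdata(np.concatenate([a, b]))
        ra = ranks[:12].sum()
        E = 12 * 25 / 2
        V = 12 * 12 / (24 * 23) * ((ranks**2).sum() - 24 * 25**2 / 4)
        z = (ra - E) / np.sqrt(V)
        assert row["statistic"] == pytest.approx(z, rel=1e-12)
        p_norm = 2 * sps.norm.sf(abs(z))
        p_sr2 = float(sps.studentized_range.sf(np.sqrt(2) * abs(z), 2, np.inf))
        assert p_sr2 == pytest.approx(p_norm, rel=1e-4)

    def test_steel_dwass_needs_three_groups(self):
        t = long_table({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(DataError):
            steel_dwass(t, ["g"])

    def test_steel_dwass_label_permutation_invariance(self):
        rng = np.random.default_rng(14)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        t1 = long_table(groups)
        relabel = {"a": "z", "b": "y", "c": "x"}
        t2 = t1.assign(g=t1["g"].map(relabel))
        p1 = steel_dwass(t1, ["g"]).pairwise
        p2 = steel_dwass(t2, ["g"]).pairwise
        assert sorted(p1["p_adj"].round(12)) == sorted(p2["p_adj"].round(12))


class TestPairedCompare:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        res = paired_compare(x, x)
        assert res.p_value == 1.0 and res.extra["effect"] == 0.0

    def test_constant_shift_smallest_attainable_p(self):
        x = np.arange(6.0)
        res = paired_compare(x, x + 2.0)
        assert res.p_value == pytest.approx(2 * 0.5**6)

    def test_power_at_effect_two_sd(self):
        rng = np.random.default_rng(15)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(0, 1, 7)
            y = x + 2.0 + rng.normal(0, 1, 7)
            if paired_compare(x, y).p_value < 0.05:
                hits += 1
        assert hits / reps >= 0.80

    def test_nonnormal_differences_use_wilcoxon(self):
        rng = np.random.default_rng(16)
        x = np.zeros(30)
        y = rng.lognormal(0, 1.5, 30)
        res = paired_compare(x, y)
        assert "Wilcoxon" in res.name


class TestPosthocFamilies:
    def test_bonferroni_is_exact_min_one(self):
        rng = np.random.default_rng(17)
        t = long_table({k: rng.normal(0, 1, 8) for k in "abcd"})
        out = bonferroni_t_posthoc(t, ["g"])
        m = len(out)
        assert m == 6
        for _, row in out.iterrows():
            a, b = row["comparison"].split(" vs ")
            p_raw = sps.ttest_ind(
                t.loc[t.g == a, "value"], t.loc[t.g == b, "value"]
            ).pvalue
            assert row["p_adj"] == pytest.approx(min(1.0, 6 * p_raw), rel=1e-12)

    def test_tukey_family_size(self):
        rng = np.random.default_rng(18)
        t = long_table({k: rng.normal(0, 1, 6) for k in "abc"})
        out = tukey_posthoc(t, ["g"])
        assert len(out) == 3  # C(3,2)
        assert out["p_adj"].between(0, 1).all()
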