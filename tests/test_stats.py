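"""Statistical designs: summary ANOVA, chi-square, mixed ANOVA, GG epsilon,
Holm, simple effects, difference correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from taskstates.stats import (
    chi_square_independence,
    greenhouse_geisser_epsilon,
    holm_bonferroni,
    mixed_anova,
    oneway_anova_from_summary,
    prepost_difference_correlation,
    simple_effects,
)
from taskstates.synth import simulate_parameter_table

GROUPS3 = ("HC", "MDD", "MDD+NSSI")


def null_table(seed, sd=75.0, sizes=(30, 30, 30)):
    means = {(g, c): 100.0 for g in GROUPS3 for c in ("neutral", "negative")}
    return simulate_parameter_table(means, dict(zip(GROUPS3, sizes)), sd=sd,
                                    seed=seed)


class TestOnewayFromSummary:
    def test_equal_means_give_zero_f(self):
        res = oneway_anova_from_summary([(5.0, 1.0, 10), (5.0, 2.0, 12)])
        assert res["F"].iloc[0] == 0.0

    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.normal(size=12), rng.normal(loc=0.7, size=15)
        res = oneway_anova_from_summary([
            (a.mean(), a.std(ddof=1), len(a)), (b.mean(), b.std(ddof=1), len(b))])
        t = sstats.ttest_ind(a, b).statistic
        assert res["F"].iloc[0] == pytest.approx(t ** 2, abs=1e-9)
        assert res["p"].iloc[0] == pytest.approx(sstats.ttest_ind(a, b).pvalue,
                                                 abs=1e-12)

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="n >= 2"):
            oneway_anova_from_summary([(1.0, 1.0, 1), (2.0, 1.0, 5)])


class TestChiSquare:
    def test_proportional_rows_independent(self):
        chi2, dof, p = chi_square_independence([[10, 20], [5, 10], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert dof == 2

    def test_hand_computed_2x2(self):
        # all expected counts are 2 -> chi2 = 4 * (1)^2 / 2 = 2
        chi2, dof, p = chi_square_independence([[1, 3], [3, 1]])
        assert chi2 == pytest.approx(2.0, abs=1e-12)
        assert dof == 1

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [3, 1]])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_down(self):
        out = holm_bonferroni([0.01, 0.02, 0.04])
        assert out == pytest.approx([0.03, 0.04, 0.04])

    def test_inflation_and_order(self, rng):
        p = rng.uniform(size=20)
        out = holm_bonferroni(p)
        assert np.all(out >= p)
        assert np.all(out <= 1.0)
        # order preserved: the smallest raw p stays the smallest adjusted
        assert np.argmin(out) == np.argmin(p)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.2, 1.3])


class TestGreenhouseGeisser:
    def test_two_levels_forced_to_one(self):
        assert greenhouse_geisser_epsilon(np.array([[2.0, 0.3], [0.3, 1.0]])) == 1.0

    def test_compound_symmetry_is_spherical(self):
        s = np.full((4, 4), 0.6) + np.eye(4) * 1.4
        assert greenhouse_geisser_epsilon(s) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula_oracle(self, rng):
        a = rng.normal(size=(3, 3))
        s = a @ a.T
        # independent evaluation of the estimator in its eigenvalue form
        L = 3
        c = np.linalg.qr(np.column_stack([np.ones(L), np.eye(L)[:, :-1]]))[0][:, 1:]
        lam = np.linalg.eigvalsh(c.T @ s @ c)
        expected = lam.sum() ** 2 / ((L - 1) * np.sum(lam ** 2))
        assert greenhouse_geisser_epsilon(s) == pytest.approx(expected, abs=1e-12)

    def test_non_psd_errors(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            greenhouse_geisser_epsilon(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestMixedAnova:
    def test_matches_pingouin_without_covariates(self, rng):
        pg = pytest.importorskip("pingouin")
        df = null_table(3, sizes=(10, 12, 15))
        df.loc[(df.group == "MDD+NSSI") & (df.condition == "negative"), "value"] += 40
        mine = mixed_anova(df, "value", "subject", within="condition",
                           between="group")
        ref = pg.mixed_anova(data=df, dv="value", within="condition",
                             between="group", subject="subject")
        f_mine = mine.set_index("effect")["F"]
        assert f_mine["group"] == pytest.approx(
            ref.loc[ref.Source == "group", "F"].iloc[0], rel=1e-9)
        assert f_mine["condition:group"] == pytest.approx(
            ref.loc[ref.Source == "Interaction", "F"].iloc[0], rel=1e-9)

    def test_constant_dv_gives_zero_f(self):
        df = null_table(4)
        df["value"] = 3.0
        res = mixed_anova(df, "value", "subject", within="condition",
                          between="group", covariates=["age"])
        assert np.all(res["F"] == 0.0)
        assert np.all(res["p"] == 1.0)

    def test_pure_between_equals_summary_anova(self, rng):
        df = null_table(5).groupby("subject").agg(
            {"value": "mean", "group": "first"}).reset_index()
        res = mixed_anova(df, "value", "subject", within=(), between="group")
        summaries = [(sub["value"].mean(), sub["value"].std(ddof=1), len(sub))
                     for _, sub in df.groupby("group")]
        ref = oneway_anova_from_summary(summaries)
        assert res.loc[res.effect == "group", "F"].iloc[0] == pytest.approx(
            ref["F"].iloc[0], rel=1e-9)

    def test_covariate_df_matches_study_layout(self):
        """138 subjects, 3 groups, 2 covariates, 2-level within factor:
        the error df of every stratum must be 133 = N - g - c."""
        means = {(g, c): 100.0 for g in GROUPS3 for c in ("neutral", "negative")}
        df = simulate_parameter_table(means, {"HC": 20, "MDD": 52, "MDD+NSSI": 66},
                                      sd=75.0, seed=8)
        res = mixed_anova(df, "value", "subject", within="condition",
                          between="group", covariates=["age", "sex"])
        idx = res.set_index("effect")
        assert idx.loc["group", "df2"] == 133
        assert idx.loc["condition:group", "df2"] == 133
        assert idx.loc["condition", "df2"] == 133

    def test_row_order_invariance(self):
        df = null_table(6, sizes=(8, 9, 10))
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = mixed_anova(df, "value", "subject", within="condition", between="group")
        b = mixed_anova(shuffled, "value", "subject", within="condition",
                        between="group")
        pd.testing.assert_frame_equal(a, b)

    def test_sum_of_squares_partition(self):
        """Model + error SS across all strata reconstruct the total SS."""
        df = null_table(7, sizes=(8, 8, 8))
        y = df.pivot(index="subject", columns="condition", values="value")
        total_ss = float(((y - y.to_numpy().mean()) ** 2).to_numpy().sum())
        res = mixed_anova(df, "value", "subject", within="condition",
                          between="group")
        # error SS per stratum = ss_effect * (1 - eta) / eta inversion is
        # fragile; recompute from F instead: ss_err = ss_eff * df2 / (F * df1)
        model_ss = res["ss"].sum()
        errs = []
        for _, r in res.iterrows():
            if r["F"] > 0:
                errs.append(r["ss"] * r["df2"] / (r["F"] * r["df1"]))
        # between and within strata each contribute one distinct error term
        err_ss = 0.0
        seen = set()
        for (_, r), e in zip(res.iterrows(), errs):
            stratum = "within" if ":" in r["effect"] or r["effect"] == "condition" \
                else "between"
            if stratum not in seen:
                err_ss += e
                seen.add(stratum)
        assert model_ss + err_ss == pytest.approx(total_ss, rel=1e-6)

    def test_missing_cell_listwise_removal(self, caplog):
        df = null_table(9, sizes=(6, 6, 6))
        df = df.drop(df[(df.subject == "HC-001")
                        & (df.condition == "negative")].index)
        res = mixed_anova(df, "value", "subject", within="condition",
                          between="group")
        # one subject dropped: 17 subjects, 3 groups -> df2 = 14
        assert res.set_index("effect").loc["group", "df2"] == 14

    def test_two_within_factors_df_structure(self):
        rng = np.random.default_rng(11)
        rows = []
        for arm, n in (("med", 8), ("combo", 7)):
            for i in range(n):
                sid = f"{arm}{i}"
                for cond in ("neutral", "negative"):
                    for time in ("before", "after"):
                        rows.append({"subject": sid, "arm": arm, "cond": cond,
                                     "time": time, "y": rng.normal()})
        df = pd.DataFrame(rows)
        res = mixed_anova(df, "y", "subject", within=["cond", "time"],
                          between="arm")
        effects = set(res["effect"])
        assert {"arm", "cond", "time", "cond:time", "cond:arm", "time:arm",
                "cond:time:arm"} <= effects
        assert np.all(res["df2"] == 13)  # (N - g) per single-contrast stratum


class TestCalibrationAndPower:
    def test_type_one_error_calibrated(self):
        """Null 2x3 mixed design: empirical alpha at 0.05 in [0.03, 0.07]."""
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            df = null_table(1000 + rep)
            res = mixed_anova(df, "value", "subject", within="condition",
                              between="group", covariates=["age", "sex"])
            p = res.set_index("effect").loc["condition:group", "p"]
            hits += p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_power_at_designed_effect(self):
        """Planted cue x group interaction at the scaled-down designed
        effect size is detected in >= 80% of replicates."""
        from taskstates.synth import scaled_down_design
        design = scaled_down_design()
        means = {}
        for g in GROUPS3:
            for c in ("neutral", "negative"):
                means[(g, c)] = design.targets(g, c)[0][2]  # class-3 duration
        sizes = design.groups
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            df = simulate_parameter_table(means, sizes, sd=75.0, seed=5000 + rep)
            res = mixed_anova(df, "value", "subject", within="condition",
                              between="group", covariates=["age", "sex"])
            p = res.set_index("effect").loc["condition:group", "p"]
            hits += p < 0.05
        assert hits / n_rep >= 0.80


class TestSimpleEffects:
    def planted(self, seed, boost=40.0):
        means = {(g, c): 100.0 for g in GROUPS3 for c in ("neutral", "negative")}
        means[("MDD+NSSI", "negative")] += boost
        return simulate_parameter_table(means, {"HC": 10, "MDD": 12, "MDD+NSSI": 15},
                                        sd=20.0, seed=seed)

    def test_cardinality_when_slicing_two_level_factor(self):
        df = self.planted(0)
        table = simple_effects(df, "value", "subject", within="condition",
                               between="group", slice_by="condition")
        assert len(table) == 2
        assert set(table["slice"]) == {"neutral", "negative"}

    def test_planted_interaction_localized_to_negative_cue(self):
        hits_neg, hits_neu = 0, 0
        for rep in range(20):
            df = self.planted(100 + rep)
            table = simple_effects(df, "value", "subject", within="condition",
                                   between="group", slice_by="condition")
            p = table.set_index("slice")["p"]
            hits_neg += p["negative"] < 0.05
            hits_neu += p["neutral"] < 0.05
        assert hits_neg >= 16       # >= 80% power where the effect lives
        assert hits_neu <= 4        # near-nominal elsewhere

    def test_no_interaction_directions_agree(self):
        means = {(g, c): 100.0 + 10.0 * (g == "MDD") for g in GROUPS3
                 for c in ("neutral", "negative")}
        df = simulate_parameter_table(means, {"HC": 20, "MDD": 20, "MDD+NSSI": 20},
                                      sd=5.0, seed=77)
        table = simple_effects(df, "value", "subject", within="condition",
                               between="group", slice_by="condition")
        pw = table.attrs["pairwise"]
        diffs = pw[pw.comparison == "HC - MDD"]["difference"]
        assert np.all(np.sign(diffs) == -1.0)

    def test_slice_by_group_tests_within_factor(self):
        df = self.planted(7, boost=60.0)
        table = simple_effects(df, "value", "subject", within="condition",
                               between="group", slice_by="group")
        assert len(table) == 3
        p = table.set_index("slice")["p"]
        assert p["MDD+NSSI"] < 0.05

    def test_unknown_slice_errors(self):
        df = self.planted(1)
        with pytest.raises(ValueError, match="slice_by"):
            simple_effects(df, "value", "subject", within="condition",
                           between="group", slice_by="banana")


class TestPrepostCorrelation:
    def make_tables(self, delta_param, n=21, seed=0):
        rng = np.random.default_rng(seed)
        subjects = [f"S{i}" for i in range(n)]
        scales = []
        params = []
        d_scale = rng.normal(size=n)
        for i, sid in enumerate(subjects):
            for time, off in (("before", 0.0), ("after", d_scale[i])):
                scales.append({"subject": sid, "time": time, "arm": "medication",
                               "HAMD": 20.0 + off,
                               "PHQ9": 18.0 + rng.normal(scale=0.5), "NSSI": 2.0})
                params.append({"subject": sid, "time": time, "arm": "medication",
                               "class": 3, "duration": 200.0 + delta_param(i, off),
                               "coverage": 0.4, "occurrence": 2.0})
        return pd.DataFrame(scales), pd.DataFrame(params)

    def test_proportional_deltas_give_r_one(self):
        scales, params = self.make_tables(lambda i, off: 3.0 * off)
        out = prepost_difference_correlation(scales, params,
                                             scale_cols=("HAMD",),
                                             param_cols=("duration",))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_antiproportional_deltas_give_r_minus_one(self):
        scales, params = self.make_tables(lambda i, off: -2.0 * off)
        out = prepost_difference_correlation(scales, params,
                                             scale_cols=("HAMD",),
                                             param_cols=("duration",))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_null_deltas_controlled_by_holm(self):
        rng = np.random.default_rng(4)
        sig = 0
        reps = 40
        for rep in range(reps):
            scales, params = self.make_tables(
                lambda i, off, r=rng: r.normal(), seed=rep)
            out = prepost_difference_correlation(scales, params,
                                                 scale_cols=("HAMD", "PHQ9"),
                                                 param_cols=("duration",))
            sig += int((out["p_holm"] < 0.05).any())
        assert sig / reps <= 0.05 + 0.08  # binomial slack at 40 replicates

    def test_too_few_pairs_errors(self):
        scales, params = self.make_tables(lambda i, off: off, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            prepost_difference_correlation(scales, params,
                                           scale_cols=("HAMD",),
                                           param_cols=("duration",))


class TestPermutationProperty:
    def test_permuting_groups_destroys_between_effect(self):
        means = {(g, c): 100.0 + 30.0 * (g == "MDD+NSSI")
                 for g in GROUPS3 for c in ("neutral", "negative")}
        df = simulate_parameter_table(means, {"HC": 15, "MDD": 15, "MDD+NSSI": 15},
                                      sd=10.0, seed=3)
        res = mixed_anova(df, "value", "subject", within="condition",
                          between="group")
        f_true = res.set_index("effect").loc["group", "F"]
        rng = np.random.default_rng(0)
        fs = []
        subjects = df["subject"].unique()
        for _ in range(30):
            perm = dict(zip(subjects, rng.permutation(
                df.drop_duplicates("subject")["group"].to_numpy())))
            shuffled = df.assign(group=df["subject"].map(perm))
            r = mixed_anova(shuffled, "value", "subject", within="condition",
                            between="group")
            fs.append(r.set_index("effect").loc["group", "F"])
        assert f_true > 10 * np.median(fs)
        assert np.median(fs) < 2.5
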