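"""Repeated-measures ANOVA, Tukey HSD, the mixed model and Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rpskit.inference import (bic_bayes_factor, fit_lmm_emm, rm_anova,
                              tukey_pairwise, two_sample_t)
from rpskit.simulate import simulate_optimal_rate_data


def _two_condition_frame(values: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for cond, vals in values.items():
        for s, v in enumerate(vals):
            rows.append({"subj": f"s{s}", "cond": cond, "y": v})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_conditions_reproduce_paired_t_squared(self):
        data = _two_condition_frame({"a": [1.0, 2.0, 4.0, 3.5],
                                     "b": [2.0, 3.5, 4.5, 5.0]})
        table = rm_anova(data, "y", ["cond"], "subj")
        t_res = stats.ttest_rel([1.0, 2.0, 4.0, 3.5], [2.0, 3.5, 4.5, 5.0])
        row = table.iloc[0]
        assert row["F"] == pytest.approx(t_res.statistic ** 2, rel=1e-10)
        assert row["p_uncorrected"] == pytest.approx(t_res.pvalue, rel=1e-10)
        assert row["df1"] == 1 and row["df2"] == 3

    def test_two_level_factor_epsilon_is_one(self):
        data = _two_condition_frame({"a": [1.0, 2.0, 4.0],
                                     "b": [2.0, 3.5, 4.5]})
        table = rm_anova(data, "y", ["cond"], "subj")
        assert table.iloc[0]["epsilon_gg"] == 1.0
        assert table.iloc[0]["mauchly_p"] == 1.0

    def test_matches_pingouin_two_way(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        rows = []
        for s in range(12):
            base = rng.normal(0, 1)
            for a in range(3):
                for b in range(4):
                    rows.append({"subj": s, "A": f"a{a}", "B": f"b{b}",
                                 "y": base + 0.5 * a + rng.normal(0, 1)})
        data = pd.DataFrame(rows)
        mine = rm_anova(data, "y", ["A", "B"], "subj").set_index("effect")
        ref = pingouin.rm_anova(data=data, dv="y", within=["A", "B"],
                                subject="subj", detailed=True,
                                effsize="np2").set_index("Source")
        for eff, ref_name in [("A", "A"), ("B", "B"), ("A:B", "A * B")]:
            assert mine.loc[eff, "F"] == pytest.approx(
                ref.loc[ref_name, "F"], rel=1e-8)
            assert mine.loc[eff, "p_uncorrected"] == pytest.approx(
                ref.loc[ref_name, "p_unc"], rel=1e-6)
        # main-effect GG epsilons follow the same pooled-contrast recipe
        for eff in ("A", "B"):
            assert mine.loc[eff, "epsilon_gg"] == pytest.approx(
                ref.loc[eff, "eps"], rel=1e-6)

    def test_matches_anovarm_three_way(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(7)
        rows = []
        for s in range(10):
            base = rng.normal(0, 1)
            for a in range(2):
                for b in range(3):
                    for d in range(3):
                        rows.append({"s": s, "A": a, "B": b, "D": d,
                                     "y": base + 0.3 * a + 0.2 * b * d
                                     + rng.normal(0, 1)})
        data = pd.DataFrame(rows)
        mine = rm_anova(data, "y", ["A", "B", "D"], "s").set_index("effect")
        ref = AnovaRM(data, "y", "s", within=["A", "B", "D"]).fit().anova_table
        for eff, row in ref.iterrows():
            key = eff.replace(":", ":")
            assert mine.loc[key, "F"] == pytest.approx(
                row["F Value"], rel=1e-8)
            assert mine.loc[key, "df1"] == row["Num DF"]
            assert mine.loc[key, "df2"] == row["Den DF"]

    def test_mixed_design_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for s in range(20):
            g = "g1" if s < 10 else "g2"
            base = rng.normal(0, 1)
            for w in range(3):
                rows.append({"s": s, "grp": g, "W": f"w{w}",
                             "y": base + 0.4 * w + 0.5 * (g == "g2")
                             + rng.normal(0, 1)})
        data = pd.DataFrame(rows)
        mine = rm_anova(data, "y", ["W"], "s", between="grp").set_index("effect")
        ref = pingouin.mixed_anova(data=data, dv="y", within="W",
                                   subject="s", between="grp").set_index("Source")
        assert mine.loc["grp", "F"] == pytest.approx(ref.loc["grp", "F"],
                                                     rel=1e-8)
        assert mine.loc["W", "F"] == pytest.approx(ref.loc["W", "F"], rel=1e-8)
        assert mine.loc["grp:W", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-8)

    def test_missing_cell_is_an_error(self):
        data = _two_condition_frame({"a": [1.0, 2.0, 3.0],
                                     "b": [2.0, 3.5, 4.5]}).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(data, "y", ["cond"], "subj")

    def test_null_simulation_type_one_error(self):
        """GG-conditional testing keeps the type-I rate near nominal under
        a null with mildly non-spherical covariance."""
        rng = np.random.default_rng(42)
        n_sims, alpha = 400, 0.05
        cov = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.6], [0.2, 0.6, 1.0]])
        chol = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(n_sims):
            y = rng.normal(size=(15, 3)) @ chol.T
            data = pd.DataFrame({
                "s": np.repeat(np.arange(15), 3),
                "w": np.tile([f"w{j}" for j in range(3)], 15),
                "y": y.ravel()})
            table = rm_anova(data, "y", ["w"], "s")
            rejections += table.iloc[0]["p"] < alpha
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 3.5 * se


class TestTukey:
    def test_two_levels_reduce_to_t_test(self):
        g1 = np.array([1.0, 2.0, 3.0, 4.0])
        g2 = np.array([2.5, 3.5, 4.5, 5.5])
        mse = (g1.var(ddof=1) + g2.var(ddof=1)) / 2
        table = tukey_pairwise([g1.mean(), g2.mean()], mse, 4, 6)
        t_res = stats.ttest_ind(g1, g2)
        assert table.iloc[0]["p_tukey"] == pytest.approx(t_res.pvalue, rel=1e-6)

    def test_identical_means_give_p_one(self):
        table = tukey_pairwise([1.0, 1.0, 1.0], mse=2.0, n_per_mean=5,
                               df_error=12)
        assert (table["p_tukey"] == 1.0).all()

    def test_three_groups_match_scipy_tukey_hsd(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.2)]
        ref = stats.tukey_hsd(*groups)
        means = [g.mean() for g in groups]
        mse = np.mean([g.var(ddof=1) for g in groups])
        table = tukey_pairwise(means, mse, 8, 21)
        ref_p = {(0, 1): ref.pvalue[0, 1], (0, 2): ref.pvalue[0, 2],
                 (1, 2): ref.pvalue[1, 2]}
        for _, row in table.iterrows():
            assert row["p_tukey"] == pytest.approx(
                ref_p[(row["level_1"], row["level_2"])], rel=1e-6)


class TestBayesFactor:
    def test_closed_forms(self):
        assert bic_bayes_factor(10.0, 10.0) == 1.0
        assert bic_bayes_factor(2 * np.log(10), 0.0) == pytest.approx(10.0)

    def test_reciprocity(self):
        b1, b2 = 103.7, 91.2
        assert bic_bayes_factor(b1, b2) * bic_bayes_factor(b2, b1) == \
            pytest.approx(1.0, rel=1e-12)


class TestLmm:
    def test_balanced_emms_equal_cell_means(self):
        data = simulate_optimal_rate_data(n_participants=20, seed=3)
        res = fit_lmm_emm(data)
        raw = data.groupby("outcome", sort=False)["optimal_rate"].mean()
        for _, row in res.emms.iterrows():
            assert row["emm"] == pytest.approx(raw[row["outcome"]], abs=1e-8)

    def test_degrees_of_freedom_partition(self):
        data = simulate_optimal_rate_data(n_participants=80, seed=4)
        res = fit_lmm_emm(data)
        anova = res.anova.set_index("term")
        # 480 observations, 80 participants: within effects on 398 df,
        # the between effect on 78
        assert anova.loc["C(outcome)", "df2"] == 398
        assert anova.loc["C(experiment)", "df2"] == 78

    def test_planted_effects_recovered(self):
        data = simulate_optimal_rate_data(n_participants=80, seed=11)
        res = fit_lmm_emm(data)
        planted = {"win": 0.60, "draw": 0.50, "lose": 0.43}
        for _, row in res.emms.iterrows():
            assert row["ci_low"] - 0.02 <= planted[row["outcome"]] \
                <= row["ci_high"] + 0.02

    def test_interaction_bf_small_without_interaction(self):
        data = simulate_optimal_rate_data(n_participants=40, seed=6)
        res = fit_lmm_emm(data)
        assert res.comparison.bf_interaction < 1.0
        assert res.comparison.bf_main == pytest.approx(
            1.0 / res.comparison.bf_interaction, rel=1e-12)


class TestTwoSampleT:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computation(self):
        g1, g2 = [2.0, 4.0, 6.0], [1.0, 3.0, 5.0, 7.0]
        t, df, p = two_sample_t(g1, g2)
        # pooled variance by hand
        m1, m2 = np.mean(g1), np.mean(g2)
        sp2 = ((len(g1) - 1) * np.var(g1, ddof=1)
               + (len(g2) - 1) * np.var(g2, ddof=1)) / (len(g1) + len(g2) - 2)
        t_hand = (m1 - m2) / np.sqrt(sp2 * (1 / len(g1) + 1 / len(g2)))
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == 5

    def test_df_for_forty_per_group(self):
        rng = np.random.default_rng(0)
        _, df, _ = two_sample_t(rng.normal(size=40), rng.normal(size=40))
        assert df == 78
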