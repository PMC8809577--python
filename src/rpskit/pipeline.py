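"""End-to-end analysis orchestration.

:func:`analyze_experiment` runs the complete single-experiment pipeline
on a trial-log dataset — condition summaries, repeated-measures ANOVAs
of item choice, outcome rates and first-order strategy proportions,
Tukey follow-ups, individual bias classification, the success split and
optimal-response rates.  :func:`cross_experiment` runs the two-dataset
comparison: the pooled t test of exploitable win rates, the mixed ANOVA,
and the random-intercept mixed-model Bayes-factor comparison with
estimated marginal means.

All outputs are plain pandas objects collected in a dict, deterministic
given the input data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import inference, sequential
from .game import optimal_map_for_experiment
from .io import Dataset, validate_dataset


def _cell_outlier_flags(long: pd.DataFrame, value_col: str,
                        cell_cols: list[str]) -> pd.Series:
    """Extreme-outlier flags computed within each design cell (the
    cell-level interquartile rule)."""
    flags = pd.Series(False, index=long.index)
    for _, g in long.groupby(cell_cols, sort=False):
        vals = g[value_col].to_numpy(dtype=float)
        if len(vals) >= 4 and not np.isnan(vals).any():
            flags.loc[g.index] = sequential.flag_extreme_outliers(vals)
    return flags


def analyze_experiment(dataset: Dataset, alpha: float = 0.05,
                       pvalue_method: str = "min-likelihood",
                       success_method: str = "normal_cc",
                       block_length: int = 90) -> dict:
    """Full single-experiment analysis bundle."""
    df = dataset.df
    experiment = int(df["experiment"].iloc[0])
    cmap = optimal_map_for_experiment(experiment)

    results: dict = {
        "experiment": experiment,
        "validation": validate_dataset(dataset, block_length=block_length),
        "condition_summary": sequential.condition_summary(dataset),
    }

    # --- item choice ---------------------------------------------------
    items = sequential.item_proportions_long(dataset)
    results["anova_item"] = inference.rm_anova(
        items, "proportion", ["opponent_type", "value_condition", "item"],
        "participant_id")
    results["item_outliers"] = int(_cell_outlier_flags(
        items, "proportion",
        ["opponent_type", "value_condition", "item"]).sum())

    # --- outcome rates -------------------------------------------------
    outcomes = sequential.outcome_proportions_long(dataset)
    results["anova_outcome"] = inference.rm_anova(
        outcomes, "proportion", ["opponent_type", "value_condition", "outcome"],
        "participant_id")
    results["outcome_outliers"] = int(_cell_outlier_flags(
        outcomes, "proportion",
        ["opponent_type", "value_condition", "outcome"]).sum())

    # Tukey follow-up of outcome rates within each opponent type, using
    # the value x outcome repeated-measures error term of that subset
    tukeys = {}
    for opp in ("unexploitable", "exploitable"):
        sub = outcomes[outcomes["opponent_type"] == opp]
        cell = (sub.groupby(["participant_id", "outcome"], sort=False)
                ["proportion"].mean().reset_index())
        sub_anova = inference.rm_anova(cell, "proportion", ["outcome"],
                                       "participant_id")
        row = sub_anova.iloc[0]
        means = cell.groupby("outcome", sort=False)["proportion"].mean()
        tukeys[opp] = inference.tukey_pairwise(
            means.to_numpy(), row["MSE"], cell["participant_id"].nunique(),
            row["df2"], labels=list(means.index))
    results["tukey_outcome"] = tukeys

    # --- first-order strategy proportions ------------------------------
    strategies = sequential.strategy_proportions_long(dataset)
    complete = strategies.dropna(subset=["proportion"])
    # the classical ANOVA needs complete cells: drop whole participants
    # with any empty conditional row (mirrors whole-participant removal)
    cells_per = complete.groupby("participant_id")["proportion"].count()
    full_n = cells_per.max()
    keep = cells_per[cells_per == full_n].index
    results["anova_strategy_excluded"] = sorted(
        set(strategies["participant_id"]) - set(keep))
    results["anova_strategy"] = inference.rm_anova(
        complete[complete["participant_id"].isin(keep)], "proportion",
        ["opponent_type", "value_condition", "previous_outcome", "strategy"],
        "participant_id")
    results["strategy_outliers"] = int(_cell_outlier_flags(
        complete, "proportion",
        ["opponent_type", "value_condition", "previous_outcome",
         "strategy"]).sum())

    # --- individual bias classification (unexploitable blocks) ---------
    profiles = bias_mod.bias_profiles(dataset, alpha, pvalue_method)
    results["bias_profiles"] = profiles
    results["bias_counts"] = bias_mod.bias_count_table(profiles)
    unbiased = (profiles.groupby(["participant_id", "value_condition"])
                ["label"].apply(lambda s: (s == "none").all()).reset_index())
    results["n_unbiased"] = {
        value: int(g["label"].sum())
        for value, g in unbiased.groupby("value_condition")}

    # --- success split & optimal rates (exploitable blocks) -------------
    labels = bias_mod.success_labels(dataset, alpha, success_method)
    results["success_labels"] = labels
    results["success_split"] = bias_mod.success_split(labels)

    rates = sequential.optimal_rates_long(dataset, cmap)
    results["optimal_rates"] = rates
    expl = rates[(rates["opponent_type"] == "exploitable")
                 & (rates["previous_outcome"] != "overall")]
    results["optimal_rate_means"] = (
        expl.groupby("previous_outcome", sort=False)["optimal_rate"].mean())
    results["group_win_rate_exploitable"] = float(
        (df.loc[df["opponent_type"] == "exploitable", "outcome"] == "win")
        .mean())
    return results


def exploitable_optimal_rate_frame(*datasets: Dataset) -> pd.DataFrame:
    """Per participant x value x previous-outcome optimal-response rates
    in exploitable blocks, stacked over experiments (the cross-experiment
    analysis frame)."""
    frames = []
    for dataset in datasets:
        experiment = int(dataset.df["experiment"].iloc[0])
        cmap = optimal_map_for_experiment(experiment)
        rates = sequential.optimal_rates_long(dataset, cmap)
        sub = rates[(rates["opponent_type"] == "exploitable")
                    & (rates["previous_outcome"] != "overall")].copy()
        sub["outcome"] = sub["previous_outcome"]
        frames.append(sub[["participant_id", "experiment", "value_condition",
                           "outcome", "optimal_rate"]])
    out = pd.concat(frames, ignore_index=True)
    # participant ids are unique within an experiment only
    out["participant_id"] = (out["experiment"].astype(str) + ":"
                             + out["participant_id"].astype(str))
    return out


def cross_experiment(dataset1: Dataset, dataset2: Dataset) -> dict:
    """Cross-experiment comparison bundle.

    Pooled t test of participant-level exploitable win rates, the
    three-way mixed ANOVA of optimal rates (outcome and value within,
    experiment between), and the random-intercept mixed-model comparison
    (main effects vs interaction) with outcome EMMs.
    """
    results: dict = {}
    win_rates = []
    for dataset in (dataset1, dataset2):
        expl = dataset.df[dataset.df["opponent_type"] == "exploitable"]
        per = (expl.groupby("participant_id")["outcome"]
               .apply(lambda s: (s == "win").mean()))
        win_rates.append(per.to_numpy())
    t, df_t, p = inference.two_sample_t(win_rates[0], win_rates[1])
    results["win_rate_t"] = {"t": t, "df": df_t, "p": p,
                             "mean_1": float(np.mean(win_rates[0])),
                             "mean_2": float(np.mean(win_rates[1]))}

    frame = exploitable_optimal_rate_frame(dataset1, dataset2)
    results["optimal_rate_outliers"] = int(_cell_outlier_flags(
        frame, "optimal_rate",
        ["experiment", "value_condition", "outcome"]).sum())
    complete = frame.dropna(subset=["optimal_rate"])
    cells = complete.groupby("participant_id")["optimal_rate"].count()
    keep = cells[cells == cells.max()].index
    results["mixed_anova"] = inference.rm_anova(
        complete[complete["participant_id"].isin(keep)], "optimal_rate",
        ["value_condition", "outcome"], "participant_id",
        between="experiment")
    results["lmm"] = inference.fit_lmm_emm(complete)
    results["bayes_factor_interaction"] = (
        results["lmm"].comparison.bf_interaction)
    results["emm_percent"] = {
        row["outcome"]: 100 * row["emm"]
        for _, row in results["lmm"].emms.iterrows()}
    return results


def format_anova(table: pd.DataFrame, title: str) -> str:
    """Text report mirroring the conventional
    ``F(df1, df2) = x, MSE = y, p = z, eta_p^2 = w`` layout."""
    lines = [title]
    for _, r in table.iterrows():
        df1 = r["df1_gg"] if r.get("gg_applied", False) else r["df1"]
        df2 = r["df2_gg"] if r.get("gg_applied", False) else r["df2"]
        lines.append(
            f"  {r['effect']}: F({df1:.2f}, {df2:.2f}) = {r['F']:.2f}, "
            f"MSE = {r['MSE']:.3f}, p = {r['p']:.3f}, "
            f"eta_p^2 = {r['partial_eta_sq']:.2f}"
            + ("  [GG-corrected]" if r.get("gg_applied", False) else ""))
    return "\n".join(lines)
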