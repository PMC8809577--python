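"""First-order sequential descriptives.

The central object is the outcome-conditioned strategy table: for one
participant x block, the 3x3 matrix of counts of the strategy played at
trial n+1 (stay/upgrade/downgrade) given the outcome at trial n
(win/lose/draw), built from the last 89 trials of a 90-trial block (the
first trial has no history).  Row-normalised proportions are the
quantities entered into the group analyses; optimal-response rates score
the same transitions against an outcome -> strategy contingency map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game import (ITEMS, OUTCOMES, STRATEGIES, classify_transition)
from .io import Dataset

_BLOCK_KEYS = ["participant_id", "experiment", "block_index",
               "opponent_type", "value_condition"]


@dataclass
class ConditionalTable:
    """Counts and proportions of strategy at n+1 given outcome at n."""

    counts: pd.DataFrame        # index OUTCOMES, columns STRATEGIES
    denominators: pd.Series     # transitions per previous outcome

    @property
    def proportions(self) -> pd.DataFrame:
        """Row-normalised proportions; rows with zero transitions are NaN
        (flagged via :attr:`empty_outcomes`, never imputed)."""
        denom = self.denominators.replace(0, np.nan)
        return self.counts.div(denom, axis=0)

    @property
    def empty_outcomes(self) -> list[str]:
        return [o for o in OUTCOMES if self.denominators[o] == 0]

    @property
    def n_transitions(self) -> int:
        return int(self.denominators.sum())


@dataclass
class OptimalRateSummary:
    """Proportion of transitions matching an optimal contingency map."""

    rate_by_outcome: pd.Series   # NaN where the outcome never occurred
    denominators: pd.Series

    @property
    def overall_rate(self) -> float:
        n = self.denominators.sum()
        if n == 0:
            return float("nan")
        hits = (self.rate_by_outcome.fillna(0) * self.denominators).sum()
        return float(hits / n)


def _block_frame(block) -> pd.DataFrame:
    df = block.df if isinstance(block, Dataset) else block
    return df.sort_values("trial_index")


def item_outcome_proportions(block) -> tuple[pd.Series, pd.Series]:
    """Per-item and per-outcome proportions of one block (all trials)."""
    df = _block_frame(block)
    if df.empty:
        raise ValueError("empty block")
    n = len(df)
    items = df["player_item"].value_counts().reindex(ITEMS, fill_value=0) / n
    outcomes = df["outcome"].value_counts().reindex(OUTCOMES, fill_value=0) / n
    return items, outcomes


def transitions(block) -> pd.DataFrame:
    """Long frame of (previous outcome, strategy at n+1) per transition."""
    df = _block_frame(block)
    if len(df) < 2:
        raise ValueError("need at least 2 trials to form a transition")
    prev_item = df["player_item"].to_numpy()[:-1]
    cur_item = df["player_item"].to_numpy()[1:]
    prev_outcome = df["outcome"].to_numpy()[:-1]
    strategy = [classify_transition(a, b) for a, b in zip(prev_item, cur_item)]
    return pd.DataFrame({"previous_outcome": prev_outcome, "strategy": strategy})


def conditional_strategy_table(block) -> ConditionalTable:
    """Outcome-at-n x strategy-at-n+1 counts over the block's n-1 transitions."""
    t = transitions(block)
    counts = (pd.crosstab(t["previous_outcome"], t["strategy"])
              .reindex(index=OUTCOMES, columns=STRATEGIES, fill_value=0))
    counts.index.name = "previous_outcome"
    counts.columns.name = "strategy"
    return ConditionalTable(counts, counts.sum(axis=1))


def optimal_rates(block, contingency_map: dict[str, str]) -> OptimalRateSummary:
    """Per-outcome and overall rates of playing ``contingency_map[outcome]``."""
    table = conditional_strategy_table(block)
    hits = pd.Series(
        {o: table.counts.loc[o, contingency_map[o]] for o in OUTCOMES})
    denom = table.denominators
    rates = hits / denom.replace(0, np.nan)
    return OptimalRateSummary(rates, denom)


def flag_extreme_outliers(values, k: float = 3.0,
                          method: str = "linear") -> np.ndarray:
    """Flag extreme outliers: beyond ``k`` interquartile ranges outside
    [Q1, Q3] (default k=3, the 'extreme' multiplier).

    Quartiles use linear interpolation between order statistics by
    default; ``method`` accepts any :func:`numpy.percentile` method so
    alternative conventions remain selectable (outlier counts can depend
    on the convention).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values to define quartiles")
    q1, q3 = np.percentile(x, [25, 75], method=method)
    iqr = q3 - q1
    return (x > q3 + k * iqr) | (x < q1 - k * iqr)


def strategy_proportions_long(dataset: Dataset) -> pd.DataFrame:
    """Tidy table: one row per participant x block x previous outcome x
    strategy, with count, denominator and proportion (the ANOVA cells)."""
    rows = []
    for _, block in dataset.blocks():
        table = conditional_strategy_table(block)
        keys = {k: block[k].iloc[0] for k in _BLOCK_KEYS}
        for outcome in OUTCOMES:
            denom = int(table.denominators[outcome])
            for strategy in STRATEGIES:
                count = int(table.counts.loc[outcome, strategy])
                rows.append(keys | {
                    "previous_outcome": outcome,
                    "strategy": strategy,
                    "count": count,
                    "denominator": denom,
                    "proportion": count / denom if denom else np.nan,
                })
    return pd.DataFrame(rows)


def item_proportions_long(dataset: Dataset) -> pd.DataFrame:
    """One row per participant x block x item with the choice proportion."""
    rows = []
    for _, block in dataset.blocks():
        items, _ = item_outcome_proportions(block)
        keys = {k: block[k].iloc[0] for k in _BLOCK_KEYS}
        rows.extend(keys | {"item": i, "proportion": items[i]} for i in ITEMS)
    return pd.DataFrame(rows)


def outcome_proportions_long(dataset: Dataset) -> pd.DataFrame:
    """One row per participant x block x outcome with the outcome rate."""
    rows = []
    for _, block in dataset.blocks():
        _, outcomes = item_outcome_proportions(block)
        keys = {k: block[k].iloc[0] for k in _BLOCK_KEYS}
        rows.extend(keys | {"outcome": o, "proportion": outcomes[o]}
                    for o in OUTCOMES)
    return pd.DataFrame(rows)


def optimal_rates_long(dataset: Dataset,
                       contingency_map: dict[str, str]) -> pd.DataFrame:
    """Per participant x block x previous outcome optimal-response rates."""
    rows = []
    for _, block in dataset.blocks():
        summary = optimal_rates(block, contingency_map)
        keys = {k: block[k].iloc[0] for k in _BLOCK_KEYS}
        for outcome in OUTCOMES:
            rows.append(keys | {
                "previous_outcome": outcome,
                "optimal_rate": summary.rate_by_outcome[outcome],
                "denominator": int(summary.denominators[outcome]),
            })
        rows.append(keys | {"previous_outcome": "overall",
                            "optimal_rate": summary.overall_rate,
                            "denominator": int(summary.denominators.sum())})
    return pd.DataFrame(rows)


def condition_summary(dataset: Dataset) -> pd.DataFrame:
    """Item- and outcome-proportion summary by opponent x value condition:
    group mean with both SD and SE in separate columns (the two
    parenthetical conventions found in published condition tables)."""
    parts = []
    for kind, long in (("item", item_proportions_long(dataset)),
                       ("outcome", outcome_proportions_long(dataset))):
        level_col = "item" if kind == "item" else "outcome"
        g = (long.groupby(["opponent_type", "value_condition", level_col],
                          sort=False)["proportion"]
             .agg(mean="mean", sd="std", n="count"))
        g["se"] = g["sd"] / np.sqrt(g["n"])
        g = g.reset_index().rename(columns={level_col: "level"})
        g.insert(0, "measure", kind)
        parts.append(g)
    return pd.concat(parts, ignore_index=True)
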