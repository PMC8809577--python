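"""Sequential descriptives: conditional tables, optimal rates, outliers."""

import numpy as np
import pandas as pd
import pytest

from rpskit.game import ITEMS, OUTCOMES, apply_strategy, optimal_map_for_experiment
from rpskit.sequential import (conditional_strategy_table,
                               flag_extreme_outliers,
                               item_outcome_proportions, optimal_rates,
                               strategy_proportions_long)

from conftest import make_block_frame


class TestToyBlock:
    """Hand-enumerated four-trial example: player R,R,P,S vs S,R,R,P.

    Outcomes are win, draw, win, win; the three transitions are
    R->R (after win: stay), R->P (after draw: upgrade),
    P->S (after win: upgrade).
    """

    def test_item_outcome_proportions(self, toy_block):
        items, outcomes = item_outcome_proportions(toy_block)
        assert outcomes["win"] == 0.75
        assert outcomes["lose"] == 0.0
        assert outcomes["draw"] == 0.25
        assert items["rock"] == 0.5

    def test_conditional_table(self, toy_block):
        table = conditional_strategy_table(toy_block)
        assert table.n_transitions == 3
        win_row = table.proportions.loc["win"]
        assert win_row["stay"] == 0.5 and win_row["upgrade"] == 0.5
        assert win_row["downgrade"] == 0.0
        draw_row = table.proportions.loc["draw"]
        assert draw_row["upgrade"] == 1.0
        assert table.empty_outcomes == ["lose"]

    def test_optimal_rates_against_experiment1_map(self, toy_block):
        summary = optimal_rates(toy_block, optimal_map_for_experiment(1))
        # optimal after win is downgrade (neither observed transition),
        # after draw is stay (the observed one was upgrade)
        assert summary.rate_by_outcome["win"] == 0.0
        assert summary.rate_by_outcome["draw"] == 0.0
        assert np.isnan(summary.rate_by_outcome["lose"])
        assert summary.overall_rate == 0.0


def test_all_draw_block_outcome_vector():
    frame = make_block_frame(["rock"] * 10, ["rock"] * 10)
    _, outcomes = item_outcome_proportions(frame)
    assert outcomes.tolist() == [0.0, 0.0, 1.0]


def test_constant_item_block_is_pure_stay():
    frame = make_block_frame(["paper"] * 20, ["rock", "paper"] * 10)
    table = conditional_strategy_table(frame)
    props = table.proportions
    for outcome in OUTCOMES:
        if outcome not in table.empty_outcomes:
            assert props.loc[outcome, "stay"] == 1.0


def test_counts_partition_transitions(small_dataset):
    for _, block in small_dataset.blocks():
        table = conditional_strategy_table(block)
        assert table.n_transitions == len(block) - 1
        assert int(table.counts.to_numpy().sum()) == len(block) - 1


def test_transition_attributed_to_outcome_at_n():
    # single informative transition: trial 1 outcome is a loss, trial 2
    # transition must land in the 'lose' row regardless of trial 2 outcome
    frame = make_block_frame(["rock", "paper"], ["paper", "rock"])
    table = conditional_strategy_table(frame)
    assert table.counts.loc["lose", "upgrade"] == 1
    assert table.counts.to_numpy().sum() == 1


def test_optimal_rates_invariant_under_item_relabeling(small_dataset):
    """Cyclic relabeling of all items leaves strategy labels, outcomes and
    hence optimal rates unchanged."""
    cmap = optimal_map_for_experiment(1)
    relabel = {i: apply_strategy(i, "upgrade") for i in ITEMS}
    _, block = next(iter(small_dataset.blocks()))
    rotated = block.copy()
    rotated["player_item"] = rotated["player_item"].map(relabel)
    rotated["opponent_item"] = rotated["opponent_item"].map(relabel)
    base = optimal_rates(block, cmap)
    rot = optimal_rates(rotated, cmap)
    pd.testing.assert_series_equal(base.rate_by_outcome, rot.rate_by_outcome)


class TestExtremeOutliers:
    def test_single_extreme_value_flagged(self):
        values = list(range(1, 9)) + [1000]
        flags = flag_extreme_outliers(values)
        assert flags.tolist() == [False] * 8 + [True]

    def test_constant_vector_unflagged(self):
        assert not flag_extreme_outliers([2.0] * 10).any()

    def test_moderate_spread_unflagged(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 200)  # normal data: 3 IQR fences ~ +-5.4 SD
        assert not flag_extreme_outliers(values).any()

    def test_needs_four_values(self):
        with pytest.raises(ValueError):
            flag_extreme_outliers([1.0, 2.0, 3.0])


def test_parameter_recovery_single_block():
    """Conditional proportions estimated from one 90-trial block recover
    a known generative pi within exact binomial 99% CIs."""
    from scipy import stats

    from rpskit.agents import ConditionalStrategyAgent
    from rpskit.opponents import build_unexploitable_policy
    from rpskit.simulate import simulate_block

    pi = {"win": np.array([0.6, 0.3, 0.1]),
          "lose": np.array([0.1, 0.7, 0.2]),
          "draw": np.array([1 / 3, 1 / 3, 1 / 3])}
    agent = ConditionalStrategyAgent({k: v.copy() for k, v in pi.items()})
    rng = np.random.default_rng(123)
    records = simulate_block(agent, build_unexploitable_policy(30, rng), 90, rng)
    frame = pd.DataFrame(records)
    frame["participant_id"] = "P1"
    table = conditional_strategy_table(frame)
    for outcome in OUTCOMES:
        n = int(table.denominators[outcome])
        if n == 0:
            continue
        for j, strategy in enumerate(("stay", "upgrade", "downgrade")):
            k = int(table.counts.loc[outcome, strategy])
            low, high = stats.binom.interval(0.99, n, pi[outcome][j])
            assert low <= k <= high


def test_strategy_long_table_shape(small_dataset):
    long = strategy_proportions_long(small_dataset)
    # 8 participants x 4 blocks x 3 outcomes x 3 strategies
    assert len(long) == 8 * 4 * 9
    sums = long.groupby(["participant_id", "block_index",
                         "previous_outcome"])["count"].sum()
    denoms = long.groupby(["participant_id", "block_index",
                           "previous_outcome"])["denominator"].first()
    assert (sums == denoms).all()
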