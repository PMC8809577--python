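"""Full-experiment simulation in the original 2x2 within-participant design.

Each synthetic participant plays four 90-trial blocks crossing opponent
type (unexploitable, exploitable) with incentive value (low, high), in a
semi-counterbalanced order whose only constraint is that no two
consecutive blocks share an opponent type.  Every block gets its own
random stream derived from ``(master_seed, participant, block)``, so any
block is reproducible in isolation and the whole dataset is a pure
function of the design, the participant profiles and the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .agents import REWARD, ConditionalStrategyAgent, LearningAgent
from .game import EXPERIMENT_RULES, classify_transition, optimal_map_for_experiment, score_outcome
from .io import Dataset
from .opponents import DeckPolicy, ExploitablePolicy, build_exploitable_policy, build_unexploitable_policy

Condition = tuple[str, str]  # (opponent_type, value_condition)


def default_counterbalance_orders() -> list[tuple[Condition, ...]]:
    """The eight block orders with alternating opponent types.

    Opponent types follow either U-E-U-E or E-U-E-U; the two value
    levels are assigned to the two blocks of each opponent type in both
    orders, giving 2 x 2 x 2 = 8 orders.
    """
    orders = []
    for first in ("unexploitable", "exploitable"):
        second = ("exploitable" if first == "unexploitable" else "unexploitable")
        for v1 in ("low", "high"):
            for v2 in ("low", "high"):
                other1 = "high" if v1 == "low" else "low"
                other2 = "high" if v2 == "low" else "low"
                orders.append(((first, v1), (second, v2),
                               (first, other1), (second, other2)))
    return orders


@dataclass
class ExperimentDesign:
    """Design parameters of one experiment."""

    experiment: int = 1
    n_participants: int = 40
    block_length: int = 90
    rule_fraction: float = 0.7
    counterbalance_orders: Sequence[tuple[Condition, ...]] = field(
        default_factory=default_counterbalance_orders)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_RULES:
            raise ValueError("experiment must be 1 or 2")
        if self.block_length % 3:
            raise ValueError("block_length must be divisible by 3")
        for order in self.counterbalance_orders:
            opp = [c[0] for c in order]
            if any(a == b for a, b in zip(opp, opp[1:])):
                raise ValueError(
                    f"order {order} has consecutive blocks with the same "
                    "opponent type")

    @property
    def opponent_rule(self) -> str:
        return EXPERIMENT_RULES[self.experiment]


AgentFactory = Callable[[], ConditionalStrategyAgent | LearningAgent]


def successful_learner() -> LearningAgent:
    """Profile for a participant who learns the exploiting contingency.

    Greedy-ish softmax with valence-weighted learning rates: updating is
    slower in the loss context, emulating the observed inhibition of
    learning after losses (optimal-response rates ordered
    win > draw > lose).
    """
    return LearningAgent(
        learning_rate={"win": 0.40, "draw": 0.30, "lose": 0.12},
        temperature=0.18)


def intermediate_learner() -> LearningAgent:
    """Noisier, slower learner; exceeds chance on some blocks only."""
    return LearningAgent(
        learning_rate={"win": 0.12, "draw": 0.09, "lose": 0.04},
        temperature=0.60)


def non_learner() -> ConditionalStrategyAgent:
    """Mixed-strategy player (uniform over strategies after any outcome)."""
    return ConditionalStrategyAgent.uniform()


def default_profiles(n_participants: int = 40) -> list[AgentFactory]:
    """Profile mix emulating the observed success split: for 40
    participants, 17 consistent learners, 8 non-learners playing
    randomly, and 15 intermediate learners, interleaved across the
    counterbalance cycle."""
    quotas = {
        successful_learner: round(n_participants * 17 / 40),
        non_learner: round(n_participants * 8 / 40),
    }
    quotas[intermediate_learner] = n_participants - sum(quotas.values())
    pattern = [successful_learner, intermediate_learner, non_learner]
    profiles: list[AgentFactory] = []
    remaining = dict(quotas)
    i = 0
    while len(profiles) < n_participants:
        factory = pattern[i % len(pattern)]
        if remaining[factory] > 0:
            remaining[factory] -= 1
            profiles.append(factory)
        i += 1
        if i > 10 * n_participants:  # quotas exhausted for some profile
            for factory, left in remaining.items():
                profiles.extend([factory] * left)
            break
    return profiles[:n_participants]


def simulate_block(agent, policy: DeckPolicy | ExploitablePolicy,
                   n_trials: int, rng: np.random.Generator | int | None = None
                   ) -> list[dict]:
    """Play one block; returns one record dict per trial.

    Information flow mirrors the original task: the opponent sees only
    its own previous move; the agent sees its own previous move and the
    previous outcome (the feedback screen), and learning agents receive
    the game points of the round they just played.
    """
    if isinstance(policy, DeckPolicy) and len(policy) < n_trials:
        raise ValueError("deck smaller than the requested block length")
    if isinstance(policy, ExploitablePolicy) and policy.n_trials != n_trials:
        raise ValueError("policy block length != requested n_trials")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    records = []
    prev_own: str | None = None
    prev_outcome: str | None = None
    for t in range(1, n_trials + 1):
        player = agent.next_item(prev_own, prev_outcome, rng)
        move = policy.next_move()
        outcome = score_outcome(player, move.item)
        if prev_own is not None:
            strategy = classify_transition(prev_own, player)
            agent.observe(prev_outcome, strategy, REWARD[outcome])
        records.append({
            "trial_index": t,
            "player_item": player,
            "opponent_item": move.item,
            "outcome": outcome,
            "opp_rule_trial": int(move.provenance == "rule"),
        })
        prev_own, prev_outcome = player, outcome
    return records


def block_seed(master_seed: int, participant: int, block_index: int
               ) -> np.random.SeedSequence:
    return np.random.SeedSequence((master_seed, participant, block_index))


def simulate_experiment(design: ExperimentDesign,
                        profiles: Sequence[AgentFactory] | None = None,
                        master_seed: int = 0) -> Dataset:
    """Simulate a full experiment; returns a canonical-schema Dataset."""
    profiles = list(profiles) if profiles is not None else default_profiles(
        design.n_participants)
    if len(profiles) != design.n_participants:
        raise ValueError("one agent factory required per participant")
    orders = list(design.counterbalance_orders)
    frames = []
    for p in range(design.n_participants):
        order = orders[p % len(orders)]
        for b, (opp_type, value) in enumerate(order, start=1):
            rng = np.random.default_rng(block_seed(master_seed, p, b))
            if opp_type == "unexploitable":
                policy = build_unexploitable_policy(design.block_length // 3, rng)
            else:
                policy = build_exploitable_policy(
                    design.opponent_rule, design.block_length,
                    design.rule_fraction, rng)
            agent = profiles[p]()
            records = simulate_block(agent, policy, design.block_length, rng)
            frame = pd.DataFrame.from_records(records)
            frame.insert(0, "participant_id", f"P{p + 1:03d}")
            frame.insert(1, "experiment", design.experiment)
            frame.insert(2, "block_index", b)
            frame.insert(3, "opponent_type", opp_type)
            frame.insert(4, "value_condition", value)
            frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    return Dataset(df, provenance="simulated",
                   source=f"simulate_experiment(seed={master_seed})")


def win_rate_monte_carlo(agent_factory: AgentFactory,
                         opponent: str, experiment: int = 1,
                         n_blocks: int = 10_000, block_length: int = 90,
                         master_seed: int = 0) -> np.ndarray:
    """Per-block win rates of an agent over many independently seeded blocks.

    A lightweight loop (no data-frame assembly) so that large Monte-
    Carlo runs — e.g. verifying the exact 72/90 expectation of the
    optimal agent against the exploitable opponent — stay fast.
    """
    if opponent not in ("unexploitable", "exploitable"):
        raise ValueError("opponent must be 'unexploitable' or 'exploitable'")
    rule = EXPERIMENT_RULES[experiment]
    rates = np.empty(n_blocks)
    root = np.random.SeedSequence(master_seed)
    for i, child in enumerate(root.spawn(n_blocks)):
        rng = np.random.default_rng(child)
        if opponent == "unexploitable":
            policy = build_unexploitable_policy(block_length // 3, rng)
        else:
            policy = build_exploitable_policy(rule, block_length, 0.7, rng)
        agent = agent_factory()
        wins = 0
        prev_own = prev_outcome = None
        for _ in range(block_length):
            player = agent.next_item(prev_own, prev_outcome, rng)
            move = policy.next_move()
            outcome = score_outcome(player, move.item)
            if prev_own is not None:
                agent.observe(prev_outcome,
                              classify_transition(prev_own, player),
                              REWARD[outcome])
            wins += outcome == "win"
            prev_own, prev_outcome = player, outcome
        rates[i] = wins / block_length
    return rates


def optimal_agent_factory(experiment: int) -> AgentFactory:
    """Factory for the deterministic optimal-contingency-map agent."""
    cmap = optimal_map_for_experiment(experiment)
    return lambda: ConditionalStrategyAgent.from_map(cmap)


def simulate_optimal_rate_data(n_participants: int = 80,
                               outcome_means: dict[str, float] | None = None,
                               participant_sd: float = 0.10,
                               residual_sd: float = 0.10,
                               seed: int = 0) -> pd.DataFrame:
    """Synthetic per-block optimal-response rates with planted outcome effects.

    Emulates the cross-experiment analysis frame: participants split
    evenly across two experiments, one rate per participant x outcome x
    exploitable block (two blocks), a normal participant intercept and
    normal residual noise around planted outcome means (defaults: win
    .60, draw .50, lose .43; participant SD .10).  Rates are clipped to
    [0, 1].
    """
    outcome_means = outcome_means or {"win": 0.60, "draw": 0.50, "lose": 0.43}
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        intercept = rng.normal(0.0, participant_sd)
        experiment = 1 if p < n_participants // 2 else 2
        for outcome, mu in outcome_means.items():
            for value in ("low", "high"):
                rate = np.clip(mu + intercept + rng.normal(0.0, residual_sd),
                               0.0, 1.0)
                rows.append({"participant_id": f"P{p + 1:03d}",
                             "experiment": experiment,
                             "value_condition": value,
                             "outcome": outcome,
                             "optimal_rate": rate})
    return pd.DataFrame(rows)
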