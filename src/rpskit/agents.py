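"""Synthetic participant agents.

These agents emulate the *structure* of human play — a first-order
dependence of the current choice on the previous trial's outcome — not
any claim about the human mechanism.  Two families are provided:

``ConditionalStrategyAgent``
    A fixed outcome-conditioned Markov policy: for each previous outcome
    (win/lose/draw) a probability vector over the strategy classes
    (stay/upgrade/downgrade).  The uniform agent (all rows 1/3) is the
    mixed-strategy player; a degenerate agent with each row at the
    optimal strategy plays the exploiting counter-map perfectly.

``LearningAgent``
    A softmax/delta-rule learner over the same outcome -> strategy
    structure: it keeps an action value q[outcome][strategy], chooses by
    softmax(q / temperature), and updates the chosen entry toward the
    realised game points (+1 win, -1 loss, 0 draw).  Per-outcome
    learning rates allow valence-weighted learning (e.g. slower updating
    in the loss context).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import (ITEMS, OUTCOMES, STRATEGIES, STRATEGY_INDEX, apply_strategy)

#: game points per outcome, used as the learning signal
REWARD = {"win": 1.0, "lose": -1.0, "draw": 0.0}


def _check_prob_row(row: np.ndarray, label: str) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if row.shape != (3,) or (row < 0).any() or abs(row.sum() - 1.0) > 1e-12:
        raise ValueError(f"{label} must be a length-3 probability vector")
    return row


@dataclass
class ConditionalStrategyAgent:
    """Fixed outcome-conditioned strategy policy.

    ``pi[outcome]`` is the probability vector over (stay, upgrade,
    downgrade) used after that outcome; ``first_move_distribution`` is
    the item distribution for trial 1 (default uniform).
    """

    pi: dict[str, np.ndarray]
    first_move_distribution: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))

    def __post_init__(self) -> None:
        self.pi = {o: _check_prob_row(self.pi[o], f"pi[{o}]") for o in OUTCOMES}
        self.first_move_distribution = _check_prob_row(
            self.first_move_distribution, "first_move_distribution")

    @classmethod
    def uniform(cls) -> "ConditionalStrategyAgent":
        return cls({o: np.full(3, 1.0 / 3.0) for o in OUTCOMES})

    @classmethod
    def from_map(cls, contingency_map: dict[str, str]) -> "ConditionalStrategyAgent":
        """Degenerate agent that always plays ``contingency_map[outcome]``."""
        pi = {}
        for outcome, strategy in contingency_map.items():
            row = np.zeros(3)
            row[STRATEGY_INDEX[strategy]] = 1.0
            pi[outcome] = row
        return cls(pi)

    def strategy_probabilities(self, previous_outcome: str) -> np.ndarray:
        return self.pi[previous_outcome]

    def next_item(self, previous_own: str | None, previous_outcome: str | None,
                  rng: np.random.Generator) -> str:
        if previous_own is None or previous_outcome is None:
            if (previous_own is None) != (previous_outcome is None):
                raise ValueError("previous item and outcome must both be "
                                 "present or both absent")
            return ITEMS[rng.choice(3, p=self.first_move_distribution)]
        probs = self.strategy_probabilities(previous_outcome)
        strategy = STRATEGIES[rng.choice(3, p=probs)]
        return apply_strategy(previous_own, strategy)

    def observe(self, previous_outcome: str, chosen_strategy: str,
                reward: float) -> None:
        """Fixed policy: feedback is ignored."""


@dataclass
class LearningAgent:
    """Softmax/delta-rule learner over outcome -> strategy values.

    Parameters
    ----------
    learning_rate
        Step size(s) in (0, 1]: either a scalar or a per-outcome dict,
        allowing valence-dependent learning speed.
    temperature
        Softmax concentration (> 0); lower is greedier.  In the
        temperature -> 0 limit with values peaked at the optimal
        strategies the agent plays the optimal contingency map.
    """

    learning_rate: float | dict[str, float] = 0.3
    temperature: float = 0.25
    initial_q: float = 0.0
    first_move_distribution: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))
    q: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not isinstance(self.learning_rate, dict):
            self.learning_rate = {o: float(self.learning_rate) for o in OUTCOMES}
        for o, lr in self.learning_rate.items():
            if not 0 < lr <= 1:
                raise ValueError(f"learning rate for {o} must be in (0, 1]")
        self.first_move_distribution = _check_prob_row(
            self.first_move_distribution, "first_move_distribution")
        self.q = {o: np.full(3, float(self.initial_q)) for o in OUTCOMES}

    def strategy_probabilities(self, previous_outcome: str) -> np.ndarray:
        z = self.q[previous_outcome] / self.temperature
        z = z - z.max()  # overflow guard
        ez = np.exp(z)
        return ez / ez.sum()

    def next_item(self, previous_own: str | None, previous_outcome: str | None,
                  rng: np.random.Generator) -> str:
        if previous_own is None or previous_outcome is None:
            if (previous_own is None) != (previous_outcome is None):
                raise ValueError("previous item and outcome must both be "
                                 "present or both absent")
            return ITEMS[rng.choice(3, p=self.first_move_distribution)]
        probs = self.strategy_probabilities(previous_outcome)
        strategy = STRATEGIES[rng.choice(3, p=probs)]
        return apply_strategy(previous_own, strategy)

    def observe(self, previous_outcome: str, chosen_strategy: str,
                reward: float) -> None:
        """Delta-rule update of the chosen entry toward the reward."""
        lr = self.learning_rate[previous_outcome]
        j = STRATEGY_INDEX[chosen_strategy]
        self.q[previous_outcome][j] += lr * (reward - self.q[previous_outcome][j])

    def greedy_map(self) -> dict[str, str]:
        """Current argmax policy (ties broken by stay < upgrade < downgrade)."""
        return {o: STRATEGIES[int(np.argmax(self.q[o]))] for o in OUTCOMES}
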