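"""Computer-opponent policies.

Two opponents are modelled:

* an **unexploitable** opponent that draws its 90 moves without
  replacement from an equal deck (30 rock, 30 paper, 30 scissors) — no
  participant strategy changes expected outcomes against it;
* an **exploitable** opponent that on 70% of trials (63 of 90) applies a
  deterministic first-order rule to its own previous move, and on the
  remaining 30% (27 trials, always including trial 1) draws without
  replacement from an equal 27-card deck.

Both policies are deterministic given their seed; each move carries a
provenance flag (``rule`` or ``random``) so generated logs can be audited
post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import ITEMS, STRATEGIES, apply_rule


@dataclass
class OpponentMove:
    item: str
    provenance: str  # "rule" | "random"


class DeckPolicy:
    """Without-replacement draws from a fixed multiset of items.

    Parameters
    ----------
    counts
        Number of copies of each item in the deck, keyed by item name
        (missing items count 0).  Default 30 each, the unexploitable
        opponent's block deck.
    rng
        A seeded :class:`numpy.random.Generator`, or an integer seed.
    """

    def __init__(self, counts: dict[str, int] | None = None,
                 rng: np.random.Generator | int | None = None):
        counts = dict(counts) if counts is not None else {i: 30 for i in ITEMS}
        for item, c in counts.items():
            if item not in ITEMS:
                raise ValueError(f"unknown item in deck counts: {item!r}")
            if c < 0:
                raise ValueError("deck counts must be non-negative")
        self.counts = {i: counts.get(i, 0) for i in ITEMS}
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        deck = [item for item in ITEMS for _ in range(self.counts[item])]
        self._deck: list[str] = list(rng.permutation(deck)) if deck else []
        self._pos = 0

    def __len__(self) -> int:
        return len(self._deck) - self._pos

    @property
    def previous_item(self) -> str | None:
        return self._deck[self._pos - 1] if self._pos else None

    def next_move(self) -> OpponentMove:
        if self._pos >= len(self._deck):
            raise RuntimeError("deck exhausted")
        item = self._deck[self._pos]
        self._pos += 1
        return OpponentMove(item, "random")


class ExploitablePolicy:
    """Rule-following opponent with a fixed random/rule schedule.

    The schedule fixes, before play, which trials apply the rule and
    which draw from the equal random deck; trial 1 is always a deck draw
    (the rule needs a previous own move).  Rule trials transform the
    opponent's previous *actual* move, whatever its provenance.
    """

    def __init__(self, rule: str, n_trials: int = 90, rule_fraction: float = 0.7,
                 rng: np.random.Generator | int | None = None):
        if rule not in STRATEGIES:
            raise ValueError(f"not a valid opponent rule: {rule!r}")
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        n_rule_f = rule_fraction * n_trials
        n_rule = round(n_rule_f)
        if abs(n_rule_f - n_rule) > 1e-9:
            raise ValueError(
                f"rule_fraction * n_trials must be integral, got {n_rule_f}")
        n_random = n_trials - n_rule
        if n_random < 1:
            raise ValueError("at least one random trial required (trial 1)")
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

        # trial 1 forced random; remaining rule/random positions shuffled
        # uniformly over trials 2..n
        tail = np.array(["rule"] * n_rule + ["random"] * (n_random - 1))
        self.schedule: list[str] = ["random"] + list(rng.permutation(tail))

        per_item, rem = divmod(n_random, 3)
        if rem:
            raise ValueError("random-trial count must split equally across items")
        self.rule = rule
        self.n_trials = n_trials
        self.n_rule_trials = n_rule
        self._deck = DeckPolicy({i: per_item for i in ITEMS}, rng)
        self._trial = 0
        self._previous: str | None = None

    def next_move(self) -> OpponentMove:
        if self._trial >= self.n_trials:
            raise RuntimeError("block exhausted")
        kind = self.schedule[self._trial]
        self._trial += 1
        if kind == "rule":
            assert self._previous is not None, "rule trial with no previous move"
            move = OpponentMove(apply_rule(self.rule, self._previous), "rule")
        else:
            move = self._deck.next_move()
        self._previous = move.item
        return move


def build_unexploitable_policy(counts_per_item: int = 30,
                               seed: np.random.Generator | int | None = None) -> DeckPolicy:
    """Equal-deck opponent for one block (default 30 of each item, 90 trials)."""
    return DeckPolicy({i: counts_per_item for i in ITEMS}, seed)


def build_exploitable_policy(rule: str, n_trials: int = 90, rule_fraction: float = 0.7,
                             seed: np.random.Generator | int | None = None) -> ExploitablePolicy:
    """70/30 rule-following opponent for one block (default 63 rule + 27 deck)."""
    return ExploitablePolicy(rule, n_trials, rule_fraction, seed)


def generate_block_moves(policy: DeckPolicy | ExploitablePolicy,
                         n_trials: int) -> list[OpponentMove]:
    """Materialise a full block of opponent moves (for audits and tests)."""
    return [policy.next_move() for _ in range(n_trials)]
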