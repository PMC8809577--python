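"""Core algebra of cyclic Rock-Paper-Scissors play.

The three items form a 3-cycle under the "beats" relation (paper beats
rock, scissors beats paper, rock beats scissors).  Transitions between a
player's consecutive choices are coded into three strategy classes:

* ``stay``      — repeat the previous item;
* ``upgrade``   — shift to the item that beats the previous item
  (rock -> paper);
* ``downgrade`` — shift to the item the previous item beats
  (rock -> scissors).

These classes partition all ordered item pairs, so any trial-to-trial
transition has a unique strategy label.  The same vocabulary describes
first-order computer-opponent rules (an opponent that, say, always
downgrades its own previous move), and :func:`derive_optimal_map` turns
such a rule into the outcome-conditional counter-strategy that beats it.
"""

from __future__ import annotations

from typing import Mapping

ITEMS: tuple[str, str, str] = ("rock", "paper", "scissors")
OUTCOMES: tuple[str, str, str] = ("win", "lose", "draw")
STRATEGIES: tuple[str, str, str] = ("stay", "upgrade", "downgrade")

# item -> item it beats
_BEATS: dict[str, str] = {"rock": "scissors", "paper": "rock", "scissors": "paper"}
# item -> item that beats it
_BEATEN_BY: dict[str, str] = {v: k for k, v in _BEATS.items()}

ITEM_INDEX: dict[str, int] = {item: i for i, item in enumerate(ITEMS)}
STRATEGY_INDEX: dict[str, int] = {s: i for i, s in enumerate(STRATEGIES)}
OUTCOME_INDEX: dict[str, int] = {o: i for i, o in enumerate(OUTCOMES)}


def _check_item(item: str) -> None:
    if item not in _BEATS:
        raise ValueError(f"not a valid item: {item!r}")


def score_outcome(player: str, opponent: str) -> str:
    """Score one round from the player's perspective.

    Returns ``"win"`` if *player* beats *opponent* under the 3-cycle,
    ``"draw"`` on equal items, ``"lose"`` otherwise.
    """
    _check_item(player)
    _check_item(opponent)
    if player == opponent:
        return "draw"
    return "win" if _BEATS[player] == opponent else "lose"


def apply_strategy(previous: str, strategy: str) -> str:
    """Map a previous item through a strategy class to the next item."""
    _check_item(previous)
    if strategy == "stay":
        return previous
    if strategy == "upgrade":
        return _BEATEN_BY[previous]
    if strategy == "downgrade":
        return _BEATS[previous]
    raise ValueError(f"not a valid strategy: {strategy!r}")


def classify_transition(previous: str, current: str) -> str:
    """Inverse of :func:`apply_strategy`: label the transition previous -> current."""
    _check_item(previous)
    _check_item(current)
    if current == previous:
        return "stay"
    if current == _BEATEN_BY[previous]:
        return "upgrade"
    return "downgrade"


def apply_rule(rule: str, previous: str) -> str:
    """Apply a first-order opponent rule (a strategy class acting on the
    opponent's own previous item)."""
    return apply_strategy(previous, rule)


def derive_optimal_map(rule: str) -> dict[str, str]:
    """Derive the outcome-conditional optimal counter-strategy against a
    deterministic first-order opponent rule.

    For every ordered pair (player-previous, opponent-previous) the
    opponent's next item is ``rule(opponent-previous)``; the unique
    winning reply is the item that beats it.  The strategy class that
    carries the player's previous item onto that winning reply turns out
    to depend only on the previous round's *outcome*, never on which
    items realised it — the cyclic symmetry collapses the nine pairs to
    three outcome rows.  This collapse is asserted, not assumed.
    """
    if rule not in STRATEGIES:
        raise ValueError(f"not a valid opponent rule: {rule!r}")
    mapping: dict[str, str] = {}
    for player_prev in ITEMS:
        for opp_prev in ITEMS:
            outcome = score_outcome(player_prev, opp_prev)
            opp_next = apply_rule(rule, opp_prev)
            winning_reply = _BEATEN_BY[opp_next]
            strategy = classify_transition(player_prev, winning_reply)
            if outcome in mapping and mapping[outcome] != strategy:
                raise AssertionError(
                    "optimal strategy is not outcome-determined for "
                    f"rule={rule!r}: outcome {outcome} maps to both "
                    f"{mapping[outcome]} and {strategy}"
                )
            mapping[outcome] = strategy
    return {o: mapping[o] for o in OUTCOMES}


#: Opponent rule used by the exploitable computer opponent in each
#: experiment.  Experiment 1's opponent downgrades its own previous item;
#: experiment 2's upgrades it (the only first-order rule whose optimal
#: counter-map is win-upgrade / lose-stay / draw-downgrade).
EXPERIMENT_RULES: Mapping[int, str] = {1: "downgrade", 2: "upgrade"}


def optimal_map_for_experiment(experiment: int) -> dict[str, str]:
    """Outcome -> optimal strategy map for the given experiment (1 or 2)."""
    try:
        rule = EXPERIMENT_RULES[experiment]
    except KeyError:
        raise ValueError(f"experiment must be 1 or 2, got {experiment!r}") from None
    return derive_optimal_map(rule)
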