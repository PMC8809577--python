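"""Individual-level bias classification and the success split.

A participant has a *bias* toward a strategy after a given outcome when
(a) a two-tailed exact binomial test rejects the null rate of 1/3 for
that strategy's conditional proportion, and (b) the proportion exceeds
1/3 (a significantly *low* rate signals a bias toward some other
strategy, not this one).  Upgrade and downgrade biases collapse into a
general *shift* bias; stay biases are reported separately.  No
multiple-testing correction is applied across the nine per-participant
tests: the labels carry raw per-test alpha semantics by design, and the
summary tables should be read accordingly.

The *success* split labels each exploitable block by a one-tailed
one-sample proportions test of the win rate against 1/3 (continuity-
corrected normal by default; exact binomial selectable), and aggregates
the participant's two exploitable blocks into successful-on-both /
failed-one / failed-both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .game import OUTCOMES, STRATEGIES
from .io import Dataset
from .sequential import ConditionalTable, conditional_strategy_table

NULL_PROPORTION = 1.0 / 3.0  # the symmetric three-choice null ("33.3%")


def exact_binomial_p(k: int, n: int, p0: float = NULL_PROPORTION,
                     sided: str = "two", method: str = "min-likelihood") -> float:
    """Exact binomial p-value.

    ``sided="two"`` with ``method="min-likelihood"`` sums the pmf over
    all outcomes no more likely than the observed one (the convention of
    mainstream statistics tooling); ``method="doubling"`` doubles the
    smaller tail, capped at 1.  ``sided="one_greater"`` is the upper
    tail including k.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"null proportion must be in (0,1), got {p0}")
    if sided == "one_greater":
        return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    if sided != "two":
        raise ValueError(f"unknown sidedness {sided!r}")
    if method == "min-likelihood":
        return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    if method == "doubling":
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown two-sided method {method!r}")


@dataclass
class OutcomeBias:
    """Test results for one previous-outcome row of a conditional table."""

    label: str                    # stay_bias | shift_bias | both | none | indeterminate
    p_values: dict[str, float]    # per strategy
    proportions: dict[str, float]
    denominator: int


@dataclass
class BiasProfile:
    """Per-outcome bias labels for one participant x block."""

    by_outcome: dict[str, OutcomeBias]

    @property
    def unbiased(self) -> bool:
        """True when no test rejected after any outcome (the fully
        reinforcement-neutral pattern)."""
        return all(b.label == "none" for b in self.by_outcome.values()
                   if b.label != "indeterminate")


def classify_bias(table: ConditionalTable, alpha: float = 0.05,
                  method: str = "min-likelihood") -> BiasProfile:
    """Classify stay/shift biases from one conditional strategy table."""
    by_outcome = {}
    for outcome in OUTCOMES:
        n = int(table.denominators[outcome])
        if n == 0:
            by_outcome[outcome] = OutcomeBias(
                "indeterminate", {}, {}, 0)
            continue
        p_values, proportions, biased = {}, {}, []
        for strategy in STRATEGIES:
            k = int(table.counts.loc[outcome, strategy])
            p = exact_binomial_p(k, n, NULL_PROPORTION, "two", method)
            p_values[strategy] = p
            proportions[strategy] = k / n
            if p < alpha and k / n > NULL_PROPORTION:
                biased.append(strategy)
        has_stay = "stay" in biased
        has_shift = any(s in biased for s in ("upgrade", "downgrade"))
        if has_stay and has_shift:
            label = "both"
        elif has_stay:
            label = "stay_bias"
        elif has_shift:
            label = "shift_bias"
        else:
            label = "none"
        by_outcome[outcome] = OutcomeBias(label, p_values, proportions, n)
    return BiasProfile(by_outcome)


def bias_profiles(dataset: Dataset, alpha: float = 0.05,
                  method: str = "min-likelihood",
                  opponent_type: str = "unexploitable") -> pd.DataFrame:
    """Per participant x block bias labels for blocks of one opponent type."""
    rows = []
    for _, block in dataset.blocks():
        if block["opponent_type"].iloc[0] != opponent_type:
            continue
        profile = classify_bias(conditional_strategy_table(block), alpha, method)
        base = {k: block[k].iloc[0] for k in
                ("participant_id", "experiment", "block_index",
                 "value_condition")}
        for outcome, b in profile.by_outcome.items():
            rows.append(base | {
                "previous_outcome": outcome, "label": b.label,
                "denominator": b.denominator,
                **{f"p_{s}": b.p_values.get(s, np.nan) for s in STRATEGIES},
                **{f"prop_{s}": b.proportions.get(s, np.nan)
                   for s in STRATEGIES},
            })
    return pd.DataFrame(rows)


def bias_count_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Participant counts of stay / shift / no bias by value condition and
    previous outcome (the published summary layout for unexploitable
    blocks).  A ``both`` label counts under shift bias."""
    rows = []
    for (value, outcome), g in profiles.groupby(
            ["value_condition", "previous_outcome"], sort=False):
        rows.append({
            "value_condition": value,
            "previous_outcome": outcome,
            "stay_bias": int((g["label"] == "stay_bias").sum()),
            "shift_bias": int(g["label"].isin(["shift_bias", "both"]).sum()),
            "no_bias": int((g["label"] == "none").sum()),
            "indeterminate": int((g["label"] == "indeterminate").sum()),
        })
    return pd.DataFrame(rows)


def proportion_test_p(k: int, n: int, p0: float = NULL_PROPORTION,
                      method: str = "normal_cc") -> float:
    """One-tailed (greater) one-sample proportion test p-value.

    ``normal_cc`` is the continuity-corrected normal approximation (the
    classic textbook "proportions test"); ``exact`` is the binomial
    upper tail.  For win counts out of 90 at alpha .05 both variants
    first reject at 38 wins.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if method == "exact":
        return exact_binomial_p(k, n, p0, sided="one_greater")
    if method == "normal_cc":
        z = (k - n * p0 - 0.5) / np.sqrt(n * p0 * (1 - p0))
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown proportion test method {method!r}")


def classify_success(wins: int, n_trials: int = 90, alpha: float = 0.05,
                     method: str = "normal_cc") -> bool:
    """True when the block's win rate is significantly above 1/3."""
    return proportion_test_p(wins, n_trials, method=method) < alpha


def success_labels(dataset: Dataset, alpha: float = 0.05,
                   method: str = "normal_cc") -> pd.DataFrame:
    """Per-participant success over the two exploitable blocks.

    ``successful_both`` (above chance in both), ``failed_one``,
    ``failed_both``; block-level detail in the per-block columns.
    """
    rows = []
    exploitable = dataset.df[dataset.df["opponent_type"] == "exploitable"]
    for pid, g in exploitable.groupby("participant_id", sort=True):
        blocks = {}
        for value, gb in g.groupby("value_condition"):
            wins = int((gb["outcome"] == "win").sum())
            blocks[value] = classify_success(wins, len(gb), alpha, method)
        n_pass = sum(blocks.values())
        label = {2: "successful_both", 1: "failed_one", 0: "failed_both"}[n_pass]
        rows.append({
            "participant_id": pid, "label": label,
            "above_chance_low": blocks.get("low"),
            "above_chance_high": blocks.get("high"),
        })
    return pd.DataFrame(rows)


def success_split(labels: pd.DataFrame) -> dict[str, int]:
    """Counts of the three participant success categories."""
    return {cat: int((labels["label"] == cat).sum())
            for cat in ("successful_both", "failed_one", "failed_both")}
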