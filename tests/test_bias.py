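"""Exact binomial machinery, bias classification and the success split."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpskit.bias import (classify_bias, classify_success, exact_binomial_p,
                         proportion_test_p, success_labels, success_split)
from rpskit.game import OUTCOMES, STRATEGIES
from rpskit.io import Dataset
from rpskit.sequential import ConditionalTable, conditional_strategy_table

from conftest import make_block_frame


def brute_force_two_sided(k: int, n: int, p0: float) -> float:
    """Independent oracle: direct minimum-likelihood pmf summation."""
    pmf = [comb(n, i) * p0 ** i * (1 - p0) ** (n - i) for i in range(n + 1)]
    threshold = pmf[k] * (1 + 1e-10)  # tolerate float ties
    return min(1.0, sum(p for p in pmf if p <= threshold))


def test_frozen_oracle_value():
    # 20/30 against 1/3, two-sided minimum-likelihood, enumerated by hand
    assert exact_binomial_p(20, 30, 1 / 3) == pytest.approx(
        0.00027720082218384847, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=80)
@given(n=st.integers(1, 200), frac=st.floats(0, 1),
       p0=st.sampled_from([1 / 3, 0.25, 0.5]))
def test_two_sided_matches_enumeration(n, frac, p0):
    k = round(frac * n)
    assert exact_binomial_p(k, n, p0) == pytest.approx(
        brute_force_two_sided(k, n, p0), rel=1e-9, abs=1e-12)


def test_one_sided_closed_forms():
    assert exact_binomial_p(5, 5, 1 / 3, sided="one_greater") == \
        pytest.approx((1 / 3) ** 5, rel=1e-12)
    # observed exactly at the mode: two-sided p = 1
    assert exact_binomial_p(10, 30, 1 / 3) == pytest.approx(1.0)


def test_one_sided_monotone_in_k():
    ps = [exact_binomial_p(k, 60, 1 / 3, sided="one_greater")
          for k in range(61)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_doubling_variant_selectable():
    p_min = exact_binomial_p(20, 30, 1 / 3, method="min-likelihood")
    p_dbl = exact_binomial_p(20, 30, 1 / 3, method="doubling")
    assert p_dbl >= p_min  # doubling is never smaller here
    assert p_dbl == pytest.approx(
        2 * sum(comb(30, i) * (1 / 3) ** i * (2 / 3) ** (30 - i)
                for i in range(20, 31)), rel=1e-9)


def _table(counts: dict[str, list[int]]) -> ConditionalTable:
    frame = pd.DataFrame(counts, index=list(STRATEGIES)).T
    frame.columns = list(STRATEGIES)
    frame.index.name = "previous_outcome"
    frame = frame.reindex(OUTCOMES, fill_value=0)
    return ConditionalTable(frame, frame.sum(axis=1))


class TestBiasClassification:
    def test_pure_stay_after_losses(self):
        profile = classify_bias(_table({"lose": [29, 0, 0]}))
        assert profile.by_outcome["lose"].label == "stay_bias"
        # outcomes never experienced are indeterminate, not 'none'
        assert profile.by_outcome["win"].label == "indeterminate"

    def test_uniform_table_has_no_bias(self):
        profile = classify_bias(_table(
            {o: [10, 10, 10] for o in OUTCOMES}))
        assert all(b.label == "none" for b in profile.by_outcome.values())
        assert profile.unbiased

    def test_upgrade_or_downgrade_collapse_to_shift(self):
        up = classify_bias(_table({"win": [0, 28, 2], "lose": [10, 10, 10],
                                   "draw": [2, 0, 28]}))
        assert up.by_outcome["win"].label == "shift_bias"
        assert up.by_outcome["draw"].label == "shift_bias"

    def test_low_rate_is_not_a_bias(self):
        # stay significantly *below* 1/3 is not a stay bias, and neither
        # complementary strategy is individually significant here
        profile = classify_bias(_table({"win": [2, 14, 13]}))
        assert profile.by_outcome["win"].p_values["stay"] < 0.05
        assert profile.by_outcome["win"].label == "none"


def test_planted_bias_detection_matches_enumerated_power():
    """Detection frequency of a planted pi(lose->upgrade)=0.8 over many
    30-transition samples matches the exact binomial power."""
    n, p_true, alpha = 30, 0.8, 0.05
    power = sum(comb(n, k) * p_true ** k * (1 - p_true) ** (n - k)
                for k in range(n + 1)
                if exact_binomial_p(k, n, 1 / 3) < alpha and k / n > 1 / 3)
    rng = np.random.default_rng(77)
    reps = 2000
    detected = 0
    for k in rng.binomial(n, p_true, reps):
        profile = classify_bias(_table({"lose": [n - int(k), int(k), 0]}))
        detected += profile.by_outcome["lose"].label in ("shift_bias", "both")
    se = np.sqrt(power * (1 - power) / reps)
    assert abs(detected / reps - power) < 4 * se + 1e-9


class TestSuccess:
    def test_null_expectation_not_above_chance(self):
        assert not classify_success(30, 90)
        assert proportion_test_p(30, 90) > 0.5

    def test_perfect_block_above_chance(self):
        assert classify_success(90, 90)
        assert classify_success(90, 90, method="exact")

    @pytest.mark.parametrize("method", ["normal_cc", "exact"])
    def test_first_rejecting_win_count_is_38(self, method):
        # scan frozen before implementation: both variants reject first at 38
        ks = [k for k in range(30, 91)
              if proportion_test_p(k, 90, method=method) < 0.05]
        assert min(ks) == 38

    def test_labels_aggregate_over_two_blocks(self):
        # participant with one winning and one chance-level exploitable block
        frames = []
        win_block = make_block_frame(
            ["paper"] * 90, ["rock"] * 90, opponent_type="exploitable",
            value_condition="low", block_index=1)
        null_block = make_block_frame(
            ["rock"] * 90, ["rock"] * 90, opponent_type="exploitable",
            value_condition="high", block_index=2)
        ds = Dataset(pd.concat([win_block, null_block], ignore_index=True))
        labels = success_labels(ds)
        assert labels.iloc[0]["label"] == "failed_one"
        assert success_split(labels) == {
            "successful_both": 0, "failed_one": 1, "failed_both": 0}


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        exact_binomial_p(-1, 10)
    with pytest.raises(ValueError):
        exact_binomial_p(11, 10)
    with pytest.raises(ValueError):
        exact_binomial_p(3, 10, p0=1.0)
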