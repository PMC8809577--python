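"""Published reference values from the original two experiments, used by
the reproduction harness to compare a recomputed analysis against the
printed group statistics.

Tolerance conventions: integer counts must match exactly; values printed
as percentages to one decimal are compared within 0.1 percentage points;
proportions printed to two or three decimals within 0.005.
"""

from __future__ import annotations

import pandas as pd

#: group outcome proportions in the exploitable condition (win, lose, draw)
OUTCOME_PROPORTIONS_EXPLOITABLE = {
    1: {"win": 0.494, "lose": 0.236, "draw": 0.270},
    2: {"win": 0.4735, "lose": 0.2642, "draw": 0.2624},
}

#: participant success split over the two exploitable blocks
SUCCESS_SPLIT = {
    1: {"successful_both": 17, "failed_one": 15, "failed_both": 8},
    2: {"successful_both": 18, "failed_one": 12, "failed_both": 10},
}

#: bias-classification counts in the unexploitable blocks
#: (value condition, previous outcome) -> (stay, shift, none)
BIAS_COUNTS = {
    1: {("low", "win"): (6, 13, 21), ("low", "lose"): (8, 11, 21),
        ("low", "draw"): (7, 4, 29), ("high", "win"): (5, 16, 19),
        ("high", "lose"): (7, 4, 29), ("high", "draw"): (9, 7, 24)},
    2: {("low", "win"): (9, 10, 21), ("low", "lose"): (10, 11, 19),
        ("low", "draw"): (13, 8, 19), ("high", "win"): (9, 15, 16),
        ("high", "lose"): (9, 9, 22), ("high", "draw"): (6, 2, 32)},
}

#: participants with no bias after any outcome, per value condition
N_UNBIASED = {1: {"low": 9, "high": 11}, 2: {"low": 7, "high": 9}}

#: cross-experiment estimated marginal means of optimal-response rates (%)
CROSS_EXPERIMENT_EMM = {"win": 60.3, "draw": 50.2, "lose": 42.8}


def compare_experiment(results: dict, experiment: int) -> pd.DataFrame:
    """Tabulate computed vs reference values for one experiment's analysis
    bundle (as produced by :func:`rpskit.pipeline.analyze_experiment`)."""
    rows = []

    def add(name, computed, ref, tol):
        ok = abs(computed - ref) <= tol if pd.notna(computed) else False
        rows.append({"quantity": name, "computed": computed,
                     "reference": ref, "tolerance": tol, "match": ok})

    summary = results["condition_summary"]
    outc = summary[(summary["measure"] == "outcome")
                   & (summary["opponent_type"] == "exploitable")]
    pooled = outc.groupby("level")["mean"].mean()
    for outcome, ref in OUTCOME_PROPORTIONS_EXPLOITABLE[experiment].items():
        add(f"exploitable {outcome} proportion", float(pooled[outcome]),
            ref, 0.005)

    for category, ref in SUCCESS_SPLIT[experiment].items():
        add(f"success split {category}",
            results["success_split"][category], ref, 0)

    counts = results["bias_counts"].set_index(
        ["value_condition", "previous_outcome"])
    for (value, outcome), (stay, shift, none) in BIAS_COUNTS[experiment].items():
        row = counts.loc[(value, outcome)]
        add(f"bias {value}/{outcome} stay", int(row["stay_bias"]), stay, 0)
        add(f"bias {value}/{outcome} shift", int(row["shift_bias"]), shift, 0)
        add(f"bias {value}/{outcome} none", int(row["no_bias"]), none, 0)

    for value, ref in N_UNBIASED[experiment].items():
        add(f"unbiased participants ({value})",
            results["n_unbiased"].get(value, float("nan")), ref, 0)
    return pd.DataFrame(rows)
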