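import numpy as np
import pandas as pd
import pytest

from rpskit.io import Dataset
from rpskit.simulate import ExperimentDesign, simulate_experiment


def make_block_frame(player_items, opponent_items, *, participant="P001",
                     experiment=1, block_index=1,
                     opponent_type="unexploitable", value_condition="low"):
    """Hand-built block frame for toy examples."""
    from rpskit.game import score_outcome
    n = len(player_items)
    return pd.DataFrame({
        "participant_id": [participant] * n,
        "experiment": [experiment] * n,
        "block_index": [block_index] * n,
        "opponent_type": [opponent_type] * n,
        "value_condition": [value_condition] * n,
        "trial_index": list(range(1, n + 1)),
        "player_item": list(player_items),
        "opponent_item": list(opponent_items),
        "outcome": [score_outcome(p, o)
                    for p, o in zip(player_items, opponent_items)],
    })


@pytest.fixture
def toy_block():
    """The four-trial worked example: player R,R,P,S vs opponent S,R,R,P
    (outcomes win, draw, win, win)."""
    return make_block_frame(["rock", "rock", "paper", "scissors"],
                            ["scissors", "rock", "rock", "paper"])


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """A small but structurally complete simulated experiment
    (8 participants x 4 blocks x 90 trials)."""
    design = ExperimentDesign(experiment=1, n_participants=8)
    return simulate_experiment(design, master_seed=42)


@pytest.fixture(scope="session")
def small_dataset_exp2() -> Dataset:
    design = ExperimentDesign(experiment=2, n_participants=8)
    return simulate_experiment(design, master_seed=43)
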