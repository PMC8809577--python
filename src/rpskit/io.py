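"""Reading, writing and validating trial-log datasets.

The canonical schema is one CSV row per game round:

====================  =======================================================
column                meaning
====================  =======================================================
``participant_id``    participant identifier (kept as string)
``experiment``        1 or 2 (which opponent rule set was in force)
``block_index``       1-4, position of the block in the session
``opponent_type``     ``unexploitable`` (equal deck) or ``exploitable`` (70%
                      rule-following)
``value_condition``   ``low`` or ``high`` incentive value
``trial_index``       1-based trial number within the block
``player_item``       ``rock`` / ``paper`` / ``scissors``
``opponent_item``     ``rock`` / ``paper`` / ``scissors``
``outcome``           ``win`` / ``lose`` / ``draw`` from the player's side
``opp_rule_trial``    optional 0/1: opponent move produced by its rule
``confidence``        optional 1-5 confidence probe response
====================  =======================================================

Deposited logs from the original experiments use different column names;
a *column map* (canonical name -> file column name) adapts them on read.
Items and outcomes are normalised case-insensitively, the outcome is
recomputed from the items on load, and any mismatch is reported with its
row number.  Unknown columns ride along untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .game import ITEMS, OUTCOMES, score_outcome

CANONICAL_COLUMNS = [
    "participant_id", "experiment", "block_index", "opponent_type",
    "value_condition", "trial_index", "player_item", "opponent_item",
    "outcome", "opp_rule_trial", "confidence",
]
REQUIRED_COLUMNS = CANONICAL_COLUMNS[:9]
OPPONENT_TYPES = ("unexploitable", "exploitable")
VALUE_CONDITIONS = ("low", "high")

_ITEM_ALIASES = {i: i for i in ITEMS} | {i[0]: i for i in ITEMS}
_OUTCOME_ALIASES = {o: o for o in OUTCOMES} | {
    "won": "win", "lost": "lose", "loss": "lose", "tie": "draw", "drew": "draw",
}


@dataclass
class Dataset:
    """A trial log plus provenance metadata."""

    df: pd.DataFrame
    provenance: str = "loaded"  # "simulated" | "loaded"
    source: str | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.provenance == other.provenance and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)

    def blocks(self):
        """Iterate (keys, block frame) per participant x block, in canonical order."""
        for keys, g in self.df.groupby(
                ["participant_id", "block_index"], sort=True):
            yield keys, g.sort_values("trial_index")


@dataclass
class Violation:
    kind: str
    message: str
    participant_id: str | None = None
    block_index: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = ""
        if self.participant_id is not None:
            where = f" [participant {self.participant_id}, block {self.block_index}]"
        return f"{self.kind}: {self.message}{where}"


def _normalise_token(value: str, aliases: dict[str, str], column: str,
                     row: int) -> str:
    token = str(value).strip().lower()
    if token not in aliases:
        raise ValueError(
            f"unparseable {column} value {value!r} at data row {row}")
    return aliases[token]


def read_dataset(path: str | Path, column_map: dict[str, str] | None = None,
                 **read_csv_kwargs) -> Dataset:
    """Read a trial-log CSV into a typed :class:`Dataset`.

    Parameters
    ----------
    column_map
        Mapping from canonical column names to the file's column names,
        for logs not in the canonical schema.  Unmapped canonical names
        are looked up verbatim.
    """
    path = Path(path)
    raw = pd.read_csv(path, **read_csv_kwargs)
    column_map = column_map or {}
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source_name = column_map.get(canonical, canonical)
        if source_name in raw.columns:
            rename[source_name] = canonical
    df = raw.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "outcome"]
    if missing:
        raise ValueError(f"missing mapped column(s): {', '.join(missing)}")

    for col, aliases in (("player_item", _ITEM_ALIASES),
                         ("opponent_item", _ITEM_ALIASES)):
        df[col] = [_normalise_token(v, aliases, col, i)
                   for i, v in enumerate(df[col], start=1)]

    recomputed = [score_outcome(p, o)
                  for p, o in zip(df["player_item"], df["opponent_item"])]
    if "outcome" in df.columns:
        stated = [_normalise_token(v, _OUTCOME_ALIASES, "outcome", i)
                  for i, v in enumerate(df["outcome"], start=1)]
        bad = [i for i, (s, r) in enumerate(zip(stated, recomputed), start=1)
               if s != r]
        if bad:
            shown = ", ".join(map(str, bad[:20]))
            raise ValueError(
                f"outcome column inconsistent with items at data row(s): {shown}"
                + ("..." if len(bad) > 20 else ""))
    df["outcome"] = recomputed

    df["participant_id"] = df["participant_id"].astype(str)
    for col in ("experiment", "block_index", "trial_index"):
        df[col] = df[col].astype(int)
    for col, allowed in (("opponent_type", OPPONENT_TYPES),
                         ("value_condition", VALUE_CONDITIONS)):
        df[col] = df[col].astype(str).str.strip().str.lower()
        bad_vals = set(df[col]) - set(allowed)
        if bad_vals:
            raise ValueError(f"unparseable {col} value(s): {sorted(bad_vals)}")
    if "opp_rule_trial" in df.columns:
        df["opp_rule_trial"] = df["opp_rule_trial"].astype("Int64")
    ordered = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return Dataset(df[ordered + extra], provenance="loaded", source=str(path))


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write in canonical column and row order (deterministic, re-readable)."""
    df = dataset.df
    ordered = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    out = df[ordered + extra].sort_values(
        ["participant_id", "block_index", "trial_index"], kind="mergesort")
    out.to_csv(path, index=False, lineterminator="\n")


def validate_dataset(dataset: Dataset, block_length: int = 90) -> list[Violation]:
    """Structural validation; returns violations instead of raising.

    Checks per participant x block: block length, contiguous 1-based
    trial indices, outcome consistency with the items, exact equal deck
    counts of opponent items in unexploitable blocks, rule-provenance
    consistency when the ``opp_rule_trial`` flag is present; and per
    participant: no two consecutive blocks against the same opponent
    type.
    """
    from .game import apply_strategy  # local to avoid cycle at import time

    violations: list[Violation] = []
    df = dataset.df
    for (pid, block), g in df.groupby(["participant_id", "block_index"], sort=True):
        g = g.sort_values("trial_index")
        if len(g) != block_length:
            violations.append(Violation(
                "block length", f"expected {block_length} trials, found {len(g)}",
                pid, block))
        idx = g["trial_index"].to_numpy()
        if list(idx) != list(range(1, len(g) + 1)):
            violations.append(Violation(
                "trial index", "trial_index not contiguous from 1", pid, block))
        bad = [int(t) for t, p, o, s in zip(
            g["trial_index"], g["player_item"], g["opponent_item"], g["outcome"])
            if score_outcome(p, o) != s]
        if bad:
            violations.append(Violation(
                "outcome", f"outcome inconsistent with items at trial(s) {bad[:10]}",
                pid, block))
        opp_type = g["opponent_type"].iloc[0]
        if g["opponent_type"].nunique() > 1 or g["value_condition"].nunique() > 1:
            violations.append(Violation(
                "condition", "mixed condition labels within a block", pid, block))
        if opp_type == "unexploitable" and len(g) == block_length:
            counts = g["opponent_item"].value_counts()
            expected = block_length // 3
            if any(counts.get(i, 0) != expected for i in ITEMS):
                violations.append(Violation(
                    "deck count",
                    f"opponent item counts {counts.to_dict()} != {expected} each",
                    pid, block))
        if "opp_rule_trial" in g.columns and g["opp_rule_trial"].notna().all():
            opp = list(g["opponent_item"])
            flags = list(g["opp_rule_trial"])
            n_rule = int(sum(flags))
            if flags and flags[0] == 1:
                violations.append(Violation(
                    "rule schedule", "trial 1 flagged as a rule trial", pid, block))
            if opp_type == "exploitable":
                rules_ok = {r for r in ("stay", "upgrade", "downgrade")
                            if all(opp[i] == apply_strategy(opp[i - 1], r)
                                   for i in range(1, len(opp)) if flags[i] == 1)}
                if n_rule and not rules_ok:
                    violations.append(Violation(
                        "rule provenance",
                        "rule-flagged moves follow no single first-order rule",
                        pid, block))
    for pid, g in df.groupby("participant_id", sort=True):
        order = (g.drop_duplicates("block_index")
                  .sort_values("block_index")["opponent_type"].tolist())
        if any(a == b for a, b in zip(order, order[1:])):
            violations.append(Violation(
                "counterbalance",
                f"consecutive blocks share opponent type: {order}", pid, None))
    return violations
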