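"""Run configuration: a single serializable object from which any
simulation or analysis run is reproducible (together with the master
seed it contains)."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    experiment: int = 1
    n_participants: int = 40
    block_length: int = 90
    rule_fraction: float = 0.7
    master_seed: int = 0
    alpha: float = 0.05
    pvalue_method: str = "min-likelihood"   # or "doubling"
    success_method: str = "normal_cc"       # or "exact"
    quartile_method: str = "linear"
    column_map: dict[str, str] = field(default_factory=dict)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.block_length % 3:
            raise ValueError("block_length must be divisible by 3")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, stamped into every output."""
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
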