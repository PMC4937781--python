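"""Run configuration: every tunable threshold in one place.

Defaults are the fixed protocol values: 9 A contact cutoff, -15.00
baseline well depth doubled on beta-confirmed contacts, strand
pairings of fewer than 3 contacts discarded, 62% identity clustering
for Neff, and the MR success gate (CC >= 25.00, ACL >= 10.00,
Rfree <= 0.45).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    distance_cutoff: float = 9.0          # A
    base_well_depth: float = -15.0        # energy units, <= 0
    upweight_multiplier: float = 2.0
    min_group_size: int = 3
    identity_threshold: float = 0.62
    cc_threshold: float = 25.0
    acl_threshold: float = 10.0
    rfree_threshold: float = 0.45
    min_separation: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if self.base_well_depth > 0:
            raise ValueError("well depth must be <= 0")
        if self.min_group_size < 1:
            raise ValueError("min group size must be >= 1")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity threshold must be in (0, 1]")
        if not 0.0 <= self.rfree_threshold <= 1.0:
            raise ValueError("Rfree threshold must be in [0, 1]")
        if self.min_separation < 0:
            raise ValueError("minimum separation must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)
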