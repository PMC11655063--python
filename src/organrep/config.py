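"""Analysis configuration with YAML/JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError


def default_alpha_grid() -> tuple:
    """alpha in [0, 10] at step 0.2, including the Shannon point alpha = 1."""
    return tuple(np.round(np.arange(0.0, 10.0 + 1e-9, 0.2), 10))


@dataclass
class AnalysisConfig:
    """Tunable parameters of the repertoire analysis.

    clone_identity
        CDRH3 identity fraction required for two reads to share a clone
        (1.0 = exact match, the clone definition).
    clonotype_identity
        CDRH3 identity threshold for single-linkage clonotype clustering
        (default 0.90; linkage requires identity strictly greater than this
        unless ``inclusive_identity`` is set).
    alpha_grid
        Orders alpha at which Hill diversity/evenness profiles are evaluated.
    sp_replicates / sp_tip_change_ratio_cap
        Permutation replicates and the tip-to-change down-sampling cap of the
        switch-proportion migration test.
    clone_key_mode
        'heavy' keys clones on (V, J, CDRH3); 'paired' additionally uses CDRL3.
    """

    clone_identity: float = 1.0
    clonotype_identity: float = 0.90
    inclusive_identity: bool = False
    alpha_grid: tuple = field(default_factory=default_alpha_grid)
    sp_replicates: int = 1000
    sp_tip_change_ratio_cap: float = 20.0
    seed: Optional[int] = None
    clone_key_mode: str = "heavy"
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("clone_identity", "clonotype_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        grid = tuple(float(a) for a in self.alpha_grid)
        if any(a < 0 for a in grid):
            raise ConfigurationError("alpha grid values must be >= 0")
        if list(grid) != sorted(grid):
            raise ConfigurationError("alpha grid must be sorted ascending")
        self.alpha_grid = grid
        if self.sp_replicates < 1:
            raise ConfigurationError("sp_replicates must be a positive integer")
        if self.sp_tip_change_ratio_cap <= 0:
            raise ConfigurationError("sp_tip_change_ratio_cap must be positive")
        if self.clone_key_mode not in ("heavy", "paired"):
            raise ConfigurationError(
                f"clone_key_mode must be 'heavy' or 'paired', got {self.clone_key_mode!r}"
            )

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = asdict(self)
        data["alpha_grid"] = list(data["alpha_grid"])
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
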