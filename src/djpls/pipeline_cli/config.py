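"""Run configuration: the printed analysis constants in one round-trippable place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their published defaults."""

    filter_cutoff_hz: float = 20.0
    auto_residual: bool = False
    filter_forces: bool = True
    force_threshold_n: float = 20.0
    aggregation: str = "mean"          # or "best"
    cv_folds: int = 10
    cv_seed: int = 0
    max_components: int = 10
    corr_threshold: float = 0.95
    vif_threshold: float = 10.0
    vip_threshold: float = 1.0
    leak_free_cv: bool = True          # False = filters applied once, globally
    include_other_outcomes: bool = False
    rfd_mode: str = "time_to_peak"
    weight_kind: str = "x_weight"

    def __post_init__(self) -> None:
        for name in ("filter_cutoff_hz", "force_threshold_n", "corr_threshold",
                     "vif_threshold", "vip_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.aggregation not in ("mean", "best"):
            raise ValueError("aggregation must be 'mean' or 'best'")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
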