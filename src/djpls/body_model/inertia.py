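"""Segment inertial parameters: the bundled anthropometric table.

The default table (``djpls/data/segment_inertia.yaml``) is a standard adult
male scaling table; it is a config-replaceable asset — any YAML file with
the same schema can be substituted via :func:`load_segment_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["SegmentParams", "SegmentModel", "load_segment_model", "SEGMENT_NAMES"]

_BILATERAL = ("upper_arm", "forearm", "hand", "thigh", "shank", "foot")
_AXIAL = ("head", "trunk", "pelvis")

#: the 15 segments of the model
SEGMENT_NAMES = tuple(_AXIAL) + tuple(
    f"{seg}_{side}" for seg in _BILATERAL for side in ("left", "right")
)


@dataclass(frozen=True)
class SegmentParams:
    """Scaling coefficients for one segment type."""

    mass_fraction: float
    com_ratio: float | None = None
    r_gyr_transverse: float | None = None
    r_gyr_longitudinal: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mass_fraction < 1:
            raise ValueError("mass_fraction must lie in (0, 1)")
        for name in ("com_ratio", "r_gyr_transverse", "r_gyr_longitudinal"):
            v = getattr(self, name)
            if v is not None and not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class SegmentModel:
    """Inertial parameters of the 15-segment model plus COM placement assets."""

    params: dict[str, SegmentParams]
    hat_offsets: dict[str, np.ndarray]
    pelvis_com_offset: np.ndarray

    def __post_init__(self) -> None:
        total = self.total_mass_fraction()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, expected 1")

    def total_mass_fraction(self) -> float:
        total = 0.0
        for seg, p in self.params.items():
            total += p.mass_fraction * (2 if seg in _BILATERAL else 1)
        return total

    def mass(self, segment: str, body_mass_kg: float) -> float:
        """Mass in kg of one instance of ``segment`` (per side if bilateral)."""
        return self.params[segment].mass_fraction * body_mass_kg

    def inertia_local(
        self, segment: str, body_mass_kg: float, length_m: float
    ) -> np.ndarray:
        """Principal inertia tensor (kg m^2) in the segment frame.

        The segment longitudinal axis is the local z axis.
        """
        p = self.params[segment]
        if p.r_gyr_transverse is None or p.r_gyr_longitudinal is None:
            raise ValueError(f"no gyration radii for segment {segment!r}")
        m = p.mass_fraction * body_mass_kg
        it = m * (p.r_gyr_transverse * length_m) ** 2
        il = m * (p.r_gyr_longitudinal * length_m) ** 2
        return np.diag([it, it, il])


def load_segment_model(path: str | Path | None = None) -> SegmentModel:
    """Load a :class:`SegmentModel` from YAML (bundled table by default)."""
    if path is None:
        src = resources.files("djpls").joinpath("data/segment_inertia.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    params = {
        name: SegmentParams(
            mass_fraction=entry["mass_fraction"],
            com_ratio=entry.get("com_ratio"),
            r_gyr_transverse=entry.get("r_gyr_transverse"),
            r_gyr_longitudinal=entry.get("r_gyr_longitudinal"),
        )
        for name, entry in raw["segments"].items()
    }
    hat = {k: np.asarray(v, dtype=float) for k, v in raw["hat_offsets"].items()}
    pelvis_off = np.asarray(raw["pelvis_com_offset"], dtype=float)
    return SegmentModel(params=params, hat_offsets=hat, pelvis_com_offset=pelvis_off)
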