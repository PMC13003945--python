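"""Whole-body centre of mass from the 15-segment model."""

from __future__ import annotations

import numpy as np

from .inertia import SegmentModel
from .kinematics import BodyKinematics, reconstruct_kinematics

__all__ = ["whole_body_com", "segment_com_positions"]


def _along(prox: np.ndarray, dist: np.ndarray, ratio: float) -> np.ndarray:
    return prox + ratio * (dist - prox)


def segment_com_positions(
    kin: BodyKinematics, model: SegmentModel, markers: dict
) -> dict[str, np.ndarray]:
    """Per-segment COM positions (m), keyed by the 15 segment names."""
    p = model.params
    out: dict[str, np.ndarray] = {}

    for side in ("left", "right"):
        out[f"thigh_{side}"] = _along(
            kin.hip[side], kin.knee[side], p["thigh"].com_ratio
        )
        out[f"shank_{side}"] = _along(
            kin.knee[side], kin.ankle[side], p["shank"].com_ratio
        )
        out[f"foot_{side}"] = _along(
            kin.heel[side], kin.toe[side], p["foot"].com_ratio
        )

    d_asis = np.linalg.norm(
        np.asarray(markers["LASI"]) - np.asarray(markers["RASI"]), axis=-1
    )[..., None]
    out["pelvis"] = kin.mid_hip + np.einsum(
        "...ij,...j->...i", kin.pelvis_R, model.pelvis_com_offset * d_asis
    )

    out["trunk"] = _along(kin.trunk_upper, kin.trunk_lower, p["trunk"].com_ratio)

    trunk_len = np.linalg.norm(kin.trunk_upper - kin.trunk_lower, axis=-1)[..., None]
    for seg in ("head", "upper_arm", "forearm", "hand"):
        off = model.hat_offsets[seg]
        if seg == "head":
            local = off * trunk_len
            out["head"] = kin.trunk_upper + np.einsum(
                "...ij,...j->...i", kin.trunk_R, local
            )
        else:
            for side, sign in (("left", -1.0), ("right", 1.0)):
                local = off * np.array([1.0, sign, 1.0]) * trunk_len
                out[f"{seg}_{side}"] = kin.trunk_upper + np.einsum(
                    "...ij,...j->...i", kin.trunk_R, local
                )
    return out


def whole_body_com(markers: dict, model: SegmentModel) -> np.ndarray:
    """Mass-fraction-weighted whole-body COM trajectory, shape (n, 3).

    Parameters
    ----------
    markers : dict of marker name -> ndarray (n, 3)
    model : SegmentModel
    """
    kin = reconstruct_kinematics(markers)
    coms = segment_com_positions(kin, model, markers)
    total = np.zeros_like(next(iter(coms.values())))
    for seg, pos in coms.items():
        base = seg.rsplit("_", 1)[0] if seg.endswith(("_left", "_right")) else seg
        total = total + model.params[base].mass_fraction * pos
    return total
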