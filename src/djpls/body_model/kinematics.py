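"""Marker-based reconstruction of joint centres and segment frames.

The reduced marker set (22 markers) is sufficient to define the pelvis,
trunk and all lower-limb segment coordinate systems; upper-body segments
ride rigidly on the trunk frame (participants keep their hands on their
hips).  Lab frame: x forward, y left, z up; all frames are right-handed
with columns [x_hat, y_hat, z_hat].

Conventions (documented, swappable by replacing the functions here):

* hip joint centre — predictive offsets from the mid-ASIS point expressed
  as fractions of the inter-ASIS distance (posterior, lateral, distal);
* knee joint centre — midpoint of the femoral epicondyle markers;
* ankle joint centre — midpoint of the malleolar markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MARKER_NAMES",
    "BELL_RATIOS",
    "BodyKinematics",
    "reconstruct_kinematics",
    "hip_joint_centre",
]

#: full marker vocabulary (L/R prefixes for bilateral markers)
MARKER_NAMES = (
    "LASI", "RASI", "LPSI", "RPSI",          # pelvis
    "C7", "SJN", "T10", "XIPH",              # trunk
    "LMEP", "LLEP", "RMEP", "RLEP",          # femoral epicondyles
    "LMM", "LLM", "RMM", "RLM",              # malleoli
    "LHEE", "LTOE", "LMT5", "RHEE", "RTOE", "RMT5",  # feet
)

#: predictive hip-centre offsets as fractions of inter-ASIS distance
#: (x posterior, y lateral, z distal) in the pelvis frame
BELL_RATIOS = (-0.19, 0.36, -0.30)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("degenerate marker geometry (zero-length axis)")
    return v / n


def _orthogonalize(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return _unit(v - np.sum(v * axis, axis=-1, keepdims=True) * axis)


def _stack_frame(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    return np.stack([x, y, z], axis=-1)


def _check_markers(markers: dict, names) -> None:
    missing = [n for n in names if n not in markers]
    if missing:
        raise KeyError(f"missing markers: {missing}")
    bad: list[str] = []
    for n in names:
        arr = np.asarray(markers[n])
        if not np.all(np.isfinite(arr)):
            frames = np.unique(np.nonzero(~np.isfinite(arr))[0])
            bad.append(f"{n} (frames {frames.tolist()[:10]})")
    if bad:
        raise ValueError(f"non-finite marker data: {bad}")


def pelvis_frame(markers: dict) -> tuple[np.ndarray, np.ndarray]:
    """Pelvis origin (mid-ASIS) and frame from the four pelvis markers."""
    lasi, rasi = np.asarray(markers["LASI"]), np.asarray(markers["RASI"])
    lpsi, rpsi = np.asarray(markers["LPSI"]), np.asarray(markers["RPSI"])
    origin = 0.5 * (lasi + rasi)
    y = _unit(lasi - rasi)
    fwd = origin - 0.5 * (lpsi + rpsi)
    x = _orthogonalize(fwd, y)
    z = np.cross(x, y)
    return origin, _stack_frame(x, y, z)


def hip_joint_centre(markers: dict, side: str) -> np.ndarray:
    """Predict the hip joint centre from the pelvis markers."""
    origin, R = pelvis_frame(markers)
    d = np.linalg.norm(
        np.asarray(markers["LASI"]) - np.asarray(markers["RASI"]), axis=-1
    )[..., None]
    bx, by, bz = BELL_RATIOS
    sign = 1.0 if side == "left" else -1.0
    local = np.concatenate([bx * d, sign * by * d, bz * d], axis=-1)
    return origin + np.einsum("...ij,...j->...i", R, local)


def _long_frame(
    prox: np.ndarray, dist: np.ndarray, med: np.ndarray, lat: np.ndarray, side: str
) -> np.ndarray:
    """Frame of a long segment: z proximal, y toward body midline (left lab y)."""
    z = _unit(prox - dist)
    y_raw = (med - lat) if side == "right" else (lat - med)
    y = _orthogonalize(y_raw, z)
    x = np.cross(y, z)
    return _stack_frame(x, y, z)


def foot_frame(
    hee: np.ndarray, toe: np.ndarray, mt5: np.ndarray, side: str
) -> np.ndarray:
    x = _unit(toe - hee)
    if side == "right":
        normal = np.cross(mt5 - hee, toe - hee)
    else:
        normal = np.cross(toe - hee, mt5 - hee)
    z = _orthogonalize(normal, x)
    y = np.cross(z, x)
    return _stack_frame(x, y, z)


def trunk_frame(markers: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper origin, lower point and frame of the trunk segment."""
    c7, sjn = np.asarray(markers["C7"]), np.asarray(markers["SJN"])
    t10, xiph = np.asarray(markers["T10"]), np.asarray(markers["XIPH"])
    upper = 0.5 * (c7 + sjn)
    lower = 0.5 * (t10 + xiph)
    z = _unit(upper - lower)
    x = _orthogonalize(sjn - c7, z)
    y = np.cross(z, x)
    return upper, lower, _stack_frame(x, y, z)


@dataclass
class BodyKinematics:
    """Joint centres and segment frames reconstructed from markers.

    All point arrays have shape (n, 3); frames have shape (n, 3, 3).
    Bilateral entries are dicts keyed by "left"/"right".
    """

    pelvis_origin: np.ndarray
    pelvis_R: np.ndarray
    trunk_upper: np.ndarray
    trunk_lower: np.ndarray
    trunk_R: np.ndarray
    hip: dict[str, np.ndarray]
    knee: dict[str, np.ndarray]
    ankle: dict[str, np.ndarray]
    thigh_R: dict[str, np.ndarray]
    shank_R: dict[str, np.ndarray]
    foot_R: dict[str, np.ndarray]
    heel: dict[str, np.ndarray]
    toe: dict[str, np.ndarray]

    @property
    def mid_hip(self) -> np.ndarray:
        return 0.5 * (self.hip["left"] + self.hip["right"])

    @property
    def inter_asis(self) -> np.ndarray:
        # reconstructed lazily where needed; kept for API symmetry
        raise AttributeError("use marker distance directly")


def reconstruct_kinematics(markers: dict) -> BodyKinematics:
    """Build all joint centres and segment frames from a labeled marker dict.

    Parameters
    ----------
    markers : dict of marker name -> ndarray (n, 3)

    Raises
    ------
    KeyError
        If a required marker is absent.
    ValueError
        If marker data contain non-finite frames (listing them).
    """
    _check_markers(markers, MARKER_NAMES)
    m = {k: np.asarray(v, dtype=float) for k, v in markers.items()}

    pel_o, pel_R = pelvis_frame(m)
    trk_u, trk_l, trk_R = trunk_frame(m)

    hip, knee, ankle = {}, {}, {}
    thigh_R, shank_R, foot_R = {}, {}, {}
    heel, toe = {}, {}
    for side, p in (("left", "L"), ("right", "R")):
        hjc = hip_joint_centre(m, side)
        kjc = 0.5 * (m[f"{p}MEP"] + m[f"{p}LEP"])
        ajc = 0.5 * (m[f"{p}MM"] + m[f"{p}LM"])
        hip[side], knee[side], ankle[side] = hjc, kjc, ajc
        thigh_R[side] = _long_frame(hjc, kjc, m[f"{p}MEP"], m[f"{p}LEP"], side)
        shank_R[side] = _long_frame(kjc, ajc, m[f"{p}MM"], m[f"{p}LM"], side)
        foot_R[side] = foot_frame(m[f"{p}HEE"], m[f"{p}TOE"], m[f"{p}MT5"], side)
        heel[side], toe[side] = m[f"{p}HEE"], m[f"{p}TOE"]

    return BodyKinematics(
        pelvis_origin=pel_o,
        pelvis_R=pel_R,
        trunk_upper=trk_u,
        trunk_lower=trk_l,
        trunk_R=trk_R,
        hip=hip,
        knee=knee,
        ankle=ankle,
        thigh_R=thigh_R,
        shank_R=shank_R,
        foot_R=foot_R,
        heel=heel,
        toe=toe,
    )
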