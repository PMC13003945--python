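"""Cardan (Tait-Bryan) joint angles and ranges of motion.

Joint angles are the Cardan decomposition of the distal segment frame
relative to the proximal one.  Per-joint rotation orders follow the usual
lower-limb convention: the first axis carries flexion/extension, the
second the frontal-plane angle (abduction/adduction or valgus/varus or
inversion/eversion), the third axial rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JOINT_SEQUENCES",
    "cardan_angles",
    "cardan_matrix",
    "relative_rotation",
    "JointAngleSeries",
    "joint_angle_series",
    "range_of_motion",
    "GimbalWarning",
]

_AXES = {"x": 0, "y": 1, "z": 2}
_CYCLIC = ("xyz", "yzx", "zxy")

#: per-joint Cardan orders; with the lab convention (x forward, y left,
#: z up) the first rotation (about y) carries flexion/extension, the
#: second (about x) the frontal-plane angle, the third (about z) axial
#: rotation
JOINT_SEQUENCES = {"hip": "yxz", "knee": "yxz", "ankle": "yxz"}

#: labels of the three rotations per joint, matching the reporting
#: nomenclature of the feature table
JOINT_AXIS_LABELS = {
    "hip": ("Ext/Flex", "Abd/Add", "Ext/Int rotation"),
    "knee": ("Ext/Flex", "Valgus/Varus", "Ext/Int rotation"),
    "ankle": ("Pla/Dor flexion", "Eve/Inv", "Abd/Add"),
}


class GimbalWarning(RuntimeWarning):
    """Middle Cardan angle close to +/-90 degrees."""


def _axis_rotation(axis: str, angle_rad: np.ndarray) -> np.ndarray:
    a = np.asarray(angle_rad, dtype=float)
    c, s = np.cos(a), np.sin(a)
    shape = a.shape + (3, 3)
    R = np.zeros(shape)
    i = _AXES[axis]
    j, k = (i + 1) % 3, (i + 2) % 3
    R[..., i, i] = 1.0
    R[..., j, j] = c
    R[..., k, k] = c
    R[..., j, k] = -s
    R[..., k, j] = s
    return R


def cardan_matrix(angles_deg, sequence: str = "xyz") -> np.ndarray:
    """Compose a rotation matrix from three ordered Cardan angles (degrees).

    Rotations are intrinsic: R = R_axis1(a1) @ R_axis2(a2) @ R_axis3(a3).
    """
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if angles.shape[-1] != 3:
        raise ValueError("expected three angles")
    R = _axis_rotation(sequence[0], angles[..., 0])
    R = R @ _axis_rotation(sequence[1], angles[..., 1])
    R = R @ _axis_rotation(sequence[2], angles[..., 2])
    return R


def relative_rotation(R_prox: np.ndarray, R_dist: np.ndarray) -> np.ndarray:
    """Rotation of the distal frame expressed in the proximal frame."""
    return np.einsum("...ji,...jk->...ik", R_prox, R_dist)


def _validate_rotation(R: np.ndarray) -> None:
    eye = np.eye(3)
    err = np.max(np.abs(np.einsum("...ji,...jk->...ik", R, R) - eye))
    if err > 1e-6:
        raise ValueError(f"frame not orthonormal (max |R^T R - I| = {err:.2e})")
    det = np.linalg.det(R)
    if np.any(det < 0):
        raise ValueError("left-handed frame (det < 0)")


def cardan_angles(
    R: np.ndarray,
    sequence: str = "xyz",
    unwrap: bool = False,
    validate: bool = True,
) -> np.ndarray:
    """Decompose rotation matrices into Cardan angles (degrees).

    Parameters
    ----------
    R : ndarray (..., 3, 3)
        Relative rotation (distal in proximal frame).
    sequence : str
        Three distinct axes out of "xyz", e.g. "xyz" or "zxy".
    unwrap : bool
        Unwrap each angle channel over the leading (time) axis.
    validate : bool
        Check orthonormality and handedness first.

    A :class:`GimbalWarning` is issued when the middle angle comes within
    1 degree of +/-90 degrees anywhere in the series.
    """
    if sorted(sequence) != ["x", "y", "z"]:
        raise ValueError(f"invalid Cardan sequence {sequence!r}")
    R = np.asarray(R, dtype=float)
    if validate:
        _validate_rotation(R)
    i, j, k = (_AXES[c] for c in sequence)
    eps = 1.0 if sequence in _CYCLIC else -1.0
    sin_b = np.clip(eps * R[..., i, k], -1.0, 1.0)
    b = np.arcsin(sin_b)
    a = np.arctan2(-eps * R[..., j, k], R[..., k, k])
    c = np.arctan2(-eps * R[..., i, j], R[..., i, i])
    angles = np.stack([a, b, c], axis=-1)
    if np.any(np.abs(np.abs(b) - np.pi / 2) < np.deg2rad(1.0)):
        warnings.warn(
            "middle Cardan angle within 1 deg of +/-90 deg (gimbal proximity)",
            GimbalWarning,
        )
    if unwrap and angles.ndim > 1:
        angles = np.unwrap(angles, axis=0)
    return np.rad2deg(angles)


@dataclass
class JointAngleSeries:
    """Three Cardan angle channels for one joint over time."""

    joint: str
    side: str
    angles_deg: np.ndarray  # (n, 3)
    rate_hz: float
    t0: float
    sequence: str

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.angles_deg.shape[0]) / self.rate_hz

    def at_time(self, t: float) -> np.ndarray:
        i = int(round((t - self.t0) * self.rate_hz))
        i = min(max(i, 0), self.angles_deg.shape[0] - 1)
        return self.angles_deg[i]


def joint_angle_series(
    R_prox: np.ndarray,
    R_dist: np.ndarray,
    joint: str,
    side: str,
    rate_hz: float,
    t0: float = 0.0,
) -> JointAngleSeries:
    """Cardan angle series of a joint from proximal/distal frame series.

    Left-side frontal and axial channels are sign-flipped so both sides
    report in the same clinical convention (adduction/internal rotation
    share one sign regardless of side).
    """
    seq = JOINT_SEQUENCES[joint]
    rel = relative_rotation(R_prox, R_dist)
    ang = cardan_angles(rel, sequence=seq, unwrap=True)
    if side == "left":
        ang = ang * np.array([1.0, -1.0, -1.0])
    return JointAngleSeries(
        joint=joint, side=side, angles_deg=ang, rate_hz=rate_hz, t0=t0, sequence=seq
    )


def range_of_motion(series: JointAngleSeries, interval: tuple[float, float]) -> np.ndarray:
    """Range of motion (max - min, degrees) per rotation axis within a phase."""
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("empty phase interval")
    t = series.times
    mask = (t >= t0 - 0.5 / series.rate_hz) & (t <= t1 + 0.5 / series.rate_hz)
    if not np.any(mask):
        raise ValueError("phase interval outside the angle series support")
    window = series.angles_deg[mask]
    return window.max(axis=0) - window.min(axis=0)
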