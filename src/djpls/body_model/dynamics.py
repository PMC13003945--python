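"""Bottom-up Newton-Euler inverse dynamics for one lower limb.

Net joint forces and moments are propagated foot -> shank -> thigh using
the measured plate force applied at the centre of pressure.  Joint power
is the dot product of the net joint moment with the relative angular
velocity of the distal segment; per-phase joint work is the trapezoidal
time integral of power.  The plate free moment about the vertical axis is
neglected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inertia import SegmentModel
from .kinematics import BodyKinematics

__all__ = [
    "JointKineticsSeries",
    "angular_velocity",
    "segment_newton_euler",
    "limb_inverse_dynamics",
]

GRAVITY = np.array([0.0, 0.0, -9.81])


def _vee(W: np.ndarray) -> np.ndarray:
    return np.stack([W[..., 2, 1], W[..., 0, 2], W[..., 1, 0]], axis=-1)


def angular_velocity(R: np.ndarray, rate_hz: float) -> np.ndarray:
    """World-frame angular velocity (rad/s) of a frame series (n, 3, 3).

    Central differences of R with skew-symmetrization of R_dot R^T.
    """
    dt = 1.0 / rate_hz
    Rdot = np.gradient(R, dt, axis=0)
    W = np.einsum("nij,nkj->nik", Rdot, R)
    W = 0.5 * (W - np.swapaxes(W, -1, -2))
    return _vee(W)


def segment_newton_euler(
    com: np.ndarray,
    acc: np.ndarray,
    dH: np.ndarray,
    mass: float,
    prox_point: np.ndarray,
    dist_point: np.ndarray | None = None,
    F_dist: np.ndarray | None = None,
    M_dist: np.ndarray | None = None,
    dist_load_point: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Proximal net force and moment on one segment.

    ``F_dist``/``M_dist`` are the force/moment applied *to* this segment at
    its distal end; for the foot they are the plate force at the centre of
    pressure (``dist_load_point``).  Returns ``(F_prox, M_prox)``, the
    load exerted on the segment at the proximal joint.
    """
    zeros = np.zeros_like(com)
    F_dist = zeros if F_dist is None else F_dist
    M_dist = zeros if M_dist is None else M_dist
    load_pt = dist_point if dist_load_point is None else dist_load_point

    F_prox = mass * acc - mass * GRAVITY - F_dist
    M_prox = dH - M_dist - np.cross(prox_point - com, F_prox)
    if load_pt is not None:
        M_prox = M_prox - np.cross(load_pt - com, F_dist)
    return F_prox, M_prox


@dataclass
class JointKineticsSeries:
    """Net joint moments, relative angular velocities and powers for a limb.

    Moments are in N m (not mass-normalized); powers in W.  ``rate_hz``
    and ``t0`` define the common timebase.
    """

    side: str
    rate_hz: float
    t0: float
    moments: dict[str, np.ndarray]      # joint -> (n, 3) N m
    rel_omega: dict[str, np.ndarray]    # joint -> (n, 3) rad/s
    powers: dict[str, np.ndarray]       # joint -> (n,) W

    @property
    def times(self) -> np.ndarray:
        n = next(iter(self.powers.values())).shape[0]
        return self.t0 + np.arange(n) / self.rate_hz

    def work(self, joint: str, interval: tuple[float, float], body_mass: float) -> float:
        """Joint work (J/kg) over a phase: trapezoidal integral of power."""
        t0, t1 = interval
        if t1 <= t0:
            raise ValueError("empty phase interval")
        t = self.times
        mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        if mask.sum() < 2:
            raise ValueError("phase interval outside the kinetics support")
        return float(
            np.trapezoid(self.powers[joint][mask], t[mask]) / body_mass
        )


def _segment_dH(
    R: np.ndarray,
    I_local: np.ndarray,
    rate_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rate of change of angular momentum about the segment COM (world)."""
    omega = angular_velocity(R, rate_hz)
    alpha = np.gradient(omega, 1.0 / rate_hz, axis=0)
    I_world = np.einsum("nij,jk,nlk->nil", R, I_local, R)
    dH = np.einsum("nij,nj->ni", I_world, alpha) + np.cross(
        omega, np.einsum("nij,nj->ni", I_world, omega)
    )
    return dH, omega


def limb_inverse_dynamics(
    kin: BodyKinematics,
    side: str,
    grf: np.ndarray,
    cop: np.ndarray,
    rate_hz: float,
    body_mass: float,
    model: SegmentModel,
    t0: float = 0.0,
    plate_bounds: tuple[float, float, float, float] | None = None,
) -> JointKineticsSeries:
    """Bottom-up inverse dynamics of one limb (foot -> shank -> thigh).

    Parameters
    ----------
    kin : BodyKinematics
        Reconstructed joint centres and frames, already on the force
        timebase.
    side : "left" | "right"
    grf, cop : ndarray (n, 3)
        Plate force (N) under this foot and its centre of pressure (m).
        Force should be zero outside ground contact.
    plate_bounds : optional (xmin, xmax, ymin, ymax)
        If given, CoP samples outside the bounds while loaded raise a
        warning.
    """
    if side not in kin.hip:
        raise ValueError(f"no per-plate force assignment for side {side!r}")
    grf = np.asarray(grf, dtype=float)
    cop = np.asarray(cop, dtype=float)
    n = grf.shape[0]
    if cop.shape != (n, 3) or kin.hip[side].shape[0] != n:
        raise ValueError("kinematics and plate series length mismatch")

    if plate_bounds is not None:
        loaded = np.abs(grf[:, 2]) > 1.0
        xmin, xmax, ymin, ymax = plate_bounds
        outside = loaded & (
            (cop[:, 0] < xmin) | (cop[:, 0] > xmax)
            | (cop[:, 1] < ymin) | (cop[:, 1] > ymax)
        )
        if np.any(outside):
            warnings.warn(
                f"CoP outside plate bounds in {int(outside.sum())} loaded samples",
                RuntimeWarning,
            )

    hjc, kjc, ajc = kin.hip[side], kin.knee[side], kin.ankle[side]
    dt = 1.0 / rate_hz

    def com_acc(com: np.ndarray) -> np.ndarray:
        vel = np.gradient(com, dt, axis=0)
        return np.gradient(vel, dt, axis=0)

    p = model.params
    segments = {
        "foot": dict(
            R=kin.foot_R[side],
            com=kin.heel[side] + p["foot"].com_ratio * (kin.toe[side] - kin.heel[side]),
            length=float(np.mean(np.linalg.norm(kin.toe[side] - kin.heel[side], axis=-1))),
            prox=ajc,
        ),
        "shank": dict(
            R=kin.shank_R[side],
            com=kjc + p["shank"].com_ratio * (ajc - kjc),
            length=float(np.mean(np.linalg.norm(ajc - kjc, axis=-1))),
            prox=kjc,
            dist=ajc,
        ),
        "thigh": dict(
            R=kin.thigh_R[side],
            com=hjc + p["thigh"].com_ratio * (kjc - hjc),
            length=float(np.mean(np.linalg.norm(kjc - hjc, axis=-1))),
            prox=hjc,
            dist=kjc,
        ),
    }

    omegas: dict[str, np.ndarray] = {}
    moments: dict[str, np.ndarray] = {}

    # foot <- plate
    seg = segments["foot"]
    I_loc = model.inertia_local("foot", body_mass, seg["length"])
    dH, omegas["foot"] = _segment_dH(seg["R"], I_loc, rate_hz)
    F_ankle, M_ankle = segment_newton_euler(
        com=seg["com"],
        acc=com_acc(seg["com"]),
        dH=dH,
        mass=model.mass("foot", body_mass),
        prox_point=seg["prox"],
        F_dist=grf,
        dist_load_point=cop,
    )
    moments["ankle"] = M_ankle

    # shank <- ankle reaction
    seg = segments["shank"]
    I_loc = model.inertia_local("shank", body_mass, seg["length"])
    dH, omegas["shank"] = _segment_dH(seg["R"], I_loc, rate_hz)
    F_knee, M_knee = segment_newton_euler(
        com=seg["com"],
        acc=com_acc(seg["com"]),
        dH=dH,
        mass=model.mass("shank", body_mass),
        prox_point=seg["prox"],
        dist_point=seg["dist"],
        F_dist=-F_ankle,
        M_dist=-M_ankle,
    )
    moments["knee"] = M_knee

    # thigh <- knee reaction
    seg = segments["thigh"]
    I_loc = model.inertia_local("thigh", body_mass, seg["length"])
    dH, omegas["thigh"] = _segment_dH(seg["R"], I_loc, rate_hz)
    _, M_hip = segment_newton_euler(
        com=seg["com"],
        acc=com_acc(seg["com"]),
        dH=dH,
        mass=model.mass("thigh", body_mass),
        prox_point=seg["prox"],
        dist_point=seg["dist"],
        F_dist=-F_knee,
        M_dist=-M_knee,
    )
    moments["hip"] = M_hip

    omega_pelvis = angular_velocity(kin.pelvis_R, rate_hz)
    rel_omega = {
        "ankle": omegas["foot"] - omegas["shank"],
        "knee": omegas["shank"] - omegas["thigh"],
        "hip": omegas["thigh"] - omega_pelvis,
    }
    powers = {
        j: np.einsum("ni,ni->n", moments[j], rel_omega[j]) for j in moments
    }
    return JointKineticsSeries(
        side=side,
        rate_hz=rate_hz,
        t0=t0,
        moments=moments,
        rel_omega=rel_omega,
        powers=powers,
    )
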