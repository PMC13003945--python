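"""Dynamically consistent synthetic drop-jump trials.

The vertical COM trajectory is prescribed analytically: ballistic fall
from the box, a half-sine ground-contact acceleration bump sized so the
take-off velocity yields the requested jump height, a ballistic flight,
and a landing arrest.  The plate force is m*(a_com + g) at every sample,
exactly zero in flight.  Joint angles follow smooth prescribed profiles;
marker positions are built from the segment frames those angles define,
then the whole kinematic chain is translated so that the 15-segment model
COM of the markers reproduces the prescribed COM exactly (noise-free
case).  Everything is reproducible bit-exactly under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ..body_model.angles import cardan_matrix, JOINT_SEQUENCES
from ..body_model.com import whole_body_com
from ..body_model.inertia import SegmentModel, load_segment_model
from ..body_model.kinematics import BELL_RATIOS, reconstruct_kinematics

__all__ = [
    "Anthropometry",
    "DropJumpProfile",
    "TrialRecording",
    "TrialTruth",
    "generate_trial",
    "sample_population",
]

G = 9.81


@dataclass(frozen=True)
class Anthropometry:
    height_m: float
    mass_kg: float

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass must be positive")
        if self.height_m <= 0:
            raise ValueError("height must be positive")


#: per joint: (baseline, offset reached at ground contact, contact bump
#: amplitude) for the (flexion, frontal, axial) channels, degrees.
#: Flexion is negative for hip and knee at ground contact, matching the
#: reporting sign convention.
_DEFAULT_ANGLES = {
    "hip": dict(base=(-4.0, -1.0, 1.5), gc=(-21.0, -5.0, 0.5), amp=(-26.0, 5.0, 11.0)),
    "knee": dict(base=(-4.0, 1.5, -3.5), gc=(-16.5, 2.0, -5.5), amp=(-48.7, 6.5, 9.0)),
    "ankle": dict(base=(9.0, 4.5, 1.0), gc=(-8.5, 4.0, 0.3), amp=(45.0, 9.5, 12.0)),
}


@dataclass
class DropJumpProfile:
    """Smooth-motion parameter set for one synthetic drop jump."""

    drop_height_m: float = 0.30
    jump_height_m: float = 0.33
    contact_time_s: float = 0.22
    lead_in_s: float = 0.0
    landing_arrest_s: float = 0.25
    tail_s: float = 0.10
    prep_duration_s: float = 0.15
    marker_rate_hz: float = 250.0
    force_rate_hz: float = 1000.0
    #: per-joint angle profile parameters, see _DEFAULT_ANGLES
    angles: dict = field(default_factory=lambda: {
        j: {k: tuple(v) for k, v in d.items()} for j, d in _DEFAULT_ANGLES.items()
    })
    pelvis_pitch_gc_deg: float = -4.0
    pelvis_pitch_amp_deg: float = -7.0
    trunk_lean_amp_deg: float = -6.0
    cop_start_ratio: float = 0.35
    cop_end_ratio: float = 0.75
    #: second-harmonic coefficient of the contact force shape, in [-0.5, 0.5];
    #: skews the force peak without changing the contact impulse
    force_shape_beta: float = 0.0
    #: per-joint exponent skewing the angle bump peak away from mid-contact
    bump_skew: dict = field(default_factory=lambda: {"hip": 1.0, "knee": 1.0, "ankle": 1.0})

    def validate(self, anthropometry: Anthropometry) -> None:
        if self.drop_height_m <= 0:
            raise ValueError("descent depth must be positive")
        if not 0.05 < self.contact_time_s < 0.6:
            raise ValueError("contact time must lie in (0.05, 0.6) s")
        if self.jump_height_m <= 0:
            raise ValueError("jump height must be positive")
        leg = 0.491 * anthropometry.height_m  # thigh + shank
        if self.drop_height_m >= leg:
            raise ValueError("descent deeper than leg length")
        if abs(self.force_shape_beta) > 0.5:
            raise ValueError("force_shape_beta must lie in [-0.5, 0.5]")


@dataclass
class TrialRecording:
    """Markers at the camera rate plus dual-plate forces at the plate rate."""

    markers: dict[str, np.ndarray]       # name -> (n, 3) m
    marker_rate_hz: float
    plate_forces: dict[str, np.ndarray]  # side -> (m, 3) N
    plate_cops: dict[str, np.ndarray]    # side -> (m, 3) m
    force_rate_hz: float
    anthropometry: Anthropometry
    t0: float = 0.0

    @property
    def fz_total(self) -> np.ndarray:
        return sum(f[:, 2] for f in self.plate_forces.values())


@dataclass
class TrialTruth:
    """Ground truth for every downstream quantity of one synthetic trial."""

    contact_time_s: float
    jump_height_m: float
    rsi: float
    v_takeoff: float
    t_contact: float
    t_com_min: float
    t_takeoff: float
    t_landing: float
    body_mass_kg: float
    com_times: np.ndarray
    com_z: np.ndarray
    com_v: np.ndarray
    com_a: np.ndarray
    fz_total: np.ndarray
    joint_angle_profiles: dict[str, np.ndarray]  # joint -> (n_marker, 3) deg
    rom_truth: dict[str, dict[str, np.ndarray]]  # phase -> joint -> (3,) deg
    angles_at_gc: dict[str, np.ndarray]          # joint -> (3,) deg
    joint_work_truth: dict[str, dict[str, float]] | None = None  # phase -> joint
    ankle_moment_truth: np.ndarray | None = None  # (m, 3) N m, right side

    @property
    def ecc_duration(self) -> float:
        return self.t_com_min - self.t_contact

    @property
    def con_duration(self) -> float:
        return self.t_takeoff - self.t_com_min


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


class _ComProfile:
    """Closed-form vertical COM trajectory and its derivatives."""

    def __init__(self, profile: DropJumpProfile, anthropometry: Anthropometry):
        p = profile
        self.z_stand = 0.575 * anthropometry.height_m
        self.mass = anthropometry.mass_kg
        self.v_c = -np.sqrt(2.0 * G * p.drop_height_m)
        self.v_to = np.sqrt(2.0 * G * p.jump_height_m)
        self.ct = p.contact_time_s
        self.t_fall = -self.v_c / G
        self.t_contact = p.lead_in_s + self.t_fall
        self.t_takeoff = self.t_contact + self.ct
        # contact bump: a + g = A (sin(pi tau) + beta sin(2 pi tau)); the
        # second harmonic integrates to zero over [0, 1], so A is fixed by
        # the impulse-momentum balance alone and beta only skews the peak
        self.beta = p.force_shape_beta
        self.A = np.pi * (self.v_to - self.v_c + G * self.ct) / (2.0 * self.ct)
        self.t_flight = 2.0 * self.v_to / G
        self.t_landing = self.t_takeoff + self.t_flight
        self.t_arrest = p.landing_arrest_s
        self.A_land = np.pi * (self.v_to + G * self.t_arrest) / (2.0 * self.t_arrest)
        self.t_end = self.t_landing + self.t_arrest + p.tail_s
        self.z_box = self.z_stand + p.drop_height_m
        self.z_takeoff = self._contact_z(1.0)
        self.z_landing = self.z_takeoff  # symmetric ballistic flight

    def _contact_shape(self, tau):
        return np.sin(np.pi * tau) + self.beta * np.sin(2.0 * np.pi * tau)

    def _contact_v(self, tau):
        bump = (1.0 - np.cos(np.pi * tau)) / np.pi + self.beta * (
            1.0 - np.cos(2.0 * np.pi * tau)
        ) / (2.0 * np.pi)
        return self.v_c + self.ct * (-G * tau + self.A * bump)

    def _contact_z(self, tau):
        bump = (tau - np.sin(np.pi * tau) / np.pi) / np.pi + self.beta * (
            tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)
        ) / (2.0 * np.pi)
        return (
            self.z_stand
            + self.v_c * self.ct * tau
            + self.ct**2 * (-G * tau**2 / 2.0 + self.A * bump)
        )

    def t_com_min(self) -> float:
        f = lambda tau: self._contact_v(tau)
        # v starts negative and ends positive; bracket the upward crossing
        taus = np.linspace(0.0, 1.0, 2001)
        vals = f(taus)
        idx = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
        tau0 = taus[idx[-1]] if idx.size else 0.5
        root = brentq(f, max(tau0 - 1e-3, 0.0), min(tau0 + 2e-3, 1.0))
        return self.t_contact + root * self.ct

    def evaluate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(z, v, a) at times t, piecewise analytic."""
        t = np.asarray(t, dtype=float)
        z = np.empty_like(t)
        v = np.empty_like(t)
        a = np.empty_like(t)

        lead = t < self.t_contact - self.t_fall
        z[lead], v[lead], a[lead] = self.z_box, 0.0, 0.0

        fall = ~lead & (t < self.t_contact)
        dt = t[fall] - (self.t_contact - self.t_fall)
        z[fall] = self.z_box - G * dt**2 / 2.0
        v[fall] = -G * dt
        a[fall] = -G

        contact = (t >= self.t_contact) & (t < self.t_takeoff)
        tau = (t[contact] - self.t_contact) / self.ct
        z[contact] = self._contact_z(tau)
        v[contact] = self._contact_v(tau)
        a[contact] = -G + self.A * self._contact_shape(tau)

        flight = (t >= self.t_takeoff) & (t < self.t_landing)
        dt = t[flight] - self.t_takeoff
        z[flight] = self.z_takeoff + self.v_to * dt - G * dt**2 / 2.0
        v[flight] = self.v_to - G * dt
        a[flight] = -G

        arrest = (t >= self.t_landing) & (t < self.t_landing + self.t_arrest)
        tl = (t[arrest] - self.t_landing) / self.t_arrest
        z[arrest] = (
            self.z_landing
            - self.v_to * self.t_arrest * tl
            + self.t_arrest**2
            * (-G * tl**2 / 2.0 + self.A_land * (tl - np.sin(np.pi * tl) / np.pi) / np.pi)
        )
        v[arrest] = -self.v_to + self.t_arrest * (
            -G * tl + self.A_land * (1.0 - np.cos(np.pi * tl)) / np.pi
        )
        a[arrest] = -G + self.A_land * np.sin(np.pi * tl)

        rest = t >= self.t_landing + self.t_arrest
        if np.any(rest):
            z_rest = self.evaluate(np.array([self.t_landing + self.t_arrest - 1e-9]))[0][0]
            z[rest], v[rest], a[rest] = z_rest, 0.0, 0.0
        return z, v, a

    def fz(self, t: np.ndarray, z=None, v=None, a=None) -> np.ndarray:
        """Total plate vertical force: m (a + g) while on the plates, else 0."""
        if a is None:
            _, _, a = self.evaluate(t)
        on_ground = ((t >= self.t_contact) & (t < self.t_takeoff)) | (t >= self.t_landing)
        return np.where(on_ground, self.mass * (a + G), 0.0)


def _activation(
    t: np.ndarray, com: _ComProfile, prep_dur: float, skew: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """(prep, bump) activation profiles driving the joint angles.

    ``skew`` < 1 moves the bump peak earlier in contact (the peak sits at
    tau = 0.5 ** (1/skew)).
    """
    prep = _smoothstep((t - (com.t_contact - prep_dur)) / prep_dur)
    # release after take-off, re-engage before landing
    release = _smoothstep((t - com.t_takeoff) / 0.18)
    reland = _smoothstep((t - (com.t_landing - 0.10)) / 0.10)
    prep = np.clip(prep - release + reland, 0.0, 1.0)

    tau = np.clip((t - com.t_contact) / com.ct, 0.0, 1.0)
    bump = np.where(
        (t >= com.t_contact) & (t <= com.t_takeoff),
        np.sin(np.pi * tau ** skew) ** 2,
        0.0,
    )
    tau_l = np.clip((t - com.t_landing) / com.t_arrest, 0.0, 1.0)
    bump_land = np.where(t >= com.t_landing, np.sin(np.pi * np.minimum(tau_l, 0.5)) ** 2, 0.0)
    return prep, bump + 0.8 * bump_land


def _joint_angles(
    t: np.ndarray, profile: DropJumpProfile, com: _ComProfile
) -> dict[str, np.ndarray]:
    """Prescribed clinical joint angles (deg), identical for both sides."""
    out = {}
    for joint, par in profile.angles.items():
        prep, bump = _activation(
            t, com, profile.prep_duration_s, profile.bump_skew.get(joint, 1.0)
        )
        base = np.asarray(par["base"], dtype=float)
        gc = np.asarray(par["gc"], dtype=float)
        amp = np.asarray(par["amp"], dtype=float)
        out[joint] = (
            base[None, :]
            + gc[None, :] * prep[:, None]
            + amp[None, :] * bump[:, None]
        )
    return out


def _geometry(height: float) -> dict[str, float]:
    return dict(
        thigh=0.245 * height,
        shank=0.246 * height,
        foot=0.152 * height,
        ankle_h=0.039 * height,
        hip_half=0.088 * height / 2.0 + 0.04,  # lateral hip offset from midline
        epi_half=0.055,
        mall_half=0.040,
        trunk=0.30 * height,
        trunk_marker_x=0.06,
        psis_back=0.13,
        psis_half=0.05,
        trunk_base=0.05,
    )


def _build_markers(
    t: np.ndarray,
    profile: DropJumpProfile,
    com: _ComProfile,
    anthropometry: Anthropometry,
    model: SegmentModel,
) -> tuple[dict[str, np.ndarray], dict]:
    """Markers (exact, noise-free) such that the model COM matches com(t).

    Also returns true internal kinematics (joint centres, frames) used for
    CoP placement and truth kinetics.
    """
    n = t.shape[0]
    geo = _geometry(anthropometry.height_m)
    angles = _joint_angles(t, profile, com)
    prep, bump = _activation(t, com, profile.prep_duration_s)

    pelvis_pitch = profile.pelvis_pitch_gc_deg * prep + profile.pelvis_pitch_amp_deg * bump
    pelvis_angles = np.stack(
        [pelvis_pitch, np.zeros(n), np.zeros(n)], axis=-1
    )
    R_pelvis = cardan_matrix(pelvis_angles, "yxz")
    trunk_lean = profile.trunk_lean_amp_deg * bump
    R_trunk = R_pelvis @ cardan_matrix(
        np.stack([trunk_lean, np.zeros(n), np.zeros(n)], axis=-1), "yxz"
    )

    def rot(R, vec):
        return np.einsum("nij,j->ni", R, np.asarray(vec, dtype=float))

    # chain with mid-hip at the origin; root translation solved afterwards
    mid_hip = np.zeros((n, 3))
    markers: dict[str, np.ndarray] = {}
    internals: dict = {"R_pelvis": R_pelvis, "R_trunk": R_trunk}

    # pelvis markers placed so the predictive hip-centre equation inverts exactly
    d_asis = geo["hip_half"] / BELL_RATIOS[1]
    bx, _, bz = BELL_RATIOS[0], BELL_RATIOS[1], BELL_RATIOS[2]
    mid_asis = mid_hip - rot(R_pelvis, (bx * d_asis, 0.0, bz * d_asis))
    markers["LASI"] = mid_asis + rot(R_pelvis, (0.0, d_asis / 2.0, 0.0))
    markers["RASI"] = mid_asis + rot(R_pelvis, (0.0, -d_asis / 2.0, 0.0))
    mid_psis = mid_asis + rot(R_pelvis, (-geo["psis_back"], 0.0, 0.0))
    markers["LPSI"] = mid_psis + rot(R_pelvis, (0.0, geo["psis_half"], 0.0))
    markers["RPSI"] = mid_psis + rot(R_pelvis, (0.0, -geo["psis_half"], 0.0))

    # trunk markers
    base = mid_hip + rot(R_trunk, (0.0, 0.0, geo["trunk_base"]))
    top = base + rot(R_trunk, (0.0, 0.0, geo["trunk"]))
    cx = geo["trunk_marker_x"]
    markers["C7"] = top + rot(R_trunk, (-cx, 0.0, 0.0))
    markers["SJN"] = top + rot(R_trunk, (cx, 0.0, 0.0))
    markers["T10"] = base + rot(R_trunk, (-cx, 0.0, 0.0))
    markers["XIPH"] = base + rot(R_trunk, (cx, 0.0, 0.0))

    for side, pre in (("left", "L"), ("right", "R")):
        lat_sign = 1.0 if side == "left" else -1.0  # lab +y is left
        hjc = mid_hip + rot(R_pelvis, (0.0, lat_sign * geo["hip_half"], 0.0))
        a = angles["hip"].copy()
        if side == "left":
            a = a * np.array([1.0, -1.0, -1.0])
        R_thigh = R_pelvis @ cardan_matrix(a, JOINT_SEQUENCES["hip"])
        kjc = hjc + rot(R_thigh, (0.0, 0.0, -geo["thigh"]))
        med_sign = 1.0 if side == "right" else -1.0
        markers[f"{pre}MEP"] = kjc + rot(R_thigh, (0.0, med_sign * geo["epi_half"], 0.0))
        markers[f"{pre}LEP"] = kjc + rot(R_thigh, (0.0, -med_sign * geo["epi_half"], 0.0))

        a = angles["knee"].copy()
        if side == "left":
            a = a * np.array([1.0, -1.0, -1.0])
        R_shank = R_thigh @ cardan_matrix(a, JOINT_SEQUENCES["knee"])
        ajc = kjc + rot(R_shank, (0.0, 0.0, -geo["shank"]))
        markers[f"{pre}MM"] = ajc + rot(R_shank, (0.0, med_sign * geo["mall_half"], 0.0))
        markers[f"{pre}LM"] = ajc + rot(R_shank, (0.0, -med_sign * geo["mall_half"], 0.0))

        a = angles["ankle"].copy()
        if side == "left":
            a = a * np.array([1.0, -1.0, -1.0])
        R_foot = R_shank @ cardan_matrix(a, JOINT_SEQUENCES["ankle"])
        lf, ah = geo["foot"], geo["ankle_h"]
        markers[f"{pre}HEE"] = ajc + rot(R_foot, (-0.25 * lf, 0.0, -ah))
        markers[f"{pre}TOE"] = ajc + rot(R_foot, (0.75 * lf, 0.0, -ah))
        markers[f"{pre}MT5"] = ajc + rot(
            R_foot, (0.45 * lf, -med_sign * 0.05, -ah)
        )
        internals[f"ajc_{side}"] = ajc
        internals[f"R_foot_{side}"] = R_foot

    # solve the root translation so the model COM equals the prescribed COM
    com0 = whole_body_com(markers, model)
    z, _, _ = com.evaluate(t)
    target = np.column_stack([np.zeros(n), np.zeros(n), z])
    shift = target - com0
    for name in markers:
        markers[name] = markers[name] + shift
    for key in ("ajc_left", "ajc_right"):
        internals[key] = internals[key] + shift
    internals["angles"] = angles
    return markers, internals


def _cop_tracks(
    t: np.ndarray,
    profile: DropJumpProfile,
    com: _ComProfile,
    markers: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Centre of pressure per plate: progresses heel -> toe during contact."""
    cops = {}
    tau = np.clip((t - com.t_contact) / com.ct, 0.0, 1.0)
    ratio = profile.cop_start_ratio + (
        profile.cop_end_ratio - profile.cop_start_ratio
    ) * tau
    for side, pre in (("left", "L"), ("right", "R")):
        hee, toe = markers[f"{pre}HEE"], markers[f"{pre}TOE"]
        cops[side] = hee + ratio[:, None] * (toe - hee)
    return cops


def _resample_tracks(markers: dict[str, np.ndarray], t_src, t_dst) -> dict[str, np.ndarray]:
    from scipy.interpolate import CubicSpline

    return {
        k: CubicSpline(t_src, v, axis=0)(t_dst) for k, v in markers.items()
    }


def generate_trial(
    profile: DropJumpProfile | None = None,
    anthropometry: Anthropometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    force_noise_n: float | None = None,
    model: SegmentModel | None = None,
    with_kinetics_truth: bool = True,
) -> tuple[TrialRecording, TrialTruth]:
    """Generate one synthetic drop-jump trial plus its ground truth.

    Parameters
    ----------
    noise_sd : float
        SD (m) of i.i.d. Gaussian noise added to every marker coordinate.
    force_noise_n : float, optional
        SD (N) of noise on the plate force channels; defaults to
        ``500 * noise_sd``.
    with_kinetics_truth : bool
        Also compute truth joint kinetics via Newton-Euler on the pristine
        (noise-free, unfiltered) kinematics; disable to speed up bulk
        generation.
    """
    profile = profile or DropJumpProfile()
    anthropometry = anthropometry or Anthropometry(height_m=1.74, mass_kg=79.0)
    profile.validate(anthropometry)
    model = model or load_segment_model()
    rng = np.random.default_rng(seed)

    com = _ComProfile(profile, anthropometry)
    t_m = np.arange(0.0, com.t_end, 1.0 / profile.marker_rate_hz)
    t_f = np.arange(0.0, com.t_end, 1.0 / profile.force_rate_hz)

    markers, internals = _build_markers(t_m, profile, com, anthropometry, model)

    z_f, v_f, a_f = com.evaluate(t_f)
    fz = com.fz(t_f, a=a_f)
    # horizontal COM is constant: no horizontal plate force
    markers_f = _resample_tracks(markers, t_m, t_f)
    cops = _cop_tracks(t_f, profile, com, markers_f)
    plate_forces = {
        side: np.column_stack([np.zeros_like(fz), np.zeros_like(fz), fz / 2.0])
        for side in ("left", "right")
    }

    t_min = com.t_com_min()

    # truth: phase-resolved quantities from the analytic profiles
    angles = internals["angles"]
    angles_f = _joint_angles(t_f, profile, com)
    rom_truth: dict[str, dict[str, np.ndarray]] = {}
    for phase, (ta, tb) in (
        ("ECC", (com.t_contact, t_min)),
        ("CON", (t_min, com.t_takeoff)),
    ):
        mask = (t_f >= ta) & (t_f <= tb)
        rom_truth[phase] = {
            j: angles_f[j][mask].max(axis=0) - angles_f[j][mask].min(axis=0)
            for j in angles_f
        }
    i_gc = int(round(com.t_contact * profile.force_rate_hz))
    angles_at_gc = {j: angles_f[j][min(i_gc, len(t_f) - 1)] for j in angles_f}

    joint_work_truth = None
    ankle_moment_truth = None
    if with_kinetics_truth:
        from ..body_model.dynamics import limb_inverse_dynamics

        kin_true = reconstruct_kinematics(markers_f)
        works: dict[str, dict[str, float]] = {"ECC": {}, "CON": {}}
        for side in ("right",):
            kinetics = limb_inverse_dynamics(
                kin_true,
                side,
                plate_forces[side],
                cops[side],
                profile.force_rate_hz,
                anthropometry.mass_kg,
                model,
            )
            for phase, interval in (
                ("ECC", (com.t_contact, t_min)),
                ("CON", (t_min, com.t_takeoff)),
            ):
                for joint in ("hip", "knee", "ankle"):
                    works[phase][joint] = kinetics.work(
                        joint, interval, anthropometry.mass_kg
                    )
            ankle_moment_truth = kinetics.moments["ankle"]
        joint_work_truth = works

    if noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, noise_sd, markers[name].shape)
    fnoise = force_noise_n if force_noise_n is not None else 500.0 * noise_sd
    if fnoise > 0:
        for side in plate_forces:
            plate_forces[side] = plate_forces[side] + rng.normal(
                0.0, fnoise, plate_forces[side].shape
            )

    recording = TrialRecording(
        markers=markers,
        marker_rate_hz=profile.marker_rate_hz,
        plate_forces=plate_forces,
        plate_cops=cops,
        force_rate_hz=profile.force_rate_hz,
        anthropometry=anthropometry,
    )
    truth = TrialTruth(
        contact_time_s=profile.contact_time_s,
        jump_height_m=profile.jump_height_m,
        rsi=profile.jump_height_m / profile.contact_time_s,
        v_takeoff=com.v_to,
        t_contact=com.t_contact,
        t_com_min=t_min,
        t_takeoff=com.t_takeoff,
        t_landing=com.t_landing,
        body_mass_kg=anthropometry.mass_kg,
        com_times=t_f,
        com_z=z_f,
        com_v=v_f,
        com_a=a_f,
        fz_total=fz,
        joint_angle_profiles=angles,
        rom_truth=rom_truth,
        angles_at_gc=angles_at_gc,
        joint_work_truth=joint_work_truth,
        ankle_moment_truth=ankle_moment_truth,
    )
    return recording, truth


def sample_population(
    n_participants: int,
    seed: int = 0,
    n_trials: int = 1,
) -> list[list[tuple[DropJumpProfile, Anthropometry, int]]]:
    """Seeded population of per-participant trial parameter sets.

    A latent "reactive quality" factor couples shorter contacts with higher
    jumps and shallower joint excursions, giving the feature table its
    correlated block structure.  Returns, per participant, a list of
    (profile, anthropometry, trial_seed) tuples.
    """
    rng = np.random.default_rng(seed)
    population = []
    for i in range(n_participants):
        quality = rng.normal()
        height = float(np.clip(rng.normal(1.74, 0.07), 1.55, 1.95))
        mass = float(np.clip(rng.normal(79.0, 10.0), 55.0, 110.0))
        anthro = Anthropometry(height_m=height, mass_kg=mass)
        trials = []
        for k in range(n_trials):
            ct = float(np.clip(rng.normal(0.22 - 0.030 * quality, 0.015), 0.16, 0.38))
            jh = float(np.clip(rng.normal(0.33 + 0.035 * quality, 0.025), 0.25, 0.51))
            depth_scale = float(np.clip(1.0 + 0.45 * (ct - 0.22) / 0.05
                                        + rng.normal(0.0, 0.08), 0.55, 1.8))
            angles = {}
            for joint, par in _DEFAULT_ANGLES.items():
                amp = tuple(
                    a * depth_scale * float(np.clip(rng.normal(1.0, 0.10), 0.5, 1.5))
                    for a in par["amp"]
                )
                gc = tuple(
                    g0 * float(np.clip(rng.normal(1.0, 0.15), 0.4, 1.6))
                    for g0 in par["gc"]
                )
                angles[joint] = dict(base=tuple(par["base"]), gc=gc, amp=amp)
            profile = DropJumpProfile(
                contact_time_s=ct,
                jump_height_m=jh,
                angles=angles,
                pelvis_pitch_amp_deg=-7.0 * depth_scale,
                trunk_lean_amp_deg=-6.0 * depth_scale,
                force_shape_beta=float(np.clip(rng.normal(0.12, 0.15), -0.45, 0.45)),
                bump_skew={
                    j: float(np.clip(rng.normal(0.95, 0.18), 0.55, 1.5))
                    for j in ("hip", "knee", "ankle")
                },
            )
            trials.append((profile, anthro, int(rng.integers(0, 2**31 - 1))))
        population.append(trials)
    return population
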