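"""Outcome measures and the phase-tagged predictor set.

Variable nomenclature: ``CT`` (ground contact time), ``Ht`` (jump height),
``RSI`` (reactive strength index) are the three outcomes.  Predictors are
tagged ``@GC`` (at initial ground contact), ``(ECC)`` (eccentric phase) or
``(CON)`` (concentric phase); whole-contact variables carry no tag.
``BH``/``BM`` are body height and mass.

Interpretation notes (the source constants give units only):

* ``RFD`` — peak eccentric vertical GRF divided by the time from contact
  to that peak (a max-slope alternative is available via ``rfd_mode``);
* ``Synchro`` — absolute timing offset between the vertical GRF peak during
  contact and the COM-minimum instant, as a percentage of contact time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events_phases import TrialEvents
from .signal_processing import SampledSignal

__all__ = [
    "GRAVITY_MS2",
    "OUTCOME_NAMES",
    "PREDICTOR_NAMES",
    "VARIABLE_UNITS",
    "FeatureTable",
    "jump_height",
    "reactive_strength_index",
    "phase_impulse",
    "grf_summaries",
    "com_power_work",
    "extract_trial_features",
    "aggregate_trials",
    "assemble_feature_table",
]

GRAVITY_MS2 = 9.81

_JOINT_AXES = {
    "Hip": ("Ext/Flex", "Abd/Add", "Ext/Int rotation"),
    "Knee": ("Ext/Flex", "Valgus/Varus", "Ext/Int rotation"),
    "Ankle": ("Pla/Dor flexion", "Eve/Inv", "Abd/Add"),
}


def _build_units() -> dict[str, str]:
    units: dict[str, str] = {
        "CT": "s",
        "Ht": "m",
        "RSI": "m/s",
        "BH": "m",
        "BM": "kg",
        "Stiffness": "N/m/kg",
        "RFD": "N/s/kg",
        "Synchro": "%",
        "IMP_ECC/CON": "",
        "F_zero-vel": "N/kg",
    }
    for joint, axes in _JOINT_AXES.items():
        for axis in axes:
            units[f"{joint} {axis}@GC"] = "deg"
    for phase in ("ECC", "CON"):
        units[f"CT ({phase})"] = "s"
        units[f"IMP ({phase})"] = "Ns/kg"
        units[f"Mean GRF ({phase})"] = "N/kg"
        units[f"Peak GRF ({phase})"] = "N/kg"
        units[f"Disp ({phase})"] = "m"
        units[f"COM work ({phase})"] = "J/kg"
        for joint in ("Hip", "Knee", "Ankle"):
            units[f"{joint} joint work ({phase})"] = "J/kg"
        for joint, axes in _JOINT_AXES.items():
            for axis in axes:
                units[f"{joint} {axis} ({phase})"] = "deg"
    return units


VARIABLE_UNITS: dict[str, str] = _build_units()
OUTCOME_NAMES: tuple[str, ...] = ("CT", "Ht", "RSI")
PREDICTOR_NAMES: tuple[str, ...] = tuple(
    name for name in VARIABLE_UNITS if name not in OUTCOME_NAMES
)


def jump_height(v_takeoff: float, g: float = GRAVITY_MS2) -> float:
    """Jump height (m) from the vertical COM velocity at take-off."""
    if v_takeoff <= 0:
        raise ValueError("no upward velocity at take-off")
    return v_takeoff**2 / (2.0 * g)


def reactive_strength_index(height_m: float, contact_time_s: float) -> float:
    """Jump height divided by ground contact time (m/s)."""
    if contact_time_s <= 0:
        raise ValueError("contact time must be positive")
    return height_m / contact_time_s


def _phase_mask(sig: SampledSignal, interval: tuple[float, float]) -> np.ndarray:
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("empty phase interval")
    t = sig.times
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if mask.sum() < 2:
        raise ValueError("phase interval outside signal support")
    return mask


def phase_impulse(
    fz: SampledSignal, interval: tuple[float, float], mass_kg: float
) -> float:
    """Mass-normalized vertical impulse (N s/kg): trapezoidal integral of fz."""
    mask = _phase_mask(fz, interval)
    return float(np.trapezoid(fz.values[mask], fz.times[mask]) / mass_kg)


def grf_summaries(
    fz: SampledSignal, interval: tuple[float, float], mass_kg: float
) -> dict[str, float]:
    """Mean and peak vertical GRF (N/kg) over a phase."""
    mask = _phase_mask(fz, interval)
    window = fz.values[mask]
    return {
        "mean": float(np.mean(window) / mass_kg),
        "peak": float(np.max(window) / mass_kg),
    }


def com_power_work(
    fz: SampledSignal,
    com_velocity: SampledSignal,
    interval: tuple[float, float],
    mass_kg: float,
) -> tuple[np.ndarray, float]:
    """COM power series (W/kg) over a phase and its time integral (J/kg).

    Power is the product of vertical GRF and vertical COM velocity.
    """
    if len(fz) != len(com_velocity):
        raise ValueError("force and COM velocity series length mismatch")
    mask = _phase_mask(fz, interval)
    power = fz.values[mask] * com_velocity.values[mask] / mass_kg
    work = float(np.trapezoid(power, fz.times[mask]))
    return power, work


def vertical_stiffness(
    peak_ecc_grf_nkg: float, ecc_displacement_m: float
) -> float:
    """Peak eccentric GRF over |eccentric COM displacement| (N/m/kg)."""
    if abs(ecc_displacement_m) < 1e-9:
        raise ValueError("zero eccentric displacement: stiffness undefined")
    return peak_ecc_grf_nkg / abs(ecc_displacement_m)


def extract_trial_features(
    fz_total: SampledSignal,
    com_z: SampledSignal,
    events: TrialEvents,
    mass_kg: float,
    height_m: float,
    angle_series: dict,
    joint_works: dict[str, dict[str, float]] | None = None,
    rfd_mode: str = "time_to_peak",
) -> dict[str, float]:
    """Compute all scalar variables for one analyzed trial.

    Parameters
    ----------
    fz_total : SampledSignal
        Summed vertical GRF (N) on the force timebase.
    com_z : SampledSignal
        Vertical whole-body COM (m) on the same timebase.
    events : TrialEvents
        With phases segmented.
    angle_series : dict
        ``angle_series[joint][side]`` -> JointAngleSeries; sides are
        averaged for reporting.
    joint_works : dict, optional
        ``joint_works[phase][joint]`` -> J/kg (already side-averaged).
        When omitted the joint-work columns are left out.
    """
    from .body_model.angles import range_of_motion

    events.validate()
    if len(fz_total) != len(com_z):
        raise ValueError("force and COM series length mismatch")

    t = fz_total.times
    dt = 1.0 / fz_total.rate_hz
    v_com = np.gradient(com_z.values, dt)
    v_sig = SampledSignal(v_com, fz_total.rate_hz, fz_total.t0)

    ct = events.contact_time
    v_to = float(v_com[fz_total.index_at(events.t_takeoff)])
    ht = jump_height(v_to)
    out: dict[str, float] = {
        "CT": ct,
        "Ht": ht,
        "RSI": reactive_strength_index(ht, ct),
        "BH": height_m,
        "BM": mass_kg,
    }

    ecc, con = events.ecc_interval, events.con_interval
    z = com_z.values
    i_c = com_z.index_at(events.t_contact)
    i_m = com_z.index_at(events.t_com_min)
    i_to = com_z.index_at(events.t_takeoff)
    disp = {"ECC": float(z[i_m] - z[i_c]), "CON": float(z[i_to] - z[i_m])}

    imp = {}
    for phase, interval in (("ECC", ecc), ("CON", con)):
        imp[phase] = phase_impulse(fz_total, interval, mass_kg)
        summ = grf_summaries(fz_total, interval, mass_kg)
        out[f"CT ({phase})"] = interval[1] - interval[0]
        out[f"IMP ({phase})"] = imp[phase]
        out[f"Mean GRF ({phase})"] = summ["mean"]
        out[f"Peak GRF ({phase})"] = summ["peak"]
        out[f"Disp ({phase})"] = disp[phase]
        _, work = com_power_work(fz_total, v_sig, interval, mass_kg)
        out[f"COM work ({phase})"] = work

    out["IMP_ECC/CON"] = imp["ECC"] / imp["CON"]
    out["F_zero-vel"] = float(fz_total.values[i_m] / mass_kg)

    ecc_mask = _phase_mask(fz_total, ecc)
    ecc_fz = fz_total.values[ecc_mask]
    ecc_t = t[ecc_mask]
    i_peak_ecc = int(np.argmax(ecc_fz))
    peak_ecc = float(ecc_fz[i_peak_ecc] / mass_kg)
    out["Stiffness"] = vertical_stiffness(peak_ecc, disp["ECC"])
    if rfd_mode == "time_to_peak":
        rise = max(ecc_t[i_peak_ecc] - events.t_contact, dt)
        out["RFD"] = peak_ecc / rise
    elif rfd_mode == "max_slope":
        out["RFD"] = float(np.max(np.gradient(ecc_fz, dt)) / mass_kg)
    else:
        raise ValueError(f"unknown rfd_mode {rfd_mode!r}")

    contact_mask = _phase_mask(fz_total, events.contact_interval)
    t_peak_contact = float(t[contact_mask][np.argmax(fz_total.values[contact_mask])])
    out["Synchro"] = abs(t_peak_contact - events.t_com_min) / ct * 100.0

    for joint_key, series_by_side in angle_series.items():
        joint = joint_key.capitalize()
        axes = _JOINT_AXES[joint]
        gc = np.mean(
            [s.at_time(events.t_contact) for s in series_by_side.values()], axis=0
        )
        for k, axis in enumerate(axes):
            out[f"{joint} {axis}@GC"] = float(gc[k])
        for phase, interval in (("ECC", ecc), ("CON", con)):
            rom = np.mean(
                [range_of_motion(s, interval) for s in series_by_side.values()],
                axis=0,
            )
            for k, axis in enumerate(axes):
                out[f"{joint} {axis} ({phase})"] = float(rom[k])

    if joint_works is not None:
        for phase in ("ECC", "CON"):
            for joint in ("Hip", "Knee", "Ankle"):
                out[f"{joint} joint work ({phase})"] = joint_works[phase][
                    joint.lower()
                ]
    return out


def aggregate_trials(trial_features: list[dict], mode: str = "mean") -> dict:
    """Aggregate repeated trials of one participant.

    ``mean`` averages every variable over trials (permutation invariant);
    ``best`` takes the single trial with the highest RSI.
    """
    if not trial_features:
        raise ValueError("no trials to aggregate")
    if mode == "best":
        return dict(max(trial_features, key=lambda d: d["RSI"]))
    if mode != "mean":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    keys = trial_features[0].keys()
    # math.fsum is exactly rounded, making the mean permutation invariant
    import math

    n = len(trial_features)
    return {k: math.fsum(d[k] for d in trial_features) / n for k in keys}


@dataclass
class FeatureTable:
    """Participants x variables table with units, outcomes first."""

    data: pd.DataFrame
    units: dict[str, str]

    def __post_init__(self) -> None:
        for col in self.data.columns:
            if col not in self.units:
                raise ValueError(f"no unit recorded for column {col!r}")

    @property
    def outcomes(self) -> pd.DataFrame:
        return self.data[list(OUTCOME_NAMES)]

    @property
    def predictors(self) -> pd.DataFrame:
        return self.data.drop(columns=list(OUTCOME_NAMES))

    def validate(self, atol: float = 1e-9) -> None:
        if self.data.isna().any().any():
            cols = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing cells in columns {cols}")
        rsi = self.data["Ht"] / self.data["CT"]
        if not np.allclose(rsi, self.data["RSI"], atol=atol, rtol=1e-7):
            raise ValueError("RSI column inconsistent with Ht / CT")

    def to_csv(self, path) -> None:
        """Write with a two-row header (names, units)."""
        header = pd.DataFrame(
            [[self.units[c] for c in self.data.columns]],
            columns=self.data.columns,
            index=pd.Index(["unit"], name=self.data.index.name or "participant"),
        )
        body = self.data.copy()
        body.index.name = header.index.name
        pd.concat([header, body]).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        raw = pd.read_csv(path, index_col=0)
        units = {c: ("" if pd.isna(u) else str(u)) for c, u in raw.iloc[0].items()}
        data = raw.iloc[1:].astype(float)
        data.index.name = "participant"
        return cls(data=data, units=units)


def assemble_feature_table(
    participant_features: dict[str, dict[str, float]],
    require_full: bool = True,
) -> FeatureTable:
    """Assemble the participant-level table (outcomes + predictors).

    Raises a ``ValueError`` naming the participant and column when a
    variable is missing and ``require_full`` is set.
    """
    columns = list(OUTCOME_NAMES) + [
        n for n in PREDICTOR_NAMES
    ]
    rows = {}
    for pid, feats in participant_features.items():
        if require_full:
            missing = [c for c in columns if c not in feats]
            if missing:
                raise ValueError(
                    f"participant {pid!r} is missing variables {missing}"
                )
        rows[pid] = {c: feats.get(c, np.nan) for c in columns}
    data = pd.DataFrame.from_dict(rows, orient="index", dtype=float)[columns]
    data.index.name = "participant"
    table = FeatureTable(data=data, units=dict(VARIABLE_UNITS))
    if require_full:
        table.validate()
    return table
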