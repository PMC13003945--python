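"""End-to-end orchestration: signals -> events -> model -> features -> PLS."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ..body_model import (
    limb_inverse_dynamics,
    joint_angle_series,
    reconstruct_kinematics,
    whole_body_com,
)
from ..body_model.inertia import SegmentModel, load_segment_model
from ..events_phases import TrialEvents, detect_contact_takeoff, segment_phases
from ..features import (
    FeatureTable,
    OUTCOME_NAMES,
    aggregate_trials,
    assemble_feature_table,
    extract_trial_features,
)
from ..pls_stats import (
    FilterReport,
    assign_variables_to_components,
    correlation_filter,
    cross_validate_components,
    fit_pls,
    model_p_value,
    vif_filter,
    zscore_columns,
)
from ..signal_processing import (
    SampledSignal,
    align_and_resample,
    butterworth_zero_lag,
    residual_analysis_cutoff,
)
from ..synthetic_data.trial import TrialRecording
from .config import RunConfig

__all__ = [
    "analyze_trial",
    "build_feature_table",
    "PLSReport",
    "run_statistics",
    "run_pipeline",
    "RESPONSE_COLUMNS",
]

log = logging.getLogger("djpls")

RESPONSE_COLUMNS = {"ct": "CT", "height": "Ht", "rsi": "RSI"}


def _filter_markers(
    markers: dict[str, np.ndarray], rate: float, t0: float, cutoff: float
) -> dict[str, np.ndarray]:
    return {
        name: butterworth_zero_lag(SampledSignal(xyz, rate, t0), cutoff).values
        for name, xyz in markers.items()
    }


def analyze_trial(
    recording: TrialRecording,
    config: RunConfig | None = None,
    model: SegmentModel | None = None,
) -> dict[str, float]:
    """Compute all outcome and predictor variables for one trial."""
    config = config or RunConfig()
    model = model or load_segment_model()
    t0 = recording.t0
    m_rate, f_rate = recording.marker_rate_hz, recording.force_rate_hz

    cutoff = config.filter_cutoff_hz
    if config.auto_residual:
        probe = SampledSignal(recording.markers["RHEE"][:, 2], m_rate, t0)
        cutoff = residual_analysis_cutoff(probe, np.arange(2.0, 31.0))
        log.info("residual analysis selected cutoff %.1f Hz", cutoff)

    markers = _filter_markers(recording.markers, m_rate, t0, cutoff)
    forces = {}
    for side, f in recording.plate_forces.items():
        sig = SampledSignal(f, f_rate, t0)
        forces[side] = (
            butterworth_zero_lag(sig, cutoff).values if config.filter_forces else sig.values
        )

    fz_total = SampledSignal(sum(f[:, 2] for f in forces.values()), f_rate, t0)
    t_contact, t_takeoff, t_landing = detect_contact_takeoff(
        fz_total, config.force_threshold_n
    )
    events = TrialEvents(t_contact=t_contact, t_takeoff=t_takeoff, t_landing=t_landing)

    com = whole_body_com(markers, model)
    com_z_m = SampledSignal(com[:, 2], m_rate, t0)
    com_z, fz_total = align_and_resample(com_z_m, fz_total)
    events = segment_phases(com_z, events)

    kin = reconstruct_kinematics(markers)
    angle_series = {
        joint: {
            side: joint_angle_series(
                prox[side] if isinstance(prox, dict) else prox,
                dist[side],
                joint,
                side,
                m_rate,
                t0,
            )
            for side in ("left", "right")
        }
        for joint, prox, dist in (
            ("hip", kin.pelvis_R, kin.thigh_R),
            ("knee", kin.thigh_R, kin.shank_R),
            ("ankle", kin.shank_R, kin.foot_R),
        )
    }

    # inverse dynamics on the force timebase
    t_f = fz_total.times
    markers_f = {
        name: align_and_resample(
            SampledSignal(xyz, m_rate, t0), fz_total
        )[0].values
        for name, xyz in markers.items()
    }
    kin_f = reconstruct_kinematics(markers_f)
    n_f = len(t_f)
    works: dict[str, dict[str, list[float]]] = {
        "ECC": {"hip": [], "knee": [], "ankle": []},
        "CON": {"hip": [], "knee": [], "ankle": []},
    }
    for side in ("left", "right"):
        grf = forces[side][:n_f]
        cop = recording.plate_cops[side][:n_f]
        kinetics = limb_inverse_dynamics(
            kin_f, side, grf, cop, f_rate, recording.anthropometry.mass_kg, model,
            t0=fz_total.t0,
        )
        for phase, interval in (("ECC", events.ecc_interval), ("CON", events.con_interval)):
            for joint in ("hip", "knee", "ankle"):
                works[phase][joint].append(
                    kinetics.work(joint, interval, recording.anthropometry.mass_kg)
                )
    joint_works = {
        phase: {joint: float(np.mean(vals)) for joint, vals in by_joint.items()}
        for phase, by_joint in works.items()
    }

    return extract_trial_features(
        fz_total,
        com_z,
        events,
        recording.anthropometry.mass_kg,
        recording.anthropometry.height_m,
        angle_series,
        joint_works=joint_works,
        rfd_mode=config.rfd_mode,
    )


def build_feature_table(
    per_participant_trials: dict[str, list[dict[str, float]]],
    config: RunConfig | None = None,
) -> FeatureTable:
    """Aggregate trial-level variable dicts per participant and assemble."""
    config = config or RunConfig()
    aggregated = {
        pid: aggregate_trials(trials, mode=config.aggregation)
        for pid, trials in per_participant_trials.items()
    }
    return assemble_feature_table(aggregated)


@dataclass
class PLSReport:
    """Bundle of one fitted response model and its selection diagnostics."""

    response: str
    filter_report: FilterReport
    selected_components: int
    rmsecv: np.ndarray
    q2: np.ndarray
    r2y_cumulative: np.ndarray
    p_values: np.ndarray
    assignment: pd.DataFrame

    def metrics(self) -> dict:
        return {
            "response": self.response,
            "selected_components": int(self.selected_components),
            "rmsecv": [round(float(v), 10) for v in self.rmsecv],
            "q2": [round(float(v), 10) for v in self.q2],
            "r2y_cumulative_pct": [round(float(v), 10) for v in self.r2y_cumulative],
            "p_values": [float(v) for v in self.p_values],
            "removed_by_correlation": [
                [a, b, round(r, 6)] for a, b, r in self.filter_report.removed_by_correlation
            ],
            "removed_by_vif": [
                [a, round(v, 6) if np.isfinite(v) else "inf"]
                for a, v in self.filter_report.removed_by_vif
            ],
            "n_retained": len(self.filter_report.retained),
        }


def run_statistics(
    table: FeatureTable, response: str, config: RunConfig | None = None
) -> PLSReport:
    """Filtered, cross-validated PLS regression for one response."""
    config = config or RunConfig()
    column = RESPONSE_COLUMNS.get(response, response)
    if column not in table.data.columns:
        raise KeyError(f"response column {column!r} not in feature table")

    drop = [column] if config.include_other_outcomes else list(OUTCOME_NAMES)
    X_raw = table.data.drop(columns=[c for c in drop if c in table.data.columns])
    y_raw = table.data[column]

    Xz, _ = zscore_columns(X_raw)
    report = FilterReport()
    Xf, report = correlation_filter(Xz, threshold=config.corr_threshold, report=report)
    Xf, report = vif_filter(Xf, threshold=config.vif_threshold, report=report)
    report.retained = list(Xf.columns)
    report.check_partition(X_raw.columns)
    for name, partner, r in report.removed_by_correlation:
        log.info("correlation filter removed %s (|r|=%.3f with %s)", name, abs(r), partner)
    for name, v in report.removed_by_vif:
        log.info("VIF filter removed %s (VIF=%.2f)", name, v)

    max_comp = min(config.max_components, len(Xf.columns), len(y_raw) - 2)
    k = min(config.cv_folds, len(y_raw))
    if k < config.cv_folds:
        log.info("reducing CV folds to %d (only %d participants)", k, len(y_raw))
    config = replace(config, cv_folds=k)
    if config.leak_free_cv:
        cv = cross_validate_components(
            X_raw,
            y_raw,
            k=config.cv_folds,
            max_components=max_comp,
            seed=config.cv_seed,
            corr_threshold=config.corr_threshold,
            vif_threshold=config.vif_threshold,
        )
    else:  # reproduction mode: filters stay fixed at the global result
        cv = cross_validate_components(
            X_raw[Xf.columns],
            y_raw,
            k=config.cv_folds,
            max_components=max_comp,
            seed=config.cv_seed,
        )
    log.info("RMSECV selected %d components for %s", cv.selected_components, column)

    yz = (y_raw - y_raw.mean()) / y_raw.std(ddof=1)
    model = fit_pls(Xf, yz, cv.selected_components)
    assignment = assign_variables_to_components(
        model, vip_threshold=config.vip_threshold, weight_kind=config.weight_kind
    )
    p_values = model_p_value(model.scores, yz.to_numpy(), cv.selected_components)
    return PLSReport(
        response=column,
        filter_report=report,
        selected_components=cv.selected_components,
        rmsecv=cv.rmsecv,
        q2=cv.q2,
        r2y_cumulative=model.r2y_cumulative,
        p_values=p_values,
        assignment=assignment,
    )


def descriptive_summary(table: FeatureTable) -> pd.DataFrame:
    """Mean, SD, max, min per variable (descriptive-table layout)."""
    data = table.data
    return pd.DataFrame(
        {
            "unit": [table.units[c] for c in data.columns],
            "mean": data.mean(),
            "sd": data.std(ddof=1),
            "max": data.max(),
            "min": data.min(),
        }
    )


def run_pipeline(
    table: FeatureTable,
    out_dir,
    config: RunConfig | None = None,
    responses: tuple[str, ...] = ("ct", "height", "rsi"),
) -> dict:
    """Descriptive summary plus one PLS report per response, written to disk."""
    from ..io import write_json

    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.validate()

    descriptive = descriptive_summary(table)
    descriptive.to_csv(out / "descriptive_summary.csv")

    metrics = {}
    for response in responses:
        rep = run_statistics(table, response, config)
        rep.assignment.to_csv(out / f"pls_report_{rep.response.replace('/', '_')}.csv", index=False)
        metrics[rep.response] = rep.metrics()
    write_json(out / "metrics.json", metrics)
    return {"descriptive": descriptive, "metrics": metrics}
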