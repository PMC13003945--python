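"""Reproduction of the published models from the deposited dataset.

The deposited participant-level table is not redistributable, so it is
looked up at ``data/supplementary_dataset.csv`` (CSV export, one header
row) with an optional column-name dictionary at
``data/supp_column_map.yaml``.  When present, the published analysis can
be re-run in paper-faithful filter mode and compared against the printed
model metrics.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..features import FeatureTable, OUTCOME_NAMES, VARIABLE_UNITS
from ..pls_stats import (
    correlation_filter,
    cross_validate_components,
    fit_pls,
    vif_filter,
    vip_scores,
    zscore_columns,
)
from .config import RunConfig

__all__ = [
    "DEFAULT_DATASET_PATH",
    "DEFAULT_COLUMN_MAP_PATH",
    "load_supplementary_table",
    "reproduce_published_models",
]

DEFAULT_DATASET_PATH = Path("data/supplementary_dataset.csv")
DEFAULT_COLUMN_MAP_PATH = Path("data/supp_column_map.yaml")

#: component counts at which the published models report their headline
#: cumulative R2Y
PUBLISHED_COMPONENTS = {"CT": 1, "Ht": 3, "RSI": 2}


def load_supplementary_table(
    csv_path=DEFAULT_DATASET_PATH,
    column_map_path=DEFAULT_COLUMN_MAP_PATH,
) -> FeatureTable:
    """Load the deposited dataset, renaming columns to canonical names."""
    raw = pd.read_csv(csv_path)
    mapping = {}
    map_path = Path(column_map_path)
    if map_path.exists():
        mapping = yaml.safe_load(map_path.read_text()).get("columns") or {}
    raw = raw.rename(columns=mapping)
    known = [c for c in raw.columns if c in VARIABLE_UNITS]
    unknown = [c for c in raw.columns if c not in VARIABLE_UNITS]
    if unknown:
        warnings.warn(f"ignoring unmapped columns: {unknown}")
    missing_outcomes = [c for c in OUTCOME_NAMES if c not in known]
    if missing_outcomes:
        raise ValueError(f"dataset lacks outcome columns {missing_outcomes}")
    data = raw[known].astype(float)
    data.index = pd.Index(
        [f"P{i + 1:03d}" for i in range(len(data))], name="participant"
    )
    return FeatureTable(data=data, units={c: VARIABLE_UNITS[c] for c in known})


def reproduce_published_models(
    table: FeatureTable, cv_seed: int = 0, config: RunConfig | None = None
) -> dict:
    """Paper-faithful reproduction: global filters, fixed component counts.

    Returns a dict with, per response: cumulative R2Y (%) at the published
    component count, VIP scores, CV metrics; plus the descriptive mean RSI
    and the hip-adduction-at-contact vs peak-eccentric-GRF correlation.
    """
    config = config or RunConfig(leak_free_cv=False, cv_seed=cv_seed)
    out: dict = {}
    for response, n_comp in PUBLISHED_COMPONENTS.items():
        X_raw = table.data.drop(
            columns=[c for c in OUTCOME_NAMES if c in table.data.columns]
        )
        y_raw = table.data[response]
        Xz, _ = zscore_columns(X_raw)
        Xf, report = correlation_filter(Xz, threshold=config.corr_threshold)
        Xf, report = vif_filter(Xf, threshold=config.vif_threshold, report=report)
        yz = (y_raw - y_raw.mean()) / y_raw.std(ddof=1)
        model = fit_pls(Xf, yz, n_comp)
        cv = cross_validate_components(
            X_raw[Xf.columns], y_raw, k=config.cv_folds,
            max_components=n_comp, seed=config.cv_seed,
        )
        out[response] = {
            "r2y_cumulative_pct": model.r2y_cumulative.tolist(),
            "vip": vip_scores(model).to_dict(),
            "q2": cv.q2.tolist(),
            "rmsecv": cv.rmsecv.tolist(),
            "n_retained": Xf.shape[1],
        }
    out["mean_rsi"] = float((table.data["Ht"] / table.data["CT"]).mean())
    if {"Hip Abd/Add@GC", "Peak GRF (ECC)"} <= set(table.data.columns):
        out["r_hip_add_gc_vs_peak_grf"] = float(
            np.corrcoef(
                table.data["Hip Abd/Add@GC"], table.data["Peak GRF (ECC)"]
            )[0, 1]
        )
    return out
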