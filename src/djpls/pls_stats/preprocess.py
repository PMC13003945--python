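"""Column standardization and collinearity prefilters.

The two filters mirror the published preprocessing: first, for every pair
of predictors with |r| above 0.95, the member with the larger overall
correlation with the remaining predictors is dropped; then variables with
a variance inflation factor above 10 are removed iteratively (largest
first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZScorer",
    "zscore_columns",
    "FilterReport",
    "correlation_filter",
    "vif_filter",
    "vif_values",
]


@dataclass
class ZScorer:
    """Stored column means/SDs of a z-score transform (SD denominator n-1)."""

    means: pd.Series
    sds: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table - self.means[table.columns]) / self.sds[table.columns]

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        return table * self.sds[table.columns] + self.means[table.columns]


def zscore_columns(table: pd.DataFrame) -> tuple[pd.DataFrame, ZScorer]:
    """Standardize every column to mean 0, SD 1 (ddof=1).

    Raises ``ValueError`` naming any zero-variance column.
    """
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    dead = sds.index[sds <= 0].tolist()
    if dead:
        raise ValueError(f"zero-variance columns: {dead}")
    scaler = ZScorer(means=means, sds=sds)
    return scaler.transform(table), scaler


@dataclass
class FilterReport:
    """Record of a collinearity-filter pass."""

    removed_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    removed_by_vif: list[tuple[str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return [name for name, *_ in self.removed_by_correlation] + [
            name for name, _ in self.removed_by_vif
        ]

    def check_partition(self, columns) -> None:
        removed = set(self.removed)
        retained = set(self.retained)
        if removed & retained:
            raise ValueError("column in both removed and retained sets")
        if removed | retained != set(columns):
            raise ValueError("removed + retained do not cover the input columns")


def correlation_filter(
    X: pd.DataFrame,
    threshold: float = 0.95,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop one member of every predictor pair with |r| above ``threshold``.

    Pairs are processed by descending |r| (recomputed after each removal),
    ties broken by column order; within a pair, the member with the larger
    mean absolute correlation to all other current predictors is dropped
    (ties retain the earlier column).
    """
    report = report or FilterReport()
    cols = list(X.columns)
    current = X.copy()
    while len(cols) > 1:
        corr = current[cols].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        abs_corr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(abs_corr), abs_corr.shape)
        if abs_corr[i, j] <= threshold:
            break
        i, j = min(i, j), max(i, j)
        mean_i = abs_corr[i].sum() / (len(cols) - 1)
        mean_j = abs_corr[j].sum() / (len(cols) - 1)
        drop = j if mean_j >= mean_i else i
        keep = i if drop == j else j
        report.removed_by_correlation.append(
            (cols[drop], cols[keep], float(corr[i, j]))
        )
        cols.pop(drop)
    report.retained = list(cols)
    return X[cols], report


def vif_values(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j | rest).

    For well-posed problems (rows > columns, full rank) each VIF is
    computed by direct least-squares regression of column j on the rest.
    When the system is under-determined or rank-deficient the diagonal of
    the pseudo-inverse of the correlation matrix is used instead
    (minimum-norm fallback); exactly collinear columns report ``inf``.
    """
    Z = X.to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    n, p = Z.shape
    if p < 2:
        raise ValueError("need at least two columns for VIF")
    out = np.empty(p)
    if n > p:
        # direct regressions; exactly collinear columns get R^2 = 1 -> inf
        for j in range(p):
            others = np.delete(Z, j, axis=1)
            coef, _, _, _ = np.linalg.lstsq(others, Z[:, j], rcond=None)
            resid = Z[:, j] - others @ coef
            r2 = 1.0 - resid @ resid / (Z[:, j] @ Z[:, j])
            out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    else:
        corr = (Z.T @ Z) / (n - 1)
        out[:] = np.diag(np.linalg.pinv(corr, rcond=1e-10))
        # exact collinearity can hide in the pseudo-inverse; flag via rank
        if np.linalg.matrix_rank(corr, tol=1e-12) < p:
            sv = np.linalg.svd(corr, compute_uv=False)
            if sv[-1] < 1e-12:
                out = np.where(out > 1e10, np.inf, out)
    return pd.Series(out, index=X.columns)


def vif_filter(
    X: pd.DataFrame,
    threshold: float = 10.0,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Iteratively remove the largest-VIF column until all are <= threshold."""
    report = report or FilterReport()
    current = X.copy()
    while current.shape[1] >= 2:
        vifs = vif_values(current)
        worst = vifs.idxmax()
        if not (vifs[worst] > threshold):
            break
        report.removed_by_vif.append((worst, float(vifs[worst])))
        current = current.drop(columns=[worst])
    report.retained = list(current.columns)
    return current, report
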