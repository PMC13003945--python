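"""K-fold cross-validated component selection (RMSECV, Q^2).

Fold assignment is a seeded shuffle into near-equal folds.  In the
default, leak-free mode, standardization and both collinearity filters are
refit on the training folds only; the "paper-faithful" reproduction mode
applies them once globally before calling this routine (pass prefiltered
data and leave the thresholds unset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import correlation_filter, vif_filter, zscore_columns
from .pls import fit_pls

__all__ = ["CVResult", "kfold_indices", "cross_validate_components"]


def kfold_indices(n: int, k: int, seed: int) -> np.ndarray:
    """Fold label (0..k-1) per row: seeded shuffle, near-equal fold sizes."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, k)):
        labels[chunk] = fold
    return labels


@dataclass
class CVResult:
    """Cross-validation metrics per cumulative component count (1-based)."""

    rmsecv: np.ndarray          # standardized-y units
    q2: np.ndarray
    selected_components: int
    fold_assignment: np.ndarray
    seed: int
    max_components: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": np.arange(1, len(self.rmsecv) + 1),
                "RMSECV": self.rmsecv,
                "Q2": self.q2,
            }
        )


def cross_validate_components(
    X: pd.DataFrame,
    y: pd.Series,
    k: int = 10,
    max_components: int = 10,
    seed: int = 0,
    corr_threshold: float | None = None,
    vif_threshold: float | None = None,
) -> CVResult:
    """RMSECV / Q^2 per component count; selected count minimizes RMSECV.

    Parameters
    ----------
    X, y : unstandardized predictors and response (standardization is
        refit inside each training fold).
    corr_threshold, vif_threshold : optional
        When given, the corresponding collinearity filter is refit on each
        training fold (leak-free).  Leave unset to cross-validate exactly
        the supplied predictor set.

    RMSECV is sqrt(PRESS/n) expressed in globally standardized response
    units; Q^2 = 1 - PRESS/TSS with TSS about the global mean.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    folds = kfold_indices(n, k, seed)

    press = np.zeros(max_components)
    for fold in range(k):
        test = folds == fold
        train = ~test
        Xtr, scaler_x = zscore_columns(X.loc[train])
        if corr_threshold is not None:
            Xtr, _ = correlation_filter(Xtr, threshold=corr_threshold)
        if vif_threshold is not None:
            Xtr, _ = vif_filter(Xtr, threshold=vif_threshold)
        y_mean = yv[train].mean()
        y_sd = yv[train].std(ddof=1)
        ytr = (yv[train] - y_mean) / y_sd

        rank = np.linalg.matrix_rank(Xtr.to_numpy())
        a_max = min(max_components, rank)
        model = fit_pls(Xtr, ytr, a_max)
        Xte = scaler_x.transform(X.loc[test, Xtr.columns])
        for a in range(1, max_components + 1):
            pred = model.predict(Xte, n_components=min(a, a_max))
            resid = yv[test] - (pred * y_sd + y_mean)
            press[a - 1] += float(resid @ resid)

    sd_global = yv.std(ddof=1)
    tss = float(((yv - yv.mean()) ** 2).sum())
    rmsecv = np.sqrt(press / n) / sd_global
    q2 = 1.0 - press / tss
    selected = int(np.argmin(rmsecv)) + 1
    return CVResult(
        rmsecv=rmsecv,
        q2=q2,
        selected_components=selected,
        fold_assignment=folds,
        seed=seed,
        max_components=max_components,
    )
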