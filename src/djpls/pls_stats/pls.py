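"""Single-response PLS regression (NIPALS with y-deflation) and VIP scores.

For a single response the NIPALS weight vector per component is the
normalized covariance direction X^T y; components maximize covariance with
the response and successive score vectors are mutually orthogonal.  At
full rank the fitted values coincide with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PLSModelResult",
    "fit_pls",
    "vip_scores",
    "assign_variables_to_components",
]


@dataclass
class PLSModelResult:
    """Fitted PLS model in standardized predictor/response space.

    Attributes
    ----------
    columns : list of str
        Predictor names, in model order.
    weights : ndarray (p, a)
        Normalized X-weights per component (unit norm each).
    loadings : ndarray (p, a)
        X-loadings per component.
    scores : ndarray (n, a)
        X-scores (mutually orthogonal).
    y_loadings : ndarray (a,)
        Response loadings q per component.
    r2y_cumulative : ndarray (a,)
        Cumulative explained response variance, in percent.
    """

    columns: list[str]
    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    r2y_cumulative: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def rotations(self) -> np.ndarray:
        """W* = W (P^T W)^-1 : weights applied to undeflated X."""
        W, P = self.weights, self.loadings
        return W @ np.linalg.inv(P.T @ W)

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficients in standardized space."""
        a = self.n_components if n_components is None else n_components
        Wstar = self.weights[:, :a] @ np.linalg.inv(
            self.loadings[:, :a].T @ self.weights[:, :a]
        )
        return Wstar @ self.y_loadings[:a]

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        Xa = np.asarray(X, dtype=float)
        return Xa @ self.coefficients(n_components)


def fit_pls(X, y, n_components: int) -> PLSModelResult:
    """Fit a single-response PLS model on standardized data.

    Parameters
    ----------
    X : DataFrame or ndarray (n, p), standardized columns.
    y : Series or ndarray (n,), standardized response.
    n_components : int
        Must not exceed the rank of X.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float).copy()
    ya = np.asarray(y, dtype=float).ravel().copy()
    n, p = Xa.shape
    if ya.shape[0] != n:
        raise ValueError("X and y length mismatch")
    rank = np.linalg.matrix_rank(Xa)
    if not 1 <= n_components <= rank:
        raise ValueError(f"n_components must lie in [1, rank(X)={rank}]")

    ss_y = float(ya @ ya)
    if ss_y <= 0:
        raise ValueError("response has zero variance")

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    r2 = np.empty(n_components)

    y_res = ya.copy()
    for a in range(n_components):
        w = Xa.T @ y_res
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(
                f"degenerate component {a + 1}: no residual covariance with y"
            )
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        p_load = Xa.T @ t / tt
        q_a = float(y_res @ t / tt)
        Xa -= np.outer(t, p_load)
        y_res = y_res - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_load, t, q_a
        r2[a] = 100.0 * (1.0 - float(y_res @ y_res) / ss_y)

    return PLSModelResult(
        columns=columns,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        r2y_cumulative=r2,
    )


def vip_scores(model: PLSModelResult, n_components: int | None = None) -> pd.Series:
    """Variable importance in projection, normalized so mean(VIP^2) = 1.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ) with
    SS_a the response variance explained by component a.
    """
    a = model.n_components if n_components is None else n_components
    W = model.weights[:, :a]
    T = model.scores[:, :a]
    q = model.y_loadings[:a]
    ss = q**2 * np.einsum("na,na->a", T, T)
    total = ss.sum()
    if total <= 0:
        raise ValueError("model explains no response variance")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = W.shape[0]
    vip = np.sqrt(p * (wn**2 @ ss) / total)
    return pd.Series(vip, index=model.columns, name="VIP")


def assign_variables_to_components(
    model: PLSModelResult,
    vip_threshold: float = 1.0,
    weight_kind: str = "x_weight",
) -> pd.DataFrame:
    """Assign each predictor to the component where its weight peaks.

    Returns a table (variable, component, VIP, weight, important) sorted by
    component then descending VIP — the layout used for per-model reports.
    ``weight_kind`` selects the reported weight: the normalized X-weight on
    the assigned component (default) or the final regression coefficient.
    """
    if model.n_components < 1:
        raise ValueError("model has no components")
    W = model.weights
    comp = np.argmax(np.abs(W), axis=1)
    vip = vip_scores(model)
    if weight_kind == "x_weight":
        weight = W[np.arange(W.shape[0]), comp]
    elif weight_kind == "coefficient":
        weight = model.coefficients()
    else:
        raise ValueError(f"unknown weight_kind {weight_kind!r}")
    table = pd.DataFrame(
        {
            "variable": model.columns,
            "component": comp + 1,
            "VIP": vip.to_numpy(),
            "weight": weight,
            "important": vip.to_numpy() > vip_threshold,
        }
    )
    table = table.sort_values(
        ["component", "VIP"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    return table
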