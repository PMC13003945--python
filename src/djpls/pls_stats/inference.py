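"""Model-level inference: latent-variable regression p-values and the
noncentral-F a-priori power computation for sample-size planning.

The PLS model is approximated by a multiple regression of the response on
its latent-variable scores; the reported p-value is the overall F test of
that regression.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["model_p_value", "f_test_power", "required_sample_size"]


def model_p_value(scores: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Overall F-test p-value of y on the first c scores, for c = 1..n_components.

    df1 = c, df2 = n - c - 1; an intercept is always included.

    Raises ``ValueError`` when the largest requested model leaves no
    residual degrees of freedom.
    """
    T = np.asarray(scores, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.shape[0]
    if T.ndim != 2 or T.shape[0] != n:
        raise ValueError("scores must be (n, a) matching y")
    if not 1 <= n_components <= T.shape[1]:
        raise ValueError("n_components outside the available score columns")
    if n - n_components - 1 <= 0:
        raise ValueError("no residual degrees of freedom (df2 <= 0)")

    yc = yv - yv.mean()
    tss = float(yc @ yc)
    out = np.empty(n_components)
    for c in range(1, n_components + 1):
        D = np.column_stack([np.ones(n), T[:, :c]])
        beta, _, _, _ = np.linalg.lstsq(D, yv, rcond=None)
        resid = yv - D @ beta
        rss = float(resid @ resid)
        df1, df2 = c, n - c - 1
        if tss <= rss:  # no explained variance
            out[c - 1] = 1.0
            continue
        if rss <= 1e-300 * tss:
            out[c - 1] = 0.0
            continue
        F = ((tss - rss) / df1) / (rss / df2)
        out[c - 1] = float(stats.f.sf(F, df1, df2))
    return out


def f_test_power(
    n: int, f2: float, n_predictors: int, alpha: float = 0.05
) -> float:
    """Power of the overall F test for R^2 deviation from zero.

    df1 = n_predictors, df2 = n - n_predictors - 1, noncentrality
    lambda = f2 * n.
    """
    df2 = n - n_predictors - 1
    if df2 <= 0:
        return 0.0
    crit = stats.f.isf(alpha, n_predictors, df2)
    return float(stats.ncf.sf(crit, n_predictors, df2, f2 * n))


def required_sample_size(
    f2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_predictors: int = 4,
    max_n: int = 100000,
) -> int:
    """Smallest N whose noncentral-F power reaches the target.

    Matches the usual a-priori power computation for multiple regression
    (R^2 deviation from zero) with ``n_predictors`` predictors.
    """
    if f2 <= 0:
        raise ValueError("effect size f2 must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(n_predictors + 2, max_n + 1):
        if f_test_power(n, f2, n_predictors, alpha) >= power:
            return n
    raise ValueError(f"target power not reachable with N <= {max_n}")
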