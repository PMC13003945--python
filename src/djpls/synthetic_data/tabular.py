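"""Tabular datasets with known latent structure for PLS validation.

The generative model is X = T P^T + E, y = T q + f with independent
standard-normal latent scores T, so the population R^2 of y on the
latents is q'q / (q'q + noise_y^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LatentTabularTruth", "default_latent_truth", "generate_pls_dataset"]


@dataclass(frozen=True)
class LatentTabularTruth:
    """Ground truth of one synthetic predictor table.

    ``loading_matrix`` has shape (n_predictors, n_latent); predictors whose
    loading row is entirely zero are pure noise columns.
    """

    n_samples: int
    n_predictors: int
    n_latent: int
    loading_matrix: np.ndarray
    response_coefficients: np.ndarray
    noise_sd: float
    noise_y_sd: float
    seed: int

    def __post_init__(self) -> None:
        P = np.asarray(self.loading_matrix, dtype=float)
        q = np.asarray(self.response_coefficients, dtype=float)
        object.__setattr__(self, "loading_matrix", P)
        object.__setattr__(self, "response_coefficients", q)
        if P.shape != (self.n_predictors, self.n_latent):
            raise ValueError(
                f"loading matrix shape {P.shape} does not match "
                f"(n_predictors={self.n_predictors}, n_latent={self.n_latent})"
            )
        if q.shape != (self.n_latent,):
            raise ValueError("response_coefficients must have length n_latent")
        if self.n_samples < self.n_latent + 2:
            raise ValueError("need n_samples >= n_latent + 2")
        if np.linalg.matrix_rank(P) < self.n_latent:
            raise ValueError("loading matrix must have full column rank")
        if self.noise_sd < 0 or self.noise_y_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def population_r2(self) -> float:
        """R^2 of y on the latent scores implied by the stored coefficients."""
        signal = float(self.response_coefficients @ self.response_coefficients)
        return signal / (signal + self.noise_y_sd**2)

    @property
    def loading_variables(self) -> np.ndarray:
        """Indices of predictors with a nonzero loading row."""
        return np.nonzero(np.any(self.loading_matrix != 0.0, axis=1))[0]


def default_latent_truth(
    n_samples: int = 43,
    n_predictors: int = 44,
    n_latent: int = 3,
    population_r2: float = 0.9,
    block_sizes: tuple[int, ...] = (20, 8, 3),
    loading_value: float = 1.0,
    noise_sd: float = 0.28,
    seed: int = 0,
) -> LatentTabularTruth:
    """A block-structured truth: disjoint predictor blocks load each latent.

    Block sizes are deliberately unequal: after per-column standardization
    the relevant covariance eigenvalues scale with block size, and the
    separation is what makes every latent require its own PLS component
    (equal blocks collapse onto one or two components).  Predictors beyond
    the blocks are pure noise columns.  The response noise SD is set from
    the requested population R^2.
    """
    if len(block_sizes) != n_latent:
        raise ValueError("need one block size per latent")
    if sum(block_sizes) > n_predictors:
        raise ValueError("blocks do not fit into n_predictors")
    P = np.zeros((n_predictors, n_latent))
    start = 0
    for a, size in enumerate(block_sizes):
        P[start : start + size, a] = loading_value
        start += size
    q = np.array([0.8 + 0.15 * a for a in range(n_latent)])
    signal = float(q @ q)
    if not 0 < population_r2 < 1:
        raise ValueError("population_r2 must lie in (0, 1)")
    noise_y = np.sqrt(signal * (1.0 - population_r2) / population_r2)
    return LatentTabularTruth(
        n_samples=n_samples,
        n_predictors=n_predictors,
        n_latent=n_latent,
        loading_matrix=P,
        response_coefficients=q,
        noise_sd=noise_sd,
        noise_y_sd=float(noise_y),
        seed=seed,
    )


def generate_pls_dataset(
    truth: LatentTabularTruth,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Draw (X, y, T) from the stored truth; bit-reproducible under the seed."""
    rng = np.random.default_rng(truth.seed)
    T = rng.standard_normal((truth.n_samples, truth.n_latent))
    E = rng.standard_normal((truth.n_samples, truth.n_predictors)) * truth.noise_sd
    f = rng.standard_normal(truth.n_samples) * truth.noise_y_sd
    X = T @ truth.loading_matrix.T + E
    y = T @ truth.response_coefficients + f
    cols = [f"x{j:02d}" for j in range(truth.n_predictors)]
    return (
        pd.DataFrame(X, columns=cols),
        pd.Series(y, name="y"),
        T,
    )
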