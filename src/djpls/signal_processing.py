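"""Filtering and timebase alignment for marker and force-plate channels.

All channels are represented as :class:`SampledSignal`, a uniformly sampled
array with an explicit rate and start time.  Smoothing follows the classic
biomechanics recipe: a fourth-order (dual-pass second-order) zero-lag
Butterworth low-pass filter, with the cutoff either fixed (20 Hz default)
or chosen by Winter-style residual analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "SampledSignal",
    "butterworth_zero_lag",
    "residual_analysis_cutoff",
    "align_and_resample",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled multichannel signal.

    Parameters
    ----------
    values : ndarray, shape (n,) or (n, c)
        Sample values; first axis is time.
    rate_hz : float
        Sampling rate, > 0.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if values.ndim not in (1, 2):
            raise ValueError("values must be 1-D or 2-D (time x channels)")
        if not np.all(np.isfinite(values)):
            raise ValueError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate_hz

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.rate_hz

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t``."""
        i = int(round((t - self.t0) * self.rate_hz))
        return min(max(i, 0), len(self) - 1)

    def crop(self, t_start: float, t_stop: float) -> "SampledSignal":
        i0 = self.index_at(t_start)
        i1 = self.index_at(t_stop)
        if i1 <= i0:
            raise ValueError("empty crop interval")
        return replace(
            self, values=self.values[i0 : i1 + 1], t0=self.t0 + i0 / self.rate_hz
        )


# Dual-pass correction factor for a second-order Butterworth run forward and
# backward: (2**(1/2) - 1)**(-1/4), applied to the design cutoff when the
# corrected variant is requested.
_DUAL_PASS_CORRECTION = (2.0 ** 0.5 - 1.0) ** -0.25


def butterworth_zero_lag(
    signal: SampledSignal,
    cutoff_hz: float,
    correct_cutoff: bool = False,
) -> SampledSignal:
    """Fourth-order zero-lag Butterworth low-pass filter.

    A second-order low-pass is applied forward and backward (``filtfilt``),
    giving a fourth-order, zero-phase effective response whose amplitude at
    the single-pass -3 dB frequency is 0.5.

    Parameters
    ----------
    signal : SampledSignal
    cutoff_hz : float
        Design cutoff; must sit strictly below the Nyquist frequency.
    correct_cutoff : bool
        If True, raise the design cutoff by the dual-pass correction factor
        so the *effective* -3 dB point lands at ``cutoff_hz``.
    """
    nyq = signal.rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq}) Hz"
        )
    order = 2  # per pass; 4th order effective
    if len(signal) < 3 * (order + 1):
        raise ValueError("signal too short for stable zero-lag filtering")
    design = cutoff_hz * (_DUAL_PASS_CORRECTION if correct_cutoff else 1.0)
    design = min(design, 0.99 * nyq)
    b, a = sps.butter(order, design / nyq, btype="low")
    # Reflective (even) padding of roughly one settling length per end.
    settle = int(np.ceil(3.0 * signal.rate_hz / cutoff_hz))
    padlen = min(len(signal) - 1, max(settle, 3 * (order + 1)))
    filtered = sps.filtfilt(b, a, signal.values, axis=0, padtype="even", padlen=padlen)
    return replace(signal, values=filtered)


def residual_analysis_cutoff(
    signal: SampledSignal,
    candidate_cutoffs_hz,
    noise_region_fraction: float = 1.0 / 3.0,
) -> float:
    """Select a low-pass cutoff by Winter-style residual analysis.

    The RMS residual between the raw signal and its filtered version is
    computed for each candidate cutoff.  A straight line is fitted to the
    high-frequency (noise-dominated) tail of the residual curve — by default
    the upper third of the candidate range — and the selected cutoff is the
    smallest candidate whose residual does not exceed that line's intercept
    at zero frequency.

    Returns the selected cutoff in Hz.  Degenerate residual curves (no
    linear tail to speak of: pure noise or pure DC) produce a warning and
    the boundary candidate.
    """
    cutoffs = np.sort(np.asarray(list(candidate_cutoffs_hz), dtype=float))
    if cutoffs.size < 4:
        raise ValueError("need at least 4 candidate cutoffs")
    if cutoffs[0] > 2.0 or cutoffs[-1] < 30.0:
        raise ValueError("candidate cutoffs must span at least [2, 30] Hz")

    x = signal.values if signal.values.ndim == 2 else signal.values[:, None]
    residuals = np.empty(cutoffs.size)
    for i, fc in enumerate(cutoffs):
        filt = butterworth_zero_lag(signal, fc).values
        filt = filt if filt.ndim == 2 else filt[:, None]
        residuals[i] = np.sqrt(np.mean((x - filt) ** 2))

    scale = max(np.sqrt(np.mean(x**2)), np.finfo(float).tiny)
    if residuals.max() < 1e-12 * scale:
        warnings.warn(
            "residual curve is flat (signal fully below all candidates); "
            "returning minimum candidate",
            RuntimeWarning,
        )
        return float(cutoffs[0])

    n_tail = max(int(np.ceil(cutoffs.size * noise_region_fraction)), 2)
    tail_f, tail_r = cutoffs[-n_tail:], residuals[-n_tail:]
    slope, intercept = np.polyfit(tail_f, tail_r, 1)
    if slope > 0:
        warnings.warn(
            "residual curve has no decreasing linear tail; "
            "returning minimum candidate",
            RuntimeWarning,
        )
        return float(cutoffs[0])

    # Smallest candidate already at/below the zero-frequency noise intercept.
    ok = residuals <= intercept + 1e-9 * scale
    if not np.any(ok):
        warnings.warn(
            "residuals never reach the noise-line intercept; "
            "returning maximum candidate",
            RuntimeWarning,
        )
        return float(cutoffs[-1])
    return float(cutoffs[np.argmax(ok)])


def align_and_resample(
    markers: SampledSignal, forces: SampledSignal
) -> tuple[SampledSignal, SampledSignal]:
    """Interpolate a kinematic signal onto the force-plate timebase.

    Cubic-spline interpolation of the (slower) marker signal at the force
    sample instants over the overlapping time range; the force signal is
    cropped to the same range.  Returns ``(markers_on_force_timebase,
    forces_cropped)``.
    """
    t_lo = max(markers.t0, forces.t0)
    t_hi = min(markers.times[-1], forces.times[-1])
    if t_hi <= t_lo:
        raise ValueError("marker and force time ranges do not overlap")
    if markers.rate_hz == forces.rate_hz and abs(markers.t0 - forces.t0) < 1e-12:
        return markers, forces

    i0 = int(np.ceil((t_lo - forces.t0) * forces.rate_hz - 1e-9))
    i1 = int(np.floor((t_hi - forces.t0) * forces.rate_hz + 1e-9))
    t_new = forces.t0 + np.arange(i0, i1 + 1) / forces.rate_hz
    spline = CubicSpline(markers.times, markers.values, axis=0)
    resampled = SampledSignal(spline(t_new), forces.rate_hz, t_new[0])
    cropped = SampledSignal(forces.values[i0 : i1 + 1], forces.rate_hz, t_new[0])
    return resampled, cropped
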