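"""Zero-lag Butterworth smoothing and residual-analysis cutoff selection.

Coordinate time series are conditioned with the convention standard in
biomechanics: a 2nd-order low-pass Butterworth filter applied forward and
backward (net 4th order, zero phase lag), with the per-pass design cutoff
raised by the dual-pass correction factor so the -3 dB point of the combined
response sits at the requested cutoff.  The default cutoff is 7 Hz; it can
also be selected automatically from the data by residual analysis (Winter's
procedure): the RMS raw-vs-filtered residual is computed over a grid of
candidate cutoffs, a straight line is fitted to the noise-dominated
high-frequency tail, and the chosen cutoff is where the residual curve meets
the line's zero-frequency intercept (the noise-floor estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import FilterError

__all__ = [
    "FilterSpec",
    "dual_pass_correction",
    "dual_pass_gain",
    "butter_lowpass_zerolag",
    "residual_analysis_cutoff",
]


@dataclass
class FilterSpec:
    """Low-pass filter settings: cutoff (Hz), net order, sampling rate (Hz)."""

    fc: float = 7.0
    order_net: int = 4
    fs: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.fc < self.fs / 2:
            raise FilterError(f"fc must lie in (0, fs/2), got fc={self.fc}, fs={self.fs}")
        if self.order_net % 2 or self.order_net < 2:
            raise FilterError(f"order_net must be a positive even number, got {self.order_net}")


def dual_pass_correction(order_per_pass: int = 2, passes: int = 2) -> float:
    """Factor by which the design cutoff is raised for multi-pass filtering.

    For a Butterworth filter of order n applied p times the -3 dB point of the
    combined magnitude falls below the single-pass cutoff; dividing the design
    cutoff by ``(2**(1/p) - 1)**(1/(2n))`` restores it (approx. 0.802 for a
    dual-pass 2nd-order filter).
    """
    return float((2.0 ** (1.0 / passes) - 1.0) ** (1.0 / (2 * order_per_pass)))


def dual_pass_gain(f: np.ndarray | float, fc: float, order_net: int = 4) -> np.ndarray | float:
    """Analytic magnitude response of the corrected dual-pass filter at ``f`` Hz."""
    n = order_net // 2
    fc_design = fc / dual_pass_correction(n, 2)
    ratio = np.asarray(f, dtype=float) / fc_design
    return 1.0 / (1.0 + ratio ** (2 * n))


def butter_lowpass_zerolag(series: np.ndarray, spec: FilterSpec, axis: int = -1) -> np.ndarray:
    """Zero-lag low-pass filter a series (forward-backward Butterworth).

    The per-pass order is ``spec.order_net / 2``; the cutoff correction keeps
    the -3 dB point of the dual pass at ``spec.fc``.  Edges are handled by
    odd reflection padding.  Output length equals input length.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[axis]
    if n <= 6 * spec.order_net:
        raise FilterError(
            f"series length {n} too short for net order {spec.order_net} "
            f"(need > {6 * spec.order_net} samples)"
        )
    if np.isnan(series).any():
        raise FilterError("series contains NaN; gap-fill before smoothing")
    order = spec.order_net // 2
    fc_design = spec.fc / dual_pass_correction(order, 2)
    wn = fc_design / (spec.fs / 2)
    if wn >= 1.0:
        raise FilterError(
            f"corrected cutoff {fc_design:.2f} Hz reaches the Nyquist rate"
        )
    b, a = butter(order, wn)
    padlen = min(3 * spec.order_net * 2, n - 1)
    return filtfilt(b, a, series, axis=axis, padtype="odd", padlen=padlen)


def residual_analysis_cutoff(
    series: np.ndarray,
    fs: float,
    fc_grid: np.ndarray | None = None,
    tail_fraction: float = 0.4,
    fallback_fc: float = 7.0,
) -> float:
    """Select a cutoff frequency by residual analysis.

    Returns the frequency at which the RMS residual between the raw and
    filtered series equals the noise level estimated by extrapolating a line
    through the high-frequency tail of the residual curve to 0 Hz.  A
    noiseless series (noise estimate indistinguishable from zero) returns the
    top of the grid with a warning; a curve admitting no intersection falls
    back to ``fallback_fc`` with a warning.
    """
    series = np.asarray(series, dtype=float)
    if fc_grid is None:
        fc_grid = np.linspace(1.0, 0.4 * fs, 40)
    fc_grid = np.asarray(fc_grid, dtype=float)
    if fc_grid.size < 10:
        raise FilterError(f"fc_grid needs >= 10 points, got {fc_grid.size}")
    if fc_grid.min() <= 0 or fc_grid.max() >= fs / 2:
        raise FilterError("fc_grid must lie within (0, fs/2)")
    fc_grid = np.sort(fc_grid)

    residuals = np.empty(fc_grid.size)
    for i, fc in enumerate(fc_grid):
        filtered = butter_lowpass_zerolag(series, FilterSpec(fc=fc, fs=fs))
        residuals[i] = np.sqrt(np.mean((series - filtered) ** 2))

    n_tail = max(2, int(round(tail_fraction * fc_grid.size)))
    slope, intercept = np.polyfit(fc_grid[-n_tail:], residuals[-n_tail:], 1)

    # a noise-floor estimate this far below the signal scale is numerical
    # residue (filter leakage), not measurement noise
    scale = np.sqrt(np.mean(series**2)) or 1.0
    if intercept <= 1e-4 * scale:
        warnings.warn(
            "residual analysis found no measurable noise; returning the top "
            "of the cutoff grid",
            stacklevel=2,
        )
        return float(fc_grid[-1])

    if residuals[0] <= intercept:
        warnings.warn(
            "residuals are below the noise estimate across the whole grid; "
            "returning the top of the cutoff grid",
            stacklevel=2,
        )
        return float(fc_grid[-1])
    if residuals[-1] > intercept:
        warnings.warn(
            f"residual curve never meets the noise level; falling back to "
            f"{fallback_fc} Hz",
            stacklevel=2,
        )
        return float(fallback_fc)

    # Residuals decrease with fc; find the first crossing of the noise level.
    above = residuals > intercept
    i = int(np.nonzero(above)[0][-1])  # last grid point above the line
    f0, f1 = fc_grid[i], fc_grid[i + 1]
    r0, r1 = residuals[i], residuals[i + 1]
    if r0 == r1:
        return float(f1)
    return float(f0 + (r0 - intercept) * (f1 - f0) / (r0 - r1))
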