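"""ECG denoising: polynomial baseline removal and Savitzky-Golay smoothing.

Baseline wander is removed by subtracting the least-squares polynomial
trend (degree 13 by default). The detrended trace is then smoothed with
a Savitzky-Golay filter (window 9, order 3 by default), which replaces
each sample by the center value of a local least-squares polynomial fit
and therefore preserves P-QRS-T morphology up to cubic shape while
attenuating broadband noise.

The degree-13 fit is computed against a time axis rescaled to [-1, 1]:
a Vandermonde system on raw sample indices is catastrophically
ill-conditioned at that degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_filter

from afdet.signal import EcgSignal


@dataclass(frozen=True)
class DetrendConfig:
    """Degree of the least-squares polynomial trend. Default 13."""

    order: int = 13

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("polynomial order must be >= 0")


@dataclass(frozen=True)
class SmoothConfig:
    """Savitzky-Golay window length (odd) and fit order. Default 9 / 3."""

    window: int = 9
    order: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("SG window length must be odd")
        if not 0 <= self.order < self.window:
            raise ValueError("SG order must satisfy 0 <= order < window")


def remove_baseline(signal: EcgSignal, cfg: DetrendConfig = DetrendConfig()) -> EcgSignal:
    """Subtract the best least-squares polynomial of degree ``cfg.order``."""
    if signal.n <= cfg.order + 1:
        raise ValueError(
            f"signal length {signal.n} too short for degree-{cfg.order} detrending"
        )
    # rescale the abscissa to [-1, 1] for conditioning
    x = np.linspace(-1.0, 1.0, signal.n)
    coeffs = npoly.polyfit(x, signal.samples, deg=cfg.order)
    trend = npoly.polyval(x, coeffs)
    return signal.with_samples(signal.samples - trend)


def sg_smooth(signal: EcgSignal, cfg: SmoothConfig = SmoothConfig()) -> EcgSignal:
    """Savitzky-Golay smoothing; segment length is preserved.

    Edges use polynomial extension (the first/last window's fit evaluated
    at the boundary positions), scipy's ``mode='interp'``.
    """
    if signal.n < cfg.window:
        raise ValueError(f"signal length {signal.n} shorter than SG window {cfg.window}")
    smoothed = savgol_filter(
        signal.samples, window_length=cfg.window, polyorder=cfg.order, mode="interp"
    )
    return signal.with_samples(smoothed)


def denoise(
    signal: EcgSignal,
    detrend_cfg: DetrendConfig = DetrendConfig(),
    smooth_cfg: SmoothConfig = SmoothConfig(),
) -> EcgSignal:
    """Full denoising chain: baseline removal then SG smoothing."""
    return sg_smooth(remove_baseline(signal, detrend_cfg), smooth_cfg)
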