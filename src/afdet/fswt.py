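"""Frequency slice wavelet transform (FSWT).

The FSWT is a windowed-Fourier-type time-frequency transform whose
frequency-domain window ("frequency slice function" p-hat) is rescaled
with the observation frequency. For an observation frequency omega and
a time-frequency resolution factor k > 0, the transform of f with
spectrum f-hat is

    W_f(t, omega) = (1/2pi) Int f-hat(u) p-hat*( k (u - omega)/omega ) e^{iut} du,

i.e. the slice window is centred at omega with width omega/k, giving
wavelet-like constant-Q behaviour while retaining a slice-independent
inverse: provided p-hat(0) = 1,

    f(t) = (1/2pi) Int_{w1}^{w2} Int_{t1}^{t2} W_f(tau, omega) e^{i omega (t - tau)} dtau domega,

so any time-frequency rectangle can be reconstructed in isolation.

Discretization: the forward transform is computed per observation
frequency as an inverse DFT of f-hat(u) . p-hat*(k(u-omega)/omega)
over the signal's own DFT grid (O(N_omega . N log N)). The frequency
grid consists of the DFT bins j/T, j = 1, 2, ..., spaced 1/duration;
the DC bin is excluded because sigma = omega/k collapses to zero width
there (and baseline content is removed in preprocessing). Only
non-negative observation frequencies are stored; the inverse doubles
the real part of the positive-frequency integral, the standard
analytic-signal convention for real inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from afdet.signal import EcgSignal


class SliceFunctionKind(str, enum.Enum):
    """The three standard frequency slice functions; all satisfy p-hat(0)=1."""

    ABS_EXP = "abs_exp"  # e^{-|w|}
    GAUSSIAN = "gaussian"  # e^{-w^2/2}
    CAUCHY = "cauchy"  # 1/(1+w^2)


def slice_hat(
    omega: np.ndarray | float, kind: SliceFunctionKind | str = SliceFunctionKind.GAUSSIAN
) -> np.ndarray | float:
    """Evaluate the frequency slice function at normalized argument ``omega``."""
    kind = SliceFunctionKind(kind)
    w = np.asarray(omega, dtype=float)
    if kind is SliceFunctionKind.ABS_EXP:
        out = np.exp(-np.abs(w))
    elif kind is SliceFunctionKind.GAUSSIAN:
        out = np.exp(-(w**2) / 2.0)
    else:
        out = 1.0 / (1.0 + w**2)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class FswtConfig:
    """Observation band, resolution factor and slice function.

    f_min/f_max : observation frequency band in Hz (default 0-80, the
        band that contains essentially all P-QRS-T and fibrillatory
        energy at clinical sampling rates).
    k : dimensionless time-frequency resolution factor; the slice width
        at observation frequency omega is omega/k, so larger k means
        sharper frequency resolution. Default 3.
    slice : one of the named slice functions, or any callable
        p-hat(w) with p-hat(0) = 1 (may return complex values).
    """

    f_min: float = 0.0
    f_max: float = 80.0
    k: float = 3.0
    slice: SliceFunctionKind | str | Callable = SliceFunctionKind.GAUSSIAN

    def __post_init__(self) -> None:
        if not 0 <= self.f_min < self.f_max:
            raise ValueError("need 0 <= f_min < f_max")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not callable(self.slice):
            object.__setattr__(self, "slice", SliceFunctionKind(self.slice))

    def slice_values(self, omega: np.ndarray) -> np.ndarray:
        if callable(self.slice):
            return np.asarray(self.slice(omega))
        return np.asarray(slice_hat(omega, self.slice))


@dataclass(frozen=True)
class TimeFrequencySpectrum:
    """Complex FSWT matrix: rows = sample times, columns = grid frequencies."""

    values: np.ndarray  # complex, shape (n_times, n_freqs)
    time_grid: np.ndarray  # s
    freq_grid: np.ndarray  # Hz
    config: FswtConfig
    fs: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def _freq_grid(n: int, fs: float, config: FswtConfig) -> np.ndarray:
    """DFT-bin observation frequencies in (f_min, f_max], DC excluded."""
    df = fs / n  # = 1/duration
    j_lo = int(np.floor(config.f_min / df)) + 1
    j_hi = int(np.floor(config.f_max / df + 1e-9))
    if j_hi < j_lo:
        raise ValueError("observation band contains no frequency bins")
    return np.arange(j_lo, j_hi + 1) * df


def fswt_forward(signal: EcgSignal, config: FswtConfig = FswtConfig()) -> TimeFrequencySpectrum:
    """Forward FSWT of a sampled segment.

    Returns a matrix with one row per input sample and one column per
    DFT-bin frequency in the observation band. For a 5 s segment at
    250 Hz analysed over 0-80 Hz this is 1250 x 400.
    """
    if signal.n < 2:
        raise ValueError("signal must have at least 2 samples")
    if config.f_max > signal.fs / 2:
        raise ValueError("f_max exceeds the Nyquist frequency")
    x = signal.samples
    n = x.size
    freqs = _freq_grid(n, signal.fs, config)
    u = np.fft.fftfreq(n, d=1.0 / signal.fs)  # signed DFT frequencies, Hz
    F = np.fft.fft(x)

    # (n_freqs, n) slice windows: conj(p-hat(k (u - omega) / omega))
    arg = config.k * (u[None, :] - freqs[:, None]) / freqs[:, None]
    windows = np.conj(config.slice_values(arg))
    W = np.fft.ifft(F[None, :] * windows, axis=1).T  # (n_times, n_freqs)
    return TimeFrequencySpectrum(
        values=W,
        time_grid=signal.times,
        freq_grid=freqs,
        config=config,
        fs=signal.fs,
    )


def fswt_inverse(
    spectrum: TimeFrequencySpectrum,
    t1: float | None = None,
    t2: float | None = None,
    w1: float | None = None,
    w2: float | None = None,
) -> EcgSignal:
    """Reconstruct the signal content of a time-frequency rectangle.

    The double integral over [t1, t2] x [w1, w2] is evaluated on the
    stored grids; the positive-frequency result is doubled and the real
    part taken (the stored grid holds only non-negative frequencies of a
    real input). With the full stored region this reconstructs the
    band-limited content of the original segment; restricting [w1, w2]
    acts as a band-selective filter, restricting [t1, t2] as a time gate.
    """
    tg, fg = spectrum.time_grid, spectrum.freq_grid
    t1 = tg[0] if t1 is None else t1
    t2 = tg[-1] if t2 is None else t2
    w1 = fg[0] if w1 is None else w1
    w2 = fg[-1] if w2 is None else w2
    rows = (tg >= t1 - 1e-12) & (tg <= t2 + 1e-12)
    cols = (fg >= w1 - 1e-12) & (fg <= w2 + 1e-12)
    if not rows.any() or not cols.any():
        raise ValueError("empty reconstruction region")

    W = spectrum.values[np.ix_(rows, cols)]  # (n_tau, n_w)
    tau = tg[rows]
    f_sel = fg[cols]
    n = tg.size
    # inner integral over tau: G(omega) = sum_tau W(tau, omega) e^{-i omega tau} dtau
    # combined with the omega integral the discrete measure dtau*df = 1/n
    G = np.einsum("tw,tw->w", W, np.exp(-2j * np.pi * f_sel[None, :] * tau[:, None]))
    recon = np.exp(2j * np.pi * np.outer(tg, f_sel)) @ G
    x = (2.0 / n) * np.real(recon)
    return EcgSignal(samples=x, fs=spectrum.fs)
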