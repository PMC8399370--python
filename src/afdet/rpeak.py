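"""Pan-Tompkins QRS detection.

The classic real-time detector: 5-15 Hz bandpass to isolate QRS energy,
five-point derivative to emphasise slope, squaring, 150 ms moving-window
integration, then adaptive dual-threshold peak selection with a 200 ms
refractory period and a search-back pass (triggered when an RR interval
exceeds 1.66x the running RR average, re-examined at half threshold).
Detections are refined to the local maximum of the bandpassed signal
within +/-50 ms.

The filter stages are designed directly at the signal's sampling rate
rather than resampling to the 200 Hz assumed by the original difference
equations. Because every threshold adapts to running peak estimates,
detections are invariant to positive rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from afdet.signal import EcgSignal

REFRACTORY_S = 0.200
INTEGRATION_WINDOW_S = 0.150
SEARCHBACK_RR_FACTOR = 1.66
BANDPASS_HZ = (5.0, 15.0)
REFINE_RADIUS_S = 0.050


@dataclass(frozen=True)
class RPeakSet:
    """Detected R-peak sample positions (strictly ascending) and their fs."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("R-peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    @property
    def rr_intervals(self) -> np.ndarray:
        """RR intervals in seconds (empty if fewer than two peaks)."""
        return np.diff(self.times)


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    b, a = butter(2, [BANDPASS_HZ[0] / nyq, BANDPASS_HZ[1] / nyq], btype="band")
    return filtfilt(b, a, x)


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    # five-point derivative, H(z) = (fs/8)(-z^-2 - 2z^-1 + 2z + z^2)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    return np.convolve(x, kernel[::-1], mode="same")


def _integrate(x: np.ndarray, fs: float) -> np.ndarray:
    w = max(int(round(INTEGRATION_WINDOW_S * fs)), 1)
    return np.convolve(x, np.ones(w) / w, mode="same")


def detect_rpeaks(signal: EcgSignal) -> RPeakSet:
    """Detect R peaks in a (preferably denoised) ECG segment.

    Requires at least 2 s of signal for threshold initialisation. A
    signal with no QRS energy yields an empty peak set, not an error.
    """
    if signal.duration < 2.0:
        raise ValueError("Pan-Tompkins needs at least 2 s of signal")
    fs = signal.fs
    x = signal.samples - np.mean(signal.samples)
    band = _bandpass(x, fs)
    integrated = _integrate(_derivative(band, fs) ** 2, fs)

    if not np.any(integrated > 0):
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = find_peaks(integrated, distance=refractory)
    if cand.size == 0:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)

    # adaptive dual thresholds on the integrated waveform
    init = integrated[: int(2 * fs)]
    spki = float(np.max(init)) * 0.5  # running signal-peak estimate
    npki = float(np.mean(init)) * 0.5  # running noise-peak estimate
    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in cand:
        peak = integrated[idx]
        if peak > threshold1():
            accepted.append(int(idx))
            spki = 0.125 * peak + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append((accepted[-1] - accepted[-2]) / fs)
                rr_history[:] = rr_history[-8:]
        else:
            npki = 0.125 * peak + 0.875 * npki
            # search-back: if the gap since the last accepted peak is long,
            # re-admit the candidate at the lower threshold
            if accepted and rr_history:
                gap = (idx - accepted[-1]) / fs
                if gap > SEARCHBACK_RR_FACTOR * float(np.mean(rr_history)):
                    if peak > 0.5 * threshold1():
                        accepted.append(int(idx))
                        spki = 0.25 * peak + 0.75 * spki
                        rr_history.append((accepted[-1] - accepted[-2]) / fs)
                        rr_history[:] = rr_history[-8:]

    if not accepted:
        return RPeakSet(indices=np.array([], dtype=int), fs=fs)

    # refine each detection to the local max of the bandpassed signal
    radius = int(round(REFINE_RADIUS_S * fs))
    refined = []
    for idx in accepted:
        lo = max(idx - radius, 0)
        hi = min(idx + radius + 1, band.size)
        refined.append(lo + int(np.argmax(band[lo:hi])))
    refined_arr = np.array(sorted(set(refined)), dtype=int)

    # enforce the refractory period after refinement (keep the larger peak)
    keep: list[int] = []
    for idx in refined_arr:
        if keep and idx - keep[-1] < refractory:
            if band[idx] > band[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return RPeakSet(indices=np.array(keep, dtype=int), fs=fs)
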