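"""Time-frequency matrix to 1D feature vector.

The classifier input is built from the FSWT magnitude matrix in three
steps: per-segment min-max quantization to the 0-255 gray-level range
(making features invariant to overall amplitude), non-overlapping M x N
average pooling (M time rows by N frequency columns per block), and
row-major flattening. A 1250 x 400 matrix pooled with a 10 x 5 window
becomes 125 x 80 and flattens to 10,000 feature points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from afdet.fswt import FswtConfig, TimeFrequencySpectrum, fswt_forward
from afdet.signal import EcgSignal


@dataclass(frozen=True)
class PoolingWindow:
    """Average-pooling block: ``m`` time rows by ``n`` frequency columns."""

    m: int = 10
    n: int = 5

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("pooling window dimensions must be >= 1")


@dataclass(frozen=True)
class FeatureVector:
    """Flattened pooled quantized magnitudes, each value in [0, 255]."""

    values: np.ndarray
    segment_id: str | None = None
    window: PoolingWindow | None = None
    fswt_config: FswtConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


def quantize_magnitude(spectrum: TimeFrequencySpectrum) -> np.ndarray:
    """Min-max scale |W| to integers 0..255 (per segment).

    A constant magnitude matrix (including all-zero) maps to all zeros.
    """
    mag = spectrum.magnitude
    lo, hi = float(mag.min()), float(mag.max())
    if hi == lo:
        return np.zeros(mag.shape, dtype=np.int64)
    scaled = 255.0 * (mag - lo) / (hi - lo)
    return np.rint(scaled).astype(np.int64)


def average_pool(matrix: np.ndarray, window: PoolingWindow) -> np.ndarray:
    """Non-overlapping block means; trailing partial blocks are dropped."""
    matrix = np.asarray(matrix, dtype=float)
    rows, cols = matrix.shape
    if rows < window.m or cols < window.n:
        raise ValueError(
            f"pooling window {window.m}x{window.n} larger than matrix {rows}x{cols}"
        )
    out_r, out_c = rows // window.m, cols // window.n
    trimmed = matrix[: out_r * window.m, : out_c * window.n]
    return trimmed.reshape(out_r, window.m, out_c, window.n).mean(axis=(1, 3))


def flatten(matrix: np.ndarray) -> FeatureVector:
    """Row-major flattening of a pooled matrix into a feature vector."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot flatten an empty matrix")
    return FeatureVector(values=matrix.reshape(-1))


def featurize(
    signal: EcgSignal,
    fswt_config: FswtConfig = FswtConfig(),
    window: PoolingWindow = PoolingWindow(),
    segment_id: str | None = None,
) -> FeatureVector:
    """signal -> FSWT -> quantize -> average-pool -> flatten."""
    spectrum = fswt_forward(signal, fswt_config)
    pooled = average_pool(quantize_magnitude(spectrum), window)
    vec = flatten(pooled)
    return FeatureVector(
        values=vec.values,
        segment_id=segment_id,
        window=window,
        fswt_config=fswt_config,
    )
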