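"""The core sampled-ECG container and its CSV interchange format."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class EcgSignal:
    """A uniformly sampled single-channel ECG trace.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes in millivolts.
    fs : float
        Sampling rate in Hz.
    beat_times : ndarray of float, optional
        Ground-truth R-peak times in seconds (emitted by the synthetic
        generator so that detector tests need no manual annotation).
    label : str, optional
        Rhythm label for the whole segment ("AF" or "non-AF").
    """

    samples: np.ndarray
    fs: float
    beat_times: np.ndarray | None = field(default=None, compare=False)
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)
        if self.beat_times is not None:
            object.__setattr__(
                self, "beat_times", np.asarray(self.beat_times, dtype=float)
            )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgSignal":
        """Copy of this signal with new amplitude values (same fs/metadata)."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def to_csv(self, path: str | Path) -> None:
        """Write one mV value per line; the header comment records fs."""
        header = f"fs={self.fs}\nmV"
        np.savetxt(path, self.samples, fmt="%.9g", header=header, comments="# ")

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "EcgSignal":
        """Read a signal written by :meth:`to_csv`.

        An explicit ``fs`` overrides the value recorded in the header;
        one of the two must be available.
        """
        path = Path(path)
        header_fs = None
        with path.open() as fh:
            for line in fh:
                if line.startswith("#") and "fs=" in line:
                    header_fs = float(line.split("fs=")[1].strip())
                if not line.startswith("#"):
                    break
        if fs is None:
            fs = header_fs
        if fs is None:
            raise ValueError(f"{path}: no fs in header and none supplied")
        samples = np.loadtxt(path, comments="#", skiprows=0, ndmin=1)
        return cls(samples=samples, fs=fs)
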