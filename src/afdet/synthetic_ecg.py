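"""Synthetic normal-sinus and atrial-fibrillation ECG generator.

Emulates the two rhythm classes the detector distinguishes:

* **NSR** — full P-QRS-T morphology with near-regular RR intervals.
* **AF** — absent P wave, irregular RR intervals (high coefficient of
  variation), and a band-limited fibrillatory oscillation (f wave) in
  the 4-9 Hz band superimposed on the baseline.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T); presence or
absence of the P wave is therefore exactly controllable, which real
recordings never allow. RR intervals are log-normal with a specified
mean heart rate and coefficient of variation. The generator returns the
ground-truth beat times with every segment so that R-peak detection can
be scored without manual annotation.

This is a morphological emulator, not a physiological model: there is
no respiration modulation, no heart-rate drift, and no dynamical-system
coupling between beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from afdet.signal import EcgSignal

# Default NSR beat morphology: (amplitude mV, center offset s relative to
# the R peak, Gaussian width s) for P, Q, R, S, T.
_DEFAULT_WAVES: tuple[tuple[float, float, float], ...] = (
    (0.15, -0.17, 0.025),  # P
    (-0.10, -0.03, 0.010),  # Q
    (1.00, 0.00, 0.012),  # R
    (-0.20, 0.03, 0.010),  # S
    (0.30, 0.22, 0.050),  # T
)


@dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians beat morphology.

    ``wave_params`` lists (amplitude mV, center offset s, width s) for the
    P, Q, R, S and T components, offsets relative to the R-peak center.
    """

    wave_params: tuple[tuple[float, float, float], ...] = _DEFAULT_WAVES

    def __post_init__(self) -> None:
        params = tuple(tuple(float(v) for v in w) for w in self.wave_params)
        if any(w[2] <= 0 for w in params):
            raise ValueError("Gaussian widths must be strictly positive")
        amps = [abs(w[0]) for w in params]
        # R is by convention the third component
        if len(params) == 5 and max(amps) != abs(params[2][0]):
            raise ValueError("R component must have the largest absolute amplitude")
        object.__setattr__(self, "wave_params", params)

    def without_p(self) -> "BeatTemplate":
        """Template with the P-wave amplitude zeroed (AF morphology)."""
        waves = list(self.wave_params)
        waves[0] = (0.0, waves[0][1], waves[0][2])
        return BeatTemplate(tuple(waves))

    def render(self, t: np.ndarray, r_center: float) -> np.ndarray:
        """Evaluate the beat on the time grid ``t`` for an R peak at ``r_center``."""
        out = np.zeros_like(t)
        for amp, off, width in self.wave_params:
            if amp != 0.0:
                out += amp * np.exp(-0.5 * ((t - r_center - off) / width) ** 2)
        return out


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm-class parameters for the generator.

    kind : "NSR" or "AF"
    mean_hr : mean heart rate, beats/min
    rr_cv : coefficient of variation of the RR intervals (dimensionless)
    fwave_amp : fibrillatory-wave amplitude, mV (0 for NSR)
    fwave_band : (low, high) Hz band of the f wave, within [4, 9] Hz
    template : beat morphology; for AF the P wave is forced to zero
    """

    kind: str
    mean_hr: float = 75.0
    rr_cv: float = 0.03
    fwave_amp: float = 0.0
    fwave_band: tuple[float, float] = (4.0, 9.0)
    template: BeatTemplate = field(default_factory=BeatTemplate)

    def __post_init__(self) -> None:
        if self.kind not in ("NSR", "AF"):
            raise ValueError(f"unknown rhythm kind {self.kind!r}")
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")
        if self.kind == "NSR":
            if self.rr_cv > 0.05:
                raise ValueError("NSR rr_cv must be <= 0.05")
            if self.fwave_amp != 0:
                raise ValueError("NSR has no f wave")
        else:
            if self.rr_cv < 0.15:
                raise ValueError("AF rr_cv must be >= 0.15")
            if self.fwave_amp <= 0:
                raise ValueError("AF requires a positive f-wave amplitude")
            lo, hi = self.fwave_band
            if not (4.0 <= lo < hi <= 9.0):
                raise ValueError("fwave_band must lie within [4, 9] Hz")
            object.__setattr__(self, "template", self.template.without_p())


#: Default study conditions for the two rhythm classes.
NSR_SPEC = RhythmSpec(kind="NSR", mean_hr=75.0, rr_cv=0.03)
AF_SPEC = RhythmSpec(kind="AF", mean_hr=95.0, rr_cv=0.25, fwave_amp=0.08)


def _rr_intervals(rng: np.random.Generator, spec: RhythmSpec, total: float) -> np.ndarray:
    """Log-normal RR intervals with the spec's mean and CV, covering ``total`` s."""
    mean_rr = 60.0 / spec.mean_hr
    cv = max(spec.rr_cv, 1e-9)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean_rr) - sigma2 / 2.0
    n_guess = int(np.ceil(total / mean_rr * 2)) + 8
    rr = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_guess)
    while rr.sum() < total + 2 * mean_rr:
        rr = np.concatenate([rr, rng.lognormal(mu, np.sqrt(sigma2), size=8)])
    return rr


def _fwave(rng: np.random.Generator, spec: RhythmSpec, t: np.ndarray) -> np.ndarray:
    """Band-limited fibrillatory oscillation: 3 random-phase sinusoids in band."""
    freqs = rng.uniform(spec.fwave_band[0], spec.fwave_band[1], size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    comp = np.zeros_like(t)
    for f, ph in zip(freqs, phases):
        comp += np.sin(2 * np.pi * f * t + ph)
    # equal-power scaling: the sum carries the RMS of a single sinusoid
    # of amplitude fwave_amp, so the amplitude parameter stays honest
    comp *= spec.fwave_amp / np.sqrt(3.0)
    return comp


def generate_segment(
    spec: RhythmSpec, duration: float, fs: float, seed: int
) -> EcgSignal:
    """Generate one fixed-length ECG segment of the given rhythm class.

    Returns an :class:`EcgSignal` of exactly ``round(duration * fs)``
    samples whose ``beat_times`` attribute carries the ground-truth
    R-peak times (seconds). Deterministic for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    rr = _rr_intervals(rng, spec, duration)
    # first beat starts a fraction of one RR into the segment
    beat_times = np.cumsum(rr) - rr[0] * rng.uniform(0.1, 0.9)
    beat_times = beat_times[(beat_times >= 0) & (beat_times < duration)]

    x = np.zeros(n)
    for bt in beat_times:
        x += spec.template.render(t, bt)
    if spec.kind == "AF":
        x += _fwave(rng, spec, t)
    label = "AF" if spec.kind == "AF" else "non-AF"
    return EcgSignal(samples=x, fs=fs, beat_times=beat_times, label=label)


def fwave_component(spec: RhythmSpec, duration: float, fs: float, seed: int) -> np.ndarray:
    """The isolated f-wave component the generator would add for this seed.

    Reproduces the same random draws as :func:`generate_segment` so the
    spectral content of the fibrillatory oscillation can be verified in
    isolation, before it is summed into the beat train.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    _ = _rr_intervals(rng, spec, duration)  # consume identical draws
    _ = rng.uniform(0.1, 0.9)
    return _fwave(rng, spec, t)


def add_noise(
    signal: EcgSignal,
    baseline_amp: float = 0.0,
    baseline_freq: float = 0.3,
    powerline_amp: float = 0.0,
    powerline_freq: float = 50.0,
    white_sd: float = 0.0,
    seed: int = 0,
) -> EcgSignal:
    """Contaminate an ECG with drift, powerline interference and white noise.

    output = input + baseline_amp * sin(2π baseline_freq t)
                   + powerline_amp * sin(2π powerline_freq t)
                   + N(0, white_sd²)
    """
    if baseline_amp < 0 or powerline_amp < 0 or white_sd < 0:
        raise ValueError("noise amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    t = signal.times
    out = signal.samples.copy()
    if baseline_amp > 0:
        out = out + baseline_amp * np.sin(2 * np.pi * baseline_freq * t)
    if powerline_amp > 0:
        out = out + powerline_amp * np.sin(2 * np.pi * powerline_freq * t)
    if white_sd > 0:
        out = out + rng.normal(0.0, white_sd, size=signal.n)
    return signal.with_samples(out)
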