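"""FSWT correctness: slice functions, oracle equivalence, inversion."""

import numpy as np
import pytest

from afdet.fswt import (
    FswtConfig,
    SliceFunctionKind,
    fswt_forward,
    fswt_inverse,
    slice_hat,
)
from afdet.signal import EcgSignal


def fswt_direct(x: np.ndarray, fs: float, config: FswtConfig) -> np.ndarray:
    """Independent oracle: direct summation of the discretized transform.

    Computes the DFT by explicit summation and, for every observation
    frequency, the windowed inverse sum term by term — no FFT anywhere.
    """
    n = x.size
    m = np.arange(n)
    # signed bin frequencies in Hz; the Nyquist bin of an even-length
    # grid is negative, matching the standard DFT layout
    u = np.where(m < (n + 1) // 2, m, m - n) * fs / n
    F = np.array([np.sum(x * np.exp(-2j * np.pi * mm * m / n)) for mm in m])
    df = fs / n
    j_lo = int(np.floor(config.f_min / df)) + 1
    j_hi = int(np.floor(config.f_max / df + 1e-9))
    freqs = np.arange(j_lo, j_hi + 1) * df
    W = np.empty((n, freqs.size), dtype=complex)
    for col, omega in enumerate(freqs):
        window = np.conj(config.slice_values(config.k * (u - omega) / omega))
        for row in range(n):
            W[row, col] = np.sum(F * window * np.exp(2j * np.pi * m * row / n)) / n
    return W


class TestSliceHat:
    @pytest.mark.parametrize("kind", list(SliceFunctionKind))
    def test_unit_at_zero(self, kind):
        assert slice_hat(0.0, kind) == 1.0

    def test_closed_forms(self):
        assert slice_hat(1.0, "gaussian") == pytest.approx(np.exp(-0.5))
        assert slice_hat(1.0, "cauchy") == pytest.approx(0.5)
        assert slice_hat(-2.0, "abs_exp") == pytest.approx(np.exp(-2))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            slice_hat(1.0, "triangle")


class TestForward:
    def test_zero_signal_zero_spectrum(self):
        sp = fswt_forward(EcgSignal(np.zeros(250), 250.0))
        assert np.all(sp.values == 0)

    def test_matrix_shape_5s_250hz(self, nsr_segment):
        sp = fswt_forward(nsr_segment, FswtConfig(f_min=0, f_max=80))
        assert sp.values.shape == (1250, 400)
        assert sp.freq_grid[0] == pytest.approx(0.2)
        assert sp.freq_grid[-1] == pytest.approx(80.0)

    @pytest.mark.parametrize("kind", list(SliceFunctionKind))
    @pytest.mark.parametrize("k", [1.0, 3.0])
    def test_oracle_equivalence_small_inputs(self, kind, k):
        rng = np.random.default_rng(11)
        for n in (16, 64):
            x = rng.normal(0, 1, n)
            cfg = FswtConfig(f_min=0, f_max=40, k=k, slice=kind)
            fast = fswt_forward(EcgSignal(x, 100.0), cfg).values
            slow = fswt_direct(x, 100.0, cfg)
            assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) < 1e-8

    def test_tone_localized_within_one_bin(self):
        t = np.arange(1250) / 250.0
        sig = EcgSignal(np.sin(2 * np.pi * 10 * t), 250.0)
        sp = fswt_forward(sig, FswtConfig(k=3.0, slice="gaussian"))
        interior = (sp.time_grid >= 0.5) & (sp.time_grid <= 4.5)
        peak_freqs = sp.freq_grid[np.argmax(sp.magnitude[interior], axis=1)]
        df = sp.freq_grid[1] - sp.freq_grid[0]
        assert np.all(np.abs(peak_freqs - 10.0) <= df + 1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 128), rng.normal(0, 1, 128)
        fwd = lambda v: fswt_forward(EcgSignal(v, 250.0)).values
        lhs = fwd(2.5 * x - 1.5 * y)
        rhs = 2.5 * fwd(x) - 1.5 * fwd(y)
        assert np.max(np.abs(lhs - rhs)) <= 1e-9 * np.max(np.abs(rhs))

    def test_time_shift_covariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 128)
        m = 17
        a = np.abs(fswt_forward(EcgSignal(x, 250.0)).values)
        b = np.abs(fswt_forward(EcgSignal(np.roll(x, m), 250.0)).values)
        assert np.max(np.abs(np.roll(a, m, axis=0) - b)) < 1e-6 * a.max()

    def test_resolution_sharpens_with_k(self):
        t = np.arange(1250) / 250.0
        sig = EcgSignal(np.sin(2 * np.pi * 10 * t), 250.0)
        widths = []
        for k in (1.0, 3.0, 10.0):
            sp = fswt_forward(sig, FswtConfig(k=k))
            profile = sp.magnitude[625]  # mid-segment frequency profile
            half = profile.max() / np.sqrt(2)
            widths.append(np.sum(profile >= half))
        assert widths[0] > widths[1] > widths[2]

    def test_fmax_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            fswt_forward(EcgSignal(np.ones(100), 100.0), FswtConfig(f_max=80.0))

    def test_complex_slice_is_conjugated(self):
        # a complex-valued slice must enter as its conjugate
        phase = 0.7
        custom = lambda w: np.exp(-(w**2) / 2) * np.exp(1j * phase * np.sign(w))
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 32)
        cfg = FswtConfig(f_min=0, f_max=40, slice=custom)
        fast = fswt_forward(EcgSignal(x, 100.0), cfg).values
        slow = fswt_direct(x, 100.0, cfg)
        assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) < 1e-8


class TestInverse:
    def test_zero_spectrum_zero_signal(self):
        sp = fswt_forward(EcgSignal(np.zeros(250), 250.0))
        rec = fswt_inverse(sp)
        np.testing.assert_allclose(rec.samples, 0.0, atol=1e-12)

    def test_full_region_round_trip(self):
        t = np.arange(1250) / 250.0
        x = (
            np.sin(2 * np.pi * 1.4 * t)
            + 0.6 * np.sin(2 * np.pi * 12.2 * t + 0.5)
            + 0.3 * np.sin(2 * np.pi * 39.8 * t + 1.1)
        )
        sp = fswt_forward(EcgSignal(x, 250.0), FswtConfig(f_min=0, f_max=80))
        rec = fswt_inverse(sp)
        rel = np.linalg.norm(rec.samples - x) / np.linalg.norm(x)
        assert rel < 1e-3

    def test_band_restricted_inverse_isolates_component(self, two_tone):
        sp = fswt_forward(two_tone, FswtConfig(f_min=0, f_max=80))
        rec = fswt_inverse(sp, w1=8.0, w2=12.0)
        t = two_tone.times
        pure = np.sin(2 * np.pi * 10 * t)
        interior = slice(125, 1125)  # central 80 %
        corr = np.corrcoef(rec.samples[interior], pure[interior])[0, 1]
        assert corr > 0.99

    def test_empty_region_rejected(self, two_tone):
        sp = fswt_forward(two_tone)
        with pytest.raises(ValueError):
            fswt_inverse(sp, w1=200.0, w2=300.0)
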