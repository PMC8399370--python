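import numpy as np
import pytest

from afdet.signal import EcgSignal
from afdet.synthetic_ecg import AF_SPEC, NSR_SPEC, generate_segment


@pytest.fixture(scope="session")
def nsr_segment() -> EcgSignal:
    """Clean 5 s normal-sinus segment at 250 Hz."""
    return generate_segment(NSR_SPEC, 5.0, 250.0, seed=1)


@pytest.fixture(scope="session")
def af_segment() -> EcgSignal:
    """Clean 5 s AF segment at 250 Hz."""
    return generate_segment(AF_SPEC, 5.0, 250.0, seed=1)


@pytest.fixture(scope="session")
def two_tone() -> EcgSignal:
    """5 Hz + 10 Hz two-tone test signal, 5 s at 250 Hz."""
    t = np.arange(1250) / 250.0
    x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 10 * t)
    return EcgSignal(samples=x, fs=250.0)
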