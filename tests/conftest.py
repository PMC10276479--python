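import numpy as np
import pytest

from csfdyn import PressureTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


def make_sine_trace(freq, p2p, fs=1000.0, duration=60.0, baseline=0.0):
    """Pure sinusoid trace helper shared across waveform tests."""
    t = np.arange(int(round(duration * fs))) / fs
    p = baseline + (p2p / 2.0) * np.sin(2 * np.pi * freq * t)
    return PressureTrace(t=t, p=p, fs=fs)


@pytest.fixture
def sine_trace():
    return make_sine_trace
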