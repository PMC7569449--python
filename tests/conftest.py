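import numpy as np
import pytest

from repcount import SignedMagnitudeSeries, UniformTrace


@pytest.fixture
def make_series():
    """Factory for a SignedMagnitudeSeries from a raw sample array."""
    def _make(s, fs=50.0):
        return SignedMagnitudeSeries(fs=fs, s=np.asarray(s, dtype=float))
    return _make


@pytest.fixture
def sinusoid_series(make_series):
    """Factory for a pure-sinusoid series: f Hz over T seconds at fs Hz."""
    def _make(f, duration_s=30.0, fs=50.0, amplitude=1.0, phase=0.0):
        n = int(round(duration_s * fs)) + 1
        t = np.arange(n) / fs
        return make_series(amplitude * np.sin(2 * np.pi * f * t + phase), fs=fs)
    return _make


@pytest.fixture
def constant_trace():
    """A static trace: pure gravity along z at 50 Hz for 10 s."""
    n = 501
    return UniformTrace(fs=50.0, x=np.zeros(n), y=np.zeros(n),
                        z=np.full(n, 9.80665))
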