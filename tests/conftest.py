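import numpy as np
import pytest

from strokenet.montage import DEFAULT_MONTAGE
from strokenet.preprocessing import Recording


@pytest.fixture
def montage():
    return DEFAULT_MONTAGE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=500.0, labels=None, events=()):
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording(data=np.asarray(data, float), fs=fs, labels=tuple(labels),
                     events=tuple(events))


@pytest.fixture
def sine_recording():
    """Two-channel 10 Hz recording with A1/A2 reference channels, 20 s."""
    fs = 500.0
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * 10 * t)
    data = np.stack([x, 0.5 * x, np.zeros_like(x), np.zeros_like(x)])
    return make_recording(data, fs=fs, labels=("C3", "C4", "A1", "A2"))
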