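import numpy as np
import pytest

from ocupulse import ScenarioConfig, TimeTrace
from ocupulse.synthetic import BlinkSpec, OscSpec, SaccadeSpec


def brute_force_periodogram(x, fs, nfft):
    """Directly-summed Hamming-tapered DFT periodogram (test oracle).

    Independent of the FFT implementation: evaluates
    S(f_k) = sum_n w(n)(x(n)-mean)e^{-i2πkn/nfft} by explicit summation and
    returns (|S|^2 / Σw², f_k) on the one-sided grid.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 1:
        w = np.ones(1)
    else:
        w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(n) / (n - 1))
    xt = (x - x.mean()) * w
    ks = np.arange(nfft // 2 + 1)
    s = np.array(
        [np.sum(xt * np.exp(-2j * np.pi * k * np.arange(n) / nfft)) for k in ks]
    )
    return np.abs(s) ** 2 / np.sum(w**2), ks * fs / nfft


@pytest.fixture
def oracle_periodogram():
    return brute_force_periodogram


@pytest.fixture
def small_config():
    """Desk-scale scenario: full study frequencies on a reduced grid."""
    return ScenarioConfig(
        duration=60.0,
        seed=123,
        volume_shape=(16, 16),
        frame_shape=(48, 64),
        fec_duration=20.0,
    )


@pytest.fixture
def quiet_video_config():
    """Video scenario without blinks/saccades/noise, for exact-value checks."""
    return ScenarioConfig(
        duration=10.0,
        seed=7,
        frame_shape=(48, 64),
        fec_duration=10.0,
        noise_sd=0.0,
        blink=BlinkSpec(rate=0.0),
        saccade=SaccadeSpec(rate=0.0),
    )


@pytest.fixture
def resp_only_config():
    """Pure 0.25 Hz respiratory oscillation, no other components or noise."""
    return ScenarioConfig(
        duration=180.0,
        seed=5,
        noise_sd=0.0,
        vlf=OscSpec(0.05, 0.0),
        resp=OscSpec(0.25, 1.0, n_harmonics=1),
        card=OscSpec(1.10, 0.0),
    )


@pytest.fixture
def sine_trace():
    def make(freq, fs=10.0, duration=90.0, amplitude=1.0, phase=0.0):
        t = np.arange(int(round(duration * fs))) / fs
        return TimeTrace(
            amplitude * np.sin(2 * np.pi * freq * t + phase), fs=fs
        )

    return make
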