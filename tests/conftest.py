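import numpy as np
import pytest

from myogrip.dataio import AnalysisWindow, Recording
from myogrip.preprocess import Envelope, NormalizedEnvelope


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_window(samples: np.ndarray, fs: float = 1000.0, label=None) -> AnalysisWindow:
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1 and samples.shape[1] > samples.shape[0]:
        samples = samples.T
    return AnalysisWindow(
        samples=samples, sampling_rate=fs, duration=samples.shape[0] / fs, label=label
    )


def make_envelope(values: np.ndarray, rate: float = 20.0) -> Envelope:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > values.shape[0]:
        values = values.T
    return Envelope(values=values, envelope_rate=rate, source_window_ms=50.0)


def make_normalized(values: np.ndarray, rate: float = 20.0) -> NormalizedEnvelope:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > values.shape[0]:
        values = values.T
    peaks = values.max(axis=0)
    return NormalizedEnvelope(
        values=values, peak_per_channel=peaks, envelope_rate=rate, source_window_ms=50.0
    )


@pytest.fixture
def random_recording(rng):
    n = 3000
    return Recording(
        emg=rng.standard_normal((n, 3)),
        imu=rng.standard_normal((n, 6)) * 0.01 + 1.0,
        sampling_rate=1000.0,
        label=2,
        trial_id="t07",
    )
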