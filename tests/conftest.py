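import numpy as np
import pytest

from scgbeat import WaveSignal


def make_pulse_train(
    hr_bpm: float = 60.0,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    amplitude: float = 1.0,
    base_s: float = 0.020,
):
    """Clean train of triangular pulses; returns (WaveSignal, true times in s)."""
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    period = 60.0 / hr_bpm
    times = np.arange(0.5, duration_s - 0.3, period)
    tri_len = int(round(base_s * fs)) | 1
    tri = amplitude * (1.0 - np.abs(np.linspace(-1, 1, tri_len)))
    for t0 in times:
        i = int(round(t0 * fs)) - tri_len // 2
        x[i : i + tri_len] += tri
    return WaveSignal(x, fs, "pulses"), times


@pytest.fixture
def pulse_train():
    return make_pulse_train


def hits_within(detected_s, true_s, tol_s=0.020):
    """Count true pulses having a detection within tol_s."""
    return sum(bool(np.any(np.abs(detected_s - t0) <= tol_s)) for t0 in true_s)
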