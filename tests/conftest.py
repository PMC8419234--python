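import numpy as np
import pytest

from eeg2tms import RawRecording


def tone_recording(
    freqs, sampling_rate=250.0, duration=20.0, amplitudes=None, phases=None,
    n_channels=None, labels=None,
):
    """Multichannel recording where every channel is a sum of pure tones."""
    freqs = np.atleast_2d(freqs)  # (n_channels, n_tones)
    n_ch = n_channels or freqs.shape[0]
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    amplitudes = np.ones_like(freqs, dtype=float) if amplitudes is None \
        else np.atleast_2d(amplitudes)
    phases = np.zeros_like(freqs, dtype=float) if phases is None \
        else np.atleast_2d(phases)
    data = np.zeros((n_ch, n))
    for ch in range(n_ch):
        for f, a, p in zip(freqs[ch], amplitudes[ch], phases[ch]):
            data[ch] += a * np.sin(2 * np.pi * f * t + p)
    labels = labels or tuple(f"ch{i}" for i in range(n_ch))
    return RawRecording(data, sampling_rate, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
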