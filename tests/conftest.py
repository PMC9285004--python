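import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from mealfp import ChannelID, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4-channel, 10 s, 300 Hz noise recording."""
    channels = [ChannelID(1, 1), ChannelID(1, 2), ChannelID(2, 1), ChannelID(2, 2)]
    traces = rng.normal(0, 0.02, size=(4, 3000)).astype(np.float32)
    return Recording(channels=channels, traces=traces, sample_rate_hz=300.0)


def spiky_trace(rng, n=3000, fs=300.0, noise_sd=0.02, n_spikes=8):
    """Noise plus random-amplitude biphasic spikes; used to exercise the
    peak detector against the brute-force oracle."""
    x = rng.normal(0, noise_sd, size=n)
    t = np.arange(n) / fs
    margin = min(0.2, n / fs / 3)
    for _ in range(n_spikes):
        center = rng.uniform(margin, n / fs - margin)
        amp = rng.uniform(0.03, 0.5) * rng.choice([-1, 1])
        width = rng.uniform(0.01, 0.12)
        rel = (t - (center - width / 2)) / width
        lobe = np.sin(2 * np.pi * rel)
        lobe[(rel < 0) | (rel > 1)] = 0
        x += amp * lobe
    return x
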