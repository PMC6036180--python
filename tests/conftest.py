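import logging

import numpy as np
import pytest

from eegage.montage import CAP_32_LABELS
from eegage.recording import RawRecording

logging.getLogger("eegage").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cap_recording(rng):
    """32-channel, 120 s white-noise recording at 250 Hz on the standard cap."""
    fs = 250.0
    data = rng.normal(0.0, 10.0, (32, int(120 * fs)))
    return RawRecording(data, fs, CAP_32_LABELS)


def sine(freq, fs, duration, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)
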