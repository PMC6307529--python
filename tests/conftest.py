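import numpy as np
import pytest

from ptebio import EEGRecording, PVSMarkerTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_recording(rng):
    """5-channel, 200 Hz, 60 s independent Gaussian noise."""
    data = rng.normal(0.0, 20.0, size=(5, 12000))
    return EEGRecording(data=data, fs=200.0,
                        channel_labels=[f"C{i + 1}" for i in range(5)])


@pytest.fixture
def sine_recording():
    """Single-channel pure 10 Hz unit-amplitude sinusoid at 200 Hz, 10 s."""
    t = np.arange(2000) / 200.0
    return EEGRecording(data=np.sin(2 * np.pi * 10 * t)[None, :], fs=200.0,
                        channel_labels=["C1"])


def make_subject(subject_id="S1", group="TBI", age=30.0, sex="M",
                 right=None, left=None):
    """Build a PVSMarkerTable from caliber lists per hemisphere."""
    right = right if right is not None else []
    left = left if left is not None else []
    markers = [("right", float(c)) for c in right]
    markers += [("left", float(c)) for c in left]
    return PVSMarkerTable(subject_id=subject_id, group=group, age_years=age,
                          sex=sex, markers=markers)
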