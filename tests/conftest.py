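import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from bhi import synthetic_data
from bhi.types import PhysioRecording, SeizureAnnotation, montage_xy


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_session():
    """A short fully-simulated session (shared; treat as read-only)."""
    sc = synthetic_data.SimScenario(
        seed=11, duration_s=480.0, onset_s=150.0, offset_s=180.0,
        n_channels=8,
    )
    return synthetic_data.simulate_session(sc)


def make_recording(n_channels=29, fs=512.0, duration_s=30.0, seed=0,
                   channels=None):
    """A plain noise recording with a clean ECG pulse train."""
    rng = np.random.default_rng(seed)
    labels = channels or list(synthetic_data.STANDARD_CHANNELS[:n_channels])
    n = int(duration_s * fs)
    eeg = 10.0 * rng.standard_normal((len(labels), n))
    beats = np.arange(0.5, duration_s - 0.5, 0.8)
    ecg = synthetic_data._render_ecg(beats, fs, n)
    return PhysioRecording(
        eeg=eeg, ecg=ecg, fs=fs, channel_labels=labels,
        montage_xy=montage_xy(labels), subject_id="FIX",
    ), beats


@pytest.fixture()
def noise_recording():
    rec, beats = make_recording()
    return rec


@pytest.fixture()
def seizure_annotation():
    return SeizureAnnotation(onset_s=900.0, offset_s=960.0, event_id="sz1")
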