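"""Shared fixtures: small synthetic studies and hand-built recordings."""
from __future__ import annotations

import numpy as np
import pytest

from neuroforecast import SimConfig, generate_study
from neuroforecast.montage import DEFAULT_CHANNELS
from neuroforecast.recording import EEGRecording


@pytest.fixture(scope="session")
def tiny_study():
    """4 subjects x 4 videos at 63 s, strong preset; shared across tests."""
    cfg = SimConfig.small(n_subjects=4, n_videos=4, seed=11)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig.small(n_subjects=4, n_videos=4, seed=11)


def make_recording(signal_fn, duration: float = 20.0, fs: float = 256.0,
                   subject_id: str = "sub", n_events: int = 1,
                   event_duration: float = 10.0) -> EEGRecording:
    """Recording whose every channel carries ``signal_fn(t)`` (or zeros)."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    base = signal_fn(t) if signal_fn is not None else np.zeros(n)
    data = np.tile(base, (len(DEFAULT_CHANNELS), 1))
    events = []
    for k in range(n_events):
        onset = int(round((1.0 + k * (event_duration + 1.0)) * fs))
        events.append((f"v{k + 1:02d}", onset))
    return EEGRecording(subject_id=subject_id, channels=DEFAULT_CHANNELS,
                        fs=fs, data=data, events=events)


@pytest.fixture
def sinusoid_recording():
    """20 s recording of a pure 10 Hz unit sinusoid on every channel."""
    return make_recording(lambda t: np.sin(2 * np.pi * 10.0 * t))
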