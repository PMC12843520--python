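"""In-memory containers for continuous EEG recordings and stimulus-locked epochs.

Conventions used throughout the package:

* sample indexing is 0-based and time windows are half-open ``[t0, t1)``;
* epoch time 0 is the video-onset sample, the pre-stimulus baseline spans
  ``[-baseline, 0)``;
* voltages are microvolts, channels-by-samples, channel order is preserved
  by every operation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import EOG_CHANNEL


@dataclass
class EEGRecording:
    """One subject's continuous multichannel EEG with video-onset events.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    channels : tuple of str
        Channel labels (canonical 10-20 names plus optionally ``"EOG"``);
        must be unique.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Voltage matrix in microvolts.
    events : list of (str, int)
        ``(video_id, onset_sample)`` pairs marking stimulus starts.
    """

    subject_id: str
    channels: tuple[str, ...]
    fs: float
    data: np.ndarray
    events: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels={len(self.channels)}, n_samples), "
                f"got shape {self.data.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    @property
    def eeg_channels(self) -> tuple[str, ...]:
        """Scalp channels, i.e. everything except the EOG."""
        return tuple(c for c in self.channels if c != EOG_CHANNEL)

    @property
    def has_eog(self) -> bool:
        return EOG_CHANNEL in self.channels

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), events=list(self.events))


@dataclass
class VideoEpoch:
    """One subject-by-video EEG segment including a pre-stimulus baseline.

    ``data[:, onset_sample]`` is the sample at video onset (time 0); samples
    before it form the baseline. ``bad_channels`` records channels that were
    flagged (and possibly interpolated); ``cleaned`` marks completion of the
    artifact pipeline.
    """

    subject_id: str
    video_id: str
    channels: tuple[str, ...]
    fs: float
    data: np.ndarray
    baseline: float = 0.2
    bad_channels: frozenset[str] = frozenset()
    cleaned: bool = False

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("epoch data must be (n_channels, n_samples)")
        if self.baseline < 0.2 - 1e-12:
            raise ValueError("pre-stimulus baseline must span at least 0.2 s")
        bad = frozenset(self.bad_channels)
        if not bad <= set(self.channels):
            raise ValueError("bad_channels must be a subset of channel labels")
        self.bad_channels = bad

    @property
    def onset_sample(self) -> int:
        """Index of the video-onset sample (time 0)."""
        return int(round(self.baseline * self.fs))

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Post-onset duration in seconds."""
        return (self.n_samples - self.onset_sample) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to video onset."""
        return (np.arange(self.n_samples) - self.onset_sample) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch") from None

    @property
    def eeg_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c != EOG_CHANNEL)

    @property
    def has_eog(self) -> bool:
        return EOG_CHANNEL in self.channels

    def copy(self) -> "VideoEpoch":
        return replace(self, data=self.data.copy())
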