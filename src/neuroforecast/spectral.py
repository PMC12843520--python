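"""Alpha-band power estimation and the rolling-window grid.

Two estimators mirror the two analysis granularities:

* Welch periodogram averaging for whole-video band power (2 s Hamming
  segments, 50% overlap, >= 0.5 Hz resolution across the alpha band);
* Morlet wavelet time-frequency decomposition (7 cycles, 1 Hz grid) for
  moment-to-moment alpha-power envelopes, which are downsampled to 250 Hz
  and averaged inside 5 s windows stepped by 1 s (3 s as a robustness
  variant) up to 63 s, the shortest stimulus duration.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy.signal import resample_poly, welch

from .recording import VideoEpoch

#: sampling rate of alpha-power envelopes entering windowed analyses
ENVELOPE_FS = 250.0


@dataclass(frozen=True)
class RollingWindowSpec:
    """Half-open rolling windows ``[k*step, k*step + length)`` up to t_max."""

    length: float = 5.0
    step: float = 1.0
    t_max: float = 63.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.length > self.t_max:
            raise ValueError(
                f"window length {self.length} exceeds t_max {self.t_max}"
            )

    @property
    def starts(self) -> np.ndarray:
        n = int(np.floor((self.t_max - self.length) / self.step + 1e-9)) + 1
        return np.arange(n) * self.step

    @property
    def windows(self) -> list[tuple[float, float]]:
        return [(float(s), float(s + self.length)) for s in self.starts]

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def make_windows(duration: float, length: float = 5.0, step: float = 1.0,
                 t_max: float = 63.0) -> RollingWindowSpec:
    """Rolling-window grid for one video, truncated at ``min(duration, t_max)``."""
    if length > duration:
        raise ValueError(f"window length {length} s exceeds video duration {duration} s")
    return RollingWindowSpec(length=length, step=step, t_max=min(duration, t_max))


@dataclass
class BandPowerSeries:
    """Per-channel alpha-power series for one subject x video.

    ``power`` is channels x times; ``valid`` masks samples outside the
    wavelet edge-contamination zone. ``times`` are seconds from video onset
    and strictly increasing.
    """

    subject_id: str
    video_id: str
    channels: tuple[str, ...]
    times: np.ndarray
    power: np.ndarray
    fs: float
    valid: np.ndarray | None = None
    unit: str = "uV^2"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape != (len(self.channels), len(self.times)):
            raise ValueError("power must be (n_channels, n_times)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)

    def channel(self, label: str) -> np.ndarray:
        return self.power[self.channels.index(label)]

    def resample(self, new_fs: float = ENVELOPE_FS) -> "BandPowerSeries":
        """Polyphase-resample the envelope (e.g. 256 -> 250 Hz).

        Edge flags are recomputed from the preserved edge-zone duration.
        """
        if abs(new_fs - self.fs) < 1e-9:
            return self
        frac = Fraction(new_fs / self.fs).limit_denominator(1000)
        power = resample_poly(self.power, frac.numerator, frac.denominator, axis=-1)
        power = np.clip(power, 0.0, None)
        n = power.shape[1]
        times = self.times[0] + np.arange(n) / new_fs
        lead = self.times[np.argmax(self.valid)] - self.times[0] if self.valid.any() else 0.0
        tail = (self.times[-1] - self.times[::-1][np.argmax(self.valid[::-1])]
                if self.valid.any() else 0.0)
        valid = (times >= self.times[0] + lead - 1e-9) & (times <= self.times[-1] - tail + 1e-9)
        return BandPowerSeries(self.subject_id, self.video_id, self.channels,
                               times, power, new_fs, valid, self.unit)


def welch_band_power(epoch: VideoEpoch, band: tuple[float, float] = (8.0, 13.0),
                     seg_len: float = 2.0, overlap: float = 0.5,
                     channels: tuple[str, ...] | None = None) -> dict[str, float]:
    """Whole-epoch mean PSD over the band, per channel (uV^2/Hz).

    Hamming-windowed overlapping segments; the band is inclusive at both
    edges. Only post-onset samples enter the estimate.
    """
    lo, hi = band
    if hi >= epoch.fs / 2:
        raise ValueError(f"band {band} not resolvable at fs={epoch.fs}")
    nperseg = int(round(seg_len * epoch.fs))
    data = epoch.data[:, epoch.onset_sample:]
    if data.shape[1] < nperseg:
        raise ValueError(f"epoch shorter than the {seg_len} s Welch segment")
    labels = channels if channels is not None else epoch.channels
    rows = [epoch.channel_index(c) for c in labels]
    freqs, psd = welch(data[rows], fs=epoch.fs, window="hamming",
                       nperseg=nperseg, noverlap=int(nperseg * overlap),
                       axis=-1)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"no PSD bins fall inside band {band}")
    return {c: float(psd[i, mask].mean()) for i, c in enumerate(labels)}


def morlet_alpha_envelope(epoch: VideoEpoch,
                          freqs: np.ndarray | None = None,
                          n_cycles: float = 7.0,
                          band: tuple[float, float] = (8.0, 13.0),
                          channels: tuple[str, ...] | None = None) -> BandPowerSeries:
    """Time-resolved alpha power from a Morlet wavelet decomposition.

    Power is averaged across the 1 Hz frequency grid spanning ``band``
    (inclusive). Samples within half a wavelet of either edge (at the lowest,
    i.e. widest, frequency) are flagged invalid.
    """
    if freqs is None:
        freqs = np.arange(band[0], band[1] + 0.5, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    labels = channels if channels is not None else epoch.channels
    rows = [epoch.channel_index(c) for c in labels]
    data = epoch.data[rows].astype(np.float64)
    # widest wavelet must fit inside the epoch
    wavelet_len = int(round(n_cycles / freqs.min() * epoch.fs))
    if wavelet_len > data.shape[1]:
        raise ValueError(
            f"epoch too short for a {n_cycles}-cycle wavelet at {freqs.min()} Hz"
        )
    power = tfr_array_morlet(data[np.newaxis], sfreq=epoch.fs, freqs=freqs,
                             n_cycles=n_cycles, output="power", zero_mean=True,
                             verbose=False)[0]
    alpha = power.mean(axis=1)  # average across frequencies
    times = epoch.times
    half_span = n_cycles / (2.0 * freqs.min())
    valid = (times >= times[0] + half_span) & (times <= times[-1] - half_span)
    return BandPowerSeries(epoch.subject_id, epoch.video_id, tuple(labels),
                           times, alpha, epoch.fs, valid)


def window_average(series: BandPowerSeries, spec: RollingWindowSpec) -> np.ndarray:
    """Per-window mean of in-window, edge-valid samples.

    Returns ``(n_channels, n_windows)``. Raises if any window has no valid
    sample (the series must cover the full grid).
    """
    out = np.empty((len(series.channels), spec.n_windows))
    t = series.times
    for w, (t0, t1) in enumerate(spec.windows):
        mask = (t >= t0) & (t < t1) & series.valid
        if not mask.any():
            raise ValueError(f"window [{t0}, {t1}) contains no valid samples")
        out[:, w] = series.power[:, mask].mean(axis=1)
    return out
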