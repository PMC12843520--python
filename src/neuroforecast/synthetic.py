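"""Synthetic multi-subject EEG pitch study with known ground truth.

The generator emulates the statistical structure of a small "neural focus
group" watching pitch videos, so that every downstream stage (preprocessing,
spectral estimation, FAA/ISC metrics, forecasting, mixed models) can be
validated against latent quantities that a real study never observes:

* each video ``v`` carries a standardized latent interest level ``I_v``;
* interest modulates the left/right frontal alpha *amplitude* ratio: F3 is
  scaled by ``(1 - A_v(t)/2)`` and F4 by ``(1 + A_v(t)/2)`` with
  ``A_v(t) = a1 * I_v * (early_boost if t < 10 s else 1)``, so positive
  interest lowers left-frontal alpha (greater left activity) and raises
  frontal alpha asymmetry ``ln P(F4) - ln P(F3)``, concentrated in the first
  10 seconds;
* all subjects share a smoothed positive low-frequency envelope per video on
  the mid-central channels (Cz, C3, C4), with coupling
  ``kappa_v(t) = kappa0 + kappa1 * deal_v * ramp(t)`` that ramps over the
  pitch and is stronger for funded videos, producing the funded/unfunded
  inter-subject-correlation divergence;
* 7-point rating items, a large-population interest score, binary deal
  outcomes and lognormal funding amounts are all tied to ``I_v``;
* pink-noise background, per-channel slow alpha-amplitude drift, and blink
  artifacts on EOG/Fp1/Fp2 provide realistic nuisance structure.

Everything is deterministic given ``SimConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.ndimage import gaussian_filter1d

from .montage import DEFAULT_CHANNELS, EOG_CHANNEL, ISC_CHANNELS
from .recording import EEGRecording
from .tables import StudyTables


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    The defaults are the documented "strong" preset: effect sizes at which
    the downstream pipeline reliably recovers a positive FAA-interest
    association in early windows and a funded/unfunded ISC divergence in
    late windows. ``null()`` zeroes both couplings.
    """

    n_subjects: int = 28
    n_videos: int = 14
    #: per-video durations in seconds; None draws uniformly from 63-112 s
    video_durations: tuple[float, ...] | None = None
    fs: float = 256.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    alpha_band: tuple[float, float] = (8.0, 13.0)

    # --- neural couplings -------------------------------------------------
    faa_gain: float = 0.35          # a1: FAA-interest coupling
    faa_early_boost: float = 2.0    # multiplier on a1 in the first 10 s
    early_window: float = 10.0      # s of boosted asymmetry after onset
    isc_base: float = 0.25          # kappa0: baseline shared-envelope coupling
    isc_deal_gain: float = 0.9      # kappa1: extra coupling ramp for funded videos
    ramp_shape: str = "linear"      # "linear" or "sqrt" monotone ramp on [0, 1]

    # --- signal composition ----------------------------------------------
    alpha_amp: float = 10.0         # base alpha amplitude, uV
    env_jitter: float = 0.15        # sd of per-channel slow amplitude drift
    noise_sd: float = 12.0          # pink-noise RMS, uV
    noise_shared: float = 0.75      # variance fraction of background common to
                                    # all scalp channels (volume conduction)
    pink_slope: float = 1.0         # 1/f^slope background spectrum
    blink_rate: float = 12.0        # blink events per minute
    blink_amp: float = 120.0        # EOG blink deflection, uV

    # --- behavioral model -------------------------------------------------
    rating_mean: float = 4.0
    rating_slope: float = 0.8       # b: latent interest -> lab rating
    subject_sd: float = 0.5         # sd of per-subject rating offsets u_s
    rating_noise_sd: float = 0.5
    item_sd: float = 0.8            # per-item noise (five interest items)
    dc_item_sd: float = 0.97        # per-item noise (fourteen DC items)
    pop_n: int = 497                # population raters per video
    pop_slope: float = 0.45
    pop_rater_sd: float = 1.0
    deal_logit: tuple[float, float] = (0.0, 1.5)   # (gamma0, gamma1) on I_v
    amount_scale: float = 250_000.0                # USD
    amount_sigma: float = 0.3
    truncate_one_subject: bool = False  # one subject sees only 10 videos

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.n_videos < 1:
            raise ConfigError(f"n_videos must be >= 1, got {self.n_videos}")
        if self.video_durations is not None:
            durs = tuple(float(d) for d in self.video_durations)
            if len(durs) != self.n_videos:
                raise ConfigError(
                    f"video_durations must have n_videos={self.n_videos} entries"
                )
            if any(d < 63.0 for d in durs):
                raise ConfigError("video_durations: all durations must be >= 63 s")
            object.__setattr__(self, "video_durations", durs)
        lo, hi = self.alpha_band
        if not (0.3 < lo < hi < 50.0):
            raise ConfigError(f"alpha_band must lie inside (0.3, 50) Hz, got {self.alpha_band}")
        if self.fs <= 2.0 * hi:
            raise ConfigError(f"fs must exceed twice the upper band edge, got fs={self.fs}")
        if self.pop_n < 1:
            raise ConfigError(f"pop_n must be >= 1, got {self.pop_n}")
        if self.ramp_shape not in ("linear", "sqrt"):
            raise ConfigError(f"ramp_shape must be 'linear' or 'sqrt', got {self.ramp_shape!r}")
        if EOG_CHANNEL not in self.channels:
            raise ConfigError("channels must include the EOG channel")

    # presets --------------------------------------------------------------
    @classmethod
    def null(cls, **kw) -> "SimConfig":
        """No FAA-interest coupling and no funded/unfunded ISC contrast."""
        kw.setdefault("faa_gain", 0.0)
        kw.setdefault("isc_deal_gain", 0.0)
        return cls(**kw)

    @classmethod
    def small(cls, n_subjects: int = 8, n_videos: int = 8, duration: float = 63.0, **kw) -> "SimConfig":
        """Reduced-scale study (same effect sizes) for fast validation runs."""
        kw.setdefault("video_durations", tuple([duration] * n_videos))
        return cls(n_subjects=n_subjects, n_videos=n_videos, **kw)

    def ramp(self, frac: np.ndarray) -> np.ndarray:
        frac = np.clip(np.asarray(frac, dtype=float), 0.0, 1.0)
        return np.sqrt(frac) if self.ramp_shape == "sqrt" else frac


@dataclass
class GroundTruth:
    """Latent state of a generated study; consumed only by recovery tests."""

    video_ids: list[str]
    interest: np.ndarray            # I_v, standardized
    deal: np.ndarray                # D_v in {0, 1}
    amount: np.ndarray              # USD; 0 iff unfunded
    durations: np.ndarray           # seconds per video
    subject_offsets: dict[str, float]
    shared_envelopes: dict[str, np.ndarray]   # per-video shared(t) at fs
    video_order: dict[str, list[str]] = field(default_factory=dict)
    blink_times: dict[str, np.ndarray] = field(default_factory=dict)
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        if not np.all((self.amount > 0) == (self.deal == 1)):
            raise ValueError("amount must be positive exactly for funded videos")

    def _vidx(self, video_id: str) -> int:
        return self.video_ids.index(video_id)

    def asymmetry(self, video_id: str, t: np.ndarray) -> np.ndarray:
        """Injected asymmetry trajectory A_v(t), clipped to keep amplitudes positive."""
        cfg = self.config
        t = np.asarray(t, dtype=float)
        gain = cfg.faa_gain * self.interest[self._vidx(video_id)]
        a = np.where(t < cfg.early_window, gain * cfg.faa_early_boost, gain)
        return np.clip(a, -1.8, 1.8)

    def coupling(self, video_id: str, t: np.ndarray) -> np.ndarray:
        """Shared-envelope coupling kappa_v(t) >= 0."""
        cfg = self.config
        i = self._vidx(video_id)
        frac = np.asarray(t, dtype=float) / self.durations[i]
        return cfg.isc_base + cfg.isc_deal_gain * self.deal[i] * cfg.ramp(frac)


# ---------------------------------------------------------------------------
# low-level signal synthesis
# ---------------------------------------------------------------------------

def pink_noise(n_samples: int, n_channels: int = 1, slope: float = 1.0,
               sd: float = 1.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """1/f^slope Gaussian noise, RMS-normalized per channel.

    Returns shape ``(n_channels, n_samples)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    n_fft = next_fast_len(n_samples, real=True)  # pad: prime lengths are slow
    white = rng.standard_normal((n_channels, n_fft))
    spec = rfft(white, axis=-1)
    f = rfftfreq(n_fft)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-slope / 2.0)
    shaped = irfft(spec * scale, n=n_fft, axis=-1)[:, :n_samples]
    rms = shaped.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms * sd


def _smooth_process(n: int, fs: float, rng: np.random.Generator,
                    sigma_s: float = 0.5, ctrl_fs: float = 4.0) -> np.ndarray:
    """Standardized Gaussian process smoothed below ~1 Hz.

    Synthesized at a coarse control rate and linearly interpolated to the
    target rate; the Gaussian smoothing sets the effective bandwidth.
    """
    n_ctrl = max(int(np.ceil(n / fs * ctrl_fs)) + 2, 8)
    x = gaussian_filter1d(rng.standard_normal(n_ctrl), sigma=sigma_s * ctrl_fs,
                          mode="reflect")
    sd = x.std()
    x = (x - x.mean()) / sd if sd > 0 else np.zeros(n_ctrl)
    t_ctrl = np.arange(n_ctrl) / ctrl_fs
    return np.interp(np.arange(n) / fs, t_ctrl, x)


def shared_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed positive stimulus-locked envelope: mean ~0.5, sd ~0.25, >= 0."""
    z = _smooth_process(n, fs, rng)
    return np.clip(0.5 + 0.25 * z, 0.0, None)


def synthesize_channel_signal(duration: float, fs: float,
                              alpha_amp: float | np.ndarray = 1.0,
                              shared: np.ndarray | None = None,
                              coupling: float = 0.0,
                              pink_slope: float = 1.0,
                              noise_sd: float = 1.0,
                              seed: int | None = None,
                              alpha_freq: float = 10.0,
                              phase: float = 0.0) -> np.ndarray:
    """Single-channel voltage series: pink noise plus a modulated alpha tone.

    The alpha oscillation has instantaneous amplitude
    ``alpha_amp(t) * (1 + coupling * shared(t))``; alpha-band power therefore
    increases monotonically with ``alpha_amp``.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    amp = np.broadcast_to(np.asarray(alpha_amp, dtype=float), (n,)).copy()
    if shared is not None:
        shared = np.asarray(shared, dtype=float)
        if shared.shape != (n,):
            raise ValueError(f"shared envelope must have {n} samples, got {shared.shape}")
        amp = amp * (1.0 + coupling * shared)
    t = np.arange(n) / fs
    signal = amp * np.cos(2.0 * np.pi * alpha_freq * t + phase)
    if noise_sd > 0:
        signal = signal + pink_noise(n, 1, pink_slope, noise_sd, rng)[0]
    return signal


def blink_template(fs: float, width: float = 0.4, amplitude: float = 120.0) -> np.ndarray:
    """Raised-cosine blink deflection of ``width`` seconds, peak ``amplitude`` uV."""
    n = max(int(round(width * fs)), 3)
    return amplitude * np.hanning(n)


#: per-channel blink propagation gains (volume conduction to the frontal pole)
BLINK_GAINS = {EOG_CHANNEL: 1.0, "Fp1": 0.45, "Fp2": 0.45}


def inject_blinks(recording: EEGRecording, rate: float,
                  template: np.ndarray | None = None,
                  seed: int | None = None,
                  return_times: bool = False):
    """Add Poisson blink artifacts to the EOG and frontal-pole channels.

    ``rate`` is in events per minute. Returns a new recording (and the blink
    onset times when ``return_times``); the input is untouched.
    """
    if not recording.has_eog:
        raise ValueError("recording has no EOG channel; cannot inject blinks")
    out = recording.copy()
    rng = np.random.default_rng(seed)
    duration = recording.duration
    n_events = rng.poisson(rate * duration / 60.0) if rate > 0 else 0
    if template is None:
        template = blink_template(recording.fs)
    times = np.sort(rng.uniform(0.2, max(duration - 0.6, 0.2), size=n_events))
    tlen = len(template)
    for t0 in times:
        start = int(round(t0 * recording.fs))
        stop = min(start + tlen, out.n_samples)
        seg = template[: stop - start]
        for ch, gain in BLINK_GAINS.items():
            if ch in out.channels:
                out.data[out.channel_index(ch), start:stop] += (gain * seg).astype(
                    out.data.dtype
                )
    if return_times:
        return out, times
    return out


def simulate_rating_table(n_subjects: int = 28, n_videos: int = 14,
                          slope: float = 0.3, subject_sd: float = 0.5,
                          video_sd: float = 0.3, resid_sd: float = 0.7,
                          mean: float = 4.0,
                          seed: int | None = None) -> pd.DataFrame:
    """Tabular crossed-random-intercept ratings with a known predictor slope.

    Draws a standard-normal predictor ``x`` per subject x video and a rating

        interest = mean + slope * x + u_subject + w_video + eps

    This is the direct generative counterpart of the individual-interest
    mixed model and is used for its parameter-recovery and calibration
    checks (the full EEG generator adds measurement noise on top of this
    structure).
    """
    rng = np.random.default_rng(seed)
    u = subject_sd * rng.standard_normal(n_subjects)
    w = video_sd * rng.standard_normal(n_videos)
    rows = []
    for s in range(n_subjects):
        for v in range(n_videos):
            x = rng.standard_normal()
            y = mean + slope * x + u[s] + w[v] + resid_sd * rng.standard_normal()
            rows.append({"subject_id": f"s{s + 1:02d}", "video_id": f"v{v + 1:02d}",
                         "x": x, "interest": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full-study generation
# ---------------------------------------------------------------------------

def _subject_recording(cfg: SimConfig, subject_id: str, order: list[str],
                       video_ids: list[str], durations: np.ndarray,
                       truth_interest: np.ndarray, truth_deal: np.ndarray,
                       shared_envs: dict[str, np.ndarray],
                       rng: np.random.Generator,
                       gap: float = 2.0, lead_in: float = 1.0) -> EEGRecording:
    fs = cfg.fs
    n_ch = len(cfg.channels)
    i_eog = cfg.channels.index(EOG_CHANNEL)

    n_per = {v: int(round(durations[video_ids.index(v)] * fs)) for v in order}
    onsets, cursor = {}, int(round(lead_in * fs))
    for v in order:
        onsets[v] = cursor
        cursor += n_per[v] + int(round(gap * fs))
    n_total = cursor + int(round(gap * fs))

    # one volume-conducted alpha oscillator per subject (individual peak
    # frequency and phase); channels differ only in amplitude envelope, which
    # keeps neighboring electrodes realistically correlated
    freq = rng.uniform(9.0, 11.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_total) / fs
    osc = np.cos(2.0 * np.pi * freq * t + phase)[None, :]

    # slow per-channel amplitude drift (keeps pairwise envelopes imperfect)
    amp = np.empty((n_ch, n_total))
    gains = np.array([1.2 if c in ("O1", "O2") else 1.0 for c in cfg.channels])
    for c in range(n_ch):
        drift = 1.0 + cfg.env_jitter * _smooth_process(n_total, fs, rng)
        amp[c] = cfg.alpha_amp * gains[c] * np.clip(drift, 0.0, None)
    amp[i_eog] = 0.0  # the EOG carries no alpha rhythm

    i_f3 = cfg.channels.index("F3")
    i_f4 = cfg.channels.index("F4")
    i_isc = [cfg.channels.index(c) for c in ISC_CHANNELS]

    for v in order:
        vi = video_ids.index(v)
        span = slice(onsets[v], onsets[v] + n_per[v])
        t_rel = np.arange(n_per[v]) / fs
        a_gain = cfg.faa_gain * truth_interest[vi]
        a = np.where(t_rel < cfg.early_window, a_gain * cfg.faa_early_boost, a_gain)
        a = np.clip(a, -1.8, 1.8)
        amp[i_f3, span] *= 1.0 - a / 2.0
        amp[i_f4, span] *= 1.0 + a / 2.0
        kappa = cfg.isc_base + cfg.isc_deal_gain * truth_deal[vi] * cfg.ramp(
            t_rel / durations[vi]
        )
        mod = 1.0 + kappa * shared_envs[v][: n_per[v]]
        for c in i_isc:
            amp[c, span] *= mod

    # background: per-channel pink noise partly shared across the scalp
    # (volume conduction makes neighboring electrodes strongly correlated)
    own = pink_noise(n_total, n_ch, cfg.pink_slope, cfg.noise_sd, rng)
    common = pink_noise(n_total, 1, cfg.pink_slope, cfg.noise_sd, rng)
    a = cfg.noise_shared
    data = np.sqrt(1.0 - a) * own + np.sqrt(a) * common
    data[i_eog] = own[i_eog]  # the EOG does not share the scalp background
    data += amp * osc
    events = [(v, onsets[v]) for v in order]
    return EEGRecording(subject_id=subject_id, channels=cfg.channels, fs=fs,
                        data=data.astype(np.float32), events=events)


def generate_study(config: SimConfig | None = None, seed: int | None = None
                   ) -> tuple[list[EEGRecording], StudyTables, GroundTruth]:
    """Generate a complete synthetic study.

    Returns one continuous recording per subject (videos in per-subject
    randomized order, onset events attached), the behavioral/population/
    outcome tables, and the latent ground truth. Deterministic given
    ``config.seed`` (or the ``seed`` override).
    """
    cfg = SimConfig() if config is None else config
    if seed is not None:
        cfg = replace(cfg, seed=seed)

    ss = np.random.SeedSequence(cfg.seed)
    video_ss, table_ss, subj_ss, blink_ss = ss.spawn(4)
    rng_v = np.random.default_rng(video_ss)

    video_ids = [f"v{i + 1:02d}" for i in range(cfg.n_videos)]
    if cfg.video_durations is None:
        durations = np.round(rng_v.uniform(63.0, 112.0, size=cfg.n_videos), 1)
    else:
        durations = np.asarray(cfg.video_durations, dtype=float)

    interest = rng_v.standard_normal(cfg.n_videos)
    if cfg.n_videos > 1:
        interest = (interest - interest.mean()) / interest.std()

    g0, g1 = cfg.deal_logit
    p_deal = _sigmoid(g0 + g1 * interest)
    deal = (rng_v.uniform(size=cfg.n_videos) < p_deal).astype(int)
    # guarantee a defined funded/unfunded contrast on every seed
    if cfg.n_videos >= 4:
        for cls, want in ((1, p_deal), (0, 1.0 - p_deal)):
            short = 2 - int((deal == cls).sum())
            if short > 0:
                flip = np.argsort(np.where(deal != cls, want, -np.inf))[-short:]
                deal[flip] = cls
    amount = np.where(
        deal == 1,
        cfg.amount_scale * np.exp(0.5 * interest
                                  + cfg.amount_sigma * rng_v.standard_normal(cfg.n_videos)),
        0.0,
    )

    shared_envs = {
        v: shared_envelope(int(round(d * cfg.fs)), cfg.fs, rng_v)
        for v, d in zip(video_ids, durations)
    }

    subject_ids = [f"s{i + 1:02d}" for i in range(cfg.n_subjects)]
    recordings: list[EEGRecording] = []
    order_map: dict[str, list[str]] = {}
    blink_times: dict[str, np.ndarray] = {}
    subj_children = subj_ss.spawn(cfg.n_subjects)
    blink_children = blink_ss.spawn(cfg.n_subjects)
    for k, sid in enumerate(subject_ids):
        rng_s = np.random.default_rng(subj_children[k])
        order = [video_ids[i] for i in rng_s.permutation(cfg.n_videos)]
        if cfg.truncate_one_subject and k == cfg.n_subjects - 1:
            order = order[: min(10, len(order))]
        order_map[sid] = order
        rec = _subject_recording(cfg, sid, order, video_ids, durations,
                                 interest, deal, shared_envs, rng_s)
        rec, times = inject_blinks(rec, cfg.blink_rate,
                                   seed=np.random.default_rng(blink_children[k]),
                                   return_times=True)
        blink_times[sid] = times
        recordings.append(rec)

    rng_t = np.random.default_rng(table_ss)
    u_s = {sid: cfg.subject_sd * rng_t.standard_normal() for sid in subject_ids}
    dc_trait = {sid: 4.0 + 0.7 * rng_t.standard_normal() for sid in subject_ids}

    rows = []
    for sid in subject_ids:
        dc_items = np.clip(np.round(dc_trait[sid]
                                    + cfg.dc_item_sd * rng_t.standard_normal(14)), 1, 7)
        age = int(rng_t.integers(22, 61))
        gender = str(rng_t.choice(["F", "M"]))
        for v in order_map[sid]:
            vi = video_ids.index(v)
            latent = (cfg.rating_mean + cfg.rating_slope * interest[vi] + u_s[sid]
                      + cfg.rating_noise_sd * rng_t.standard_normal())
            items = np.clip(np.round(latent + cfg.item_sd * rng_t.standard_normal(5)), 1, 7)
            pred = int(rng_t.uniform() < _sigmoid(latent - cfg.rating_mean))
            row = {"subject_id": sid, "video_id": v,
                   **{f"q{i + 1}": items[i] for i in range(5)},
                   "deal_prediction": pred,
                   **{f"dc{i + 1}": dc_items[i] for i in range(14)},
                   "age": age, "gender": gender}
            rows.append(row)
    ratings = pd.DataFrame(rows)

    pop_rows = []
    for vi, v in enumerate(video_ids):
        raters = np.clip(cfg.rating_mean - 0.1 + cfg.pop_slope * interest[vi]
                         + cfg.pop_rater_sd * rng_t.standard_normal(cfg.pop_n), 1, 7)
        pop_rows.append({"video_id": v, "pop_interest": raters.mean(),
                         "n_raters": cfg.pop_n})
    population = pd.DataFrame(pop_rows)

    outcomes = pd.DataFrame({"video_id": video_ids, "deal": deal, "amount": amount})
    sentiment = pd.DataFrame({
        "video_id": video_ids,
        "joy": np.clip(rng_t.normal(0.3, 0.1, cfg.n_videos), 0, 1),
        "trust": np.clip(rng_t.normal(0.3, 0.1, cfg.n_videos), 0, 1),
        "positive": np.clip(rng_t.normal(0.35, 0.1, cfg.n_videos), 0, 1),
        "negative": np.clip(rng_t.normal(0.15, 0.08, cfg.n_videos), 0, 1),
        "word_count": rng_t.normal(180, 30, cfg.n_videos).round().astype(int),
    })
    videos = pd.DataFrame({"video_id": video_ids, "duration_s": durations})

    tables = StudyTables(ratings=ratings, population=population,
                         outcomes=outcomes, sentiment=sentiment, videos=videos)
    truth = GroundTruth(video_ids=video_ids, interest=interest, deal=deal,
                        amount=amount, durations=durations,
                        subject_offsets=u_s, shared_envelopes=shared_envs,
                        video_order=order_map, blink_times=blink_times,
                        config=cfg)
    return recordings, tables, truth
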