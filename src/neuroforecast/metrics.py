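"""Group-level neural statistics: frontal alpha asymmetry and inter-subject
correlation.

FAA for one subject x video is ``ln P(F4) - ln P(F3)`` on alpha-band power;
since alpha power is inversely related to cortical activity, positive values
indicate relatively greater *left*-frontal activity (approach motivation).
Whole-video FAA uses the Welch estimate; windowed FAA uses window-averaged
Morlet envelopes.

ISC for one video is the unweighted mean of the ``n(n-1)/2`` pairwise
Pearson correlations of subjects' alpha-power envelopes, channel-averaged
over the mid-central electrodes (Cz, C3, C4) before correlating.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .montage import FAA_PAIR, ISC_CHANNELS
from .spectral import BandPowerSeries, RollingWindowSpec, window_average

#: floor applied to powers before taking logs (uV^2); avoids -inf on
#: silent synthetic channels
POWER_FLOOR = 1e-12


@dataclass(frozen=True)
class FAAValue:
    """One frontal-alpha-asymmetry value; ``unreliable`` marks floored powers."""

    subject_id: str
    video_id: str
    window: tuple[float, float] | str
    value: float
    unreliable: bool = False


@dataclass
class ISCValue:
    """Inter-subject correlation for one video and window."""

    video_id: str
    window: tuple[float, float] | str
    pair_correlations: np.ndarray
    channels: tuple[str, ...]
    n_excluded_pairs: int = 0

    @property
    def mean_isc(self) -> float:
        if len(self.pair_correlations) == 0:
            return float("nan")
        return float(self.pair_correlations.mean())


def faa(p_f3: float, p_f4: float, subject_id: str = "", video_id: str = "",
        window: tuple[float, float] | str = "whole-video",
        floor: float = POWER_FLOOR) -> FAAValue:
    """``ln(p_f4) - ln(p_f3)`` with a power floor; antisymmetric in its inputs."""
    f3 = max(float(p_f3), floor)
    f4 = max(float(p_f4), floor)
    unreliable = p_f3 <= floor and p_f4 <= floor
    return FAAValue(subject_id, video_id, window,
                    float(np.log(f4) - np.log(f3)), unreliable)


def faa_series(envelopes: Mapping[str, BandPowerSeries],
               spec: RollingWindowSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Windowed FAA per subject plus the across-subject group mean.

    ``envelopes`` maps subject ids to alpha-power series containing the F3
    and F4 channels for one video. Returns a long DataFrame
    (subject_id, window index/start, faa) and the group-mean series, one
    value per window.
    """
    rows = []
    per_subject = []
    for sid, series in envelopes.items():
        for ch in FAA_PAIR:
            if ch not in series.channels:
                raise KeyError(f"envelope for subject {sid!r} lacks channel {ch!r}")
        win_pow = window_average(series, spec)
        p3 = win_pow[series.channels.index("F3")]
        p4 = win_pow[series.channels.index("F4")]
        vals = np.log(np.maximum(p4, POWER_FLOOR)) - np.log(np.maximum(p3, POWER_FLOOR))
        per_subject.append(vals)
        for w, start in enumerate(spec.starts):
            rows.append({"subject_id": sid, "window": w,
                         "window_start": float(start), "faa": float(vals[w])})
    group = np.mean(per_subject, axis=0)
    return pd.DataFrame(rows), group


def n_pairs(n: int) -> int:
    """Number of unordered subject pairs, ``n(n-1)/2``."""
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    return n * (n - 1) // 2


def _pair_correlations(stack: np.ndarray) -> tuple[np.ndarray, int]:
    """Upper-triangle Pearson correlations of rows; zero-variance rows excluded."""
    sd = stack.std(axis=1)
    ok = sd > 0
    n_excluded = 0
    if (~ok).any():
        total = n_pairs(stack.shape[0])
        if ok.sum() >= 2:
            kept = n_pairs(int(ok.sum()))
        else:
            kept = 0
        n_excluded = total - kept
        stack = stack[ok]
    if stack.shape[0] < 2:
        return np.empty(0), n_excluded
    corr = np.corrcoef(stack)
    iu = np.triu_indices(stack.shape[0], k=1)
    return corr[iu], n_excluded


def isc(envelopes: Mapping[str, BandPowerSeries],
        window: tuple[float, float],
        channels: Sequence[str] = ISC_CHANNELS,
        video_id: str | None = None,
        average_channels: bool = True) -> ISCValue:
    """Mean pairwise envelope correlation across subjects within a window.

    Envelopes are channel-averaged over ``channels`` before correlating
    (set ``average_channels=False`` to correlate per channel and then
    average the resulting coefficients, as a sensitivity variant). Subjects
    whose series is constant within the window are excluded and counted.
    """
    sids = sorted(envelopes)
    if len(sids) < 2:
        raise ValueError("ISC needs at least 2 subjects")
    t0, t1 = window
    per_subject = []
    for sid in sids:
        s = envelopes[sid]
        rows = [s.channels.index(c) for c in channels]
        mask = (s.times >= t0) & (s.times < t1) & s.valid
        if not mask.any():
            raise ValueError(f"window [{t0}, {t1}) has no valid samples for {sid!r}")
        per_subject.append(s.power[np.ix_(rows, np.flatnonzero(mask))])
    n_t = min(p.shape[1] for p in per_subject)
    per_subject = [p[:, :n_t] for p in per_subject]
    vid = video_id or next(iter(envelopes.values())).video_id

    if average_channels:
        stack = np.stack([p.mean(axis=0) for p in per_subject])
        pairs, excl = _pair_correlations(stack)
    else:
        all_pairs, excl = [], 0
        for k in range(len(channels)):
            stack = np.stack([p[k] for p in per_subject])
            pr, ex = _pair_correlations(stack)
            all_pairs.append(pr)
            excl += ex
        pairs = np.mean([p for p in all_pairs if len(p)], axis=0) if all_pairs else np.empty(0)
    return ISCValue(vid, (t0, t1), np.asarray(pairs), tuple(channels), excl)


def isc_series(envelopes: Mapping[str, BandPowerSeries],
               spec: RollingWindowSpec,
               channels: Sequence[str] = ISC_CHANNELS) -> np.ndarray:
    """Mean ISC at every rolling window for one video."""
    return np.array([
        isc(envelopes, w, channels=channels).mean_isc for w in spec.windows
    ])


def isc_channel_map(envelopes_by_video: Mapping[str, Mapping[str, BandPowerSeries]],
                    outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-channel correlation of whole-video ISC with deal and amount.

    For each EEG channel, computes the single-channel whole-video mean ISC
    of every video, then correlates those values across videos with the
    binary deal outcome (point-biserial) and with the funding amount.
    Requires at least 3 videos and non-constant outcomes.
    """
    vids = sorted(envelopes_by_video)
    if len(vids) < 3:
        raise ValueError("channel map needs at least 3 videos")
    out = outcomes.set_index("video_id")
    deal = out.loc[vids, "deal"].to_numpy(dtype=float)
    amount = out.loc[vids, "amount"].to_numpy(dtype=float)
    if np.ptp(deal) == 0:
        raise ValueError("deal outcome is constant across videos")
    channels = next(iter(envelopes_by_video[vids[0]].values())).channels
    rows = []
    for ch in channels:
        per_video = []
        for v in vids:
            envs = envelopes_by_video[v]
            t_hi = min(e.times[e.valid][-1] for e in envs.values())
            val = isc(envs, (0.0, float(t_hi) + 1e-9), channels=[ch],
                      video_id=v).mean_isc
            per_video.append(val)
        per_video = np.asarray(per_video)
        r_deal = _safe_corr(per_video, deal)
        r_amount = _safe_corr(per_video, amount)
        rows.append({"channel": ch, "r_deal": r_deal, "r_amount": r_amount})
    return pd.DataFrame(rows)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
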