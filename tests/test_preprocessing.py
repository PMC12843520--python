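"""Cleanup pipeline: filtering, epoching, bad channels, EOG, baseline."""
from __future__ import annotations

import numpy as np
import pytest

from neuroforecast import (bandpass, baseline_correct, detect_bad_channels,
                           epoch_by_events, interpolate_bad_channels,
                           preprocess_recording, remove_eog)
from neuroforecast.montage import DEFAULT_CHANNELS
from neuroforecast.recording import VideoEpoch

from conftest import make_recording


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def make_epoch(data, fs=256.0, channels=DEFAULT_CHANNELS, baseline=0.2):
    return VideoEpoch(subject_id="s", video_id="v", channels=channels,
                      fs=fs, data=data, baseline=baseline)


class TestBandpass:
    def test_line_noise_attenuated(self):
        rec = make_recording(lambda t: np.sin(2 * np.pi * 60.0 * t))
        out = bandpass(rec)
        trim = slice(int(2 * rec.fs), -int(2 * rec.fs))
        assert _rms(out.data[0, trim]) < 0.05 * _rms(rec.data[0, trim])

    def test_alpha_passes(self, sinusoid_recording):
        out = bandpass(sinusoid_recording)
        fs = sinusoid_recording.fs
        trim = slice(int(2 * fs), -int(2 * fs))
        ratio = _rms(out.data[0, trim]) / _rms(sinusoid_recording.data[0, trim])
        assert 0.95 < ratio < 1.05

    def test_dc_removed(self):
        rec = make_recording(lambda t: np.full_like(t, 7.5))
        out = bandpass(rec)
        trim = slice(int(2 * rec.fs), -int(2 * rec.fs))
        assert np.abs(out.data[:, trim]).max() < 0.05

    def test_rejects_band_above_nyquist(self, sinusoid_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(sinusoid_recording, low=0.3, high=200.0)


class TestEpoching:
    def test_one_epoch_per_event_with_exact_lengths(self):
        rec = make_recording(lambda t: np.sin(t), duration=200.0, n_events=3,
                             event_duration=63.0)
        durations = {f"v{k:02d}": 63.0 for k in (1, 2, 3)}
        epochs = epoch_by_events(rec, durations)
        assert len(epochs) == 3
        # 0.2 s baseline + 63 s at 256 Hz, rounded per the stated convention
        assert epochs[0].n_samples == round(0.2 * 256) + 63 * 256
        assert epochs[0].onset_sample == round(0.2 * 256)

    def test_onset_sample_is_time_zero(self):
        rec = make_recording(None, duration=30.0)
        rec.data[:, rec.events[0][1]] = 42.0
        ep = epoch_by_events(rec, {"v01": 10.0})[0]
        assert ep.data[0, ep.onset_sample] == 42.0
        assert ep.times[ep.onset_sample] == 0.0

    def test_event_without_baseline_room_raises(self):
        rec = make_recording(None, duration=30.0)
        rec.events = [("v01", 0)]
        with pytest.raises(ValueError, match="v01"):
            epoch_by_events(rec, {"v01": 10.0})

    def test_event_running_off_the_end_raises(self):
        rec = make_recording(None, duration=30.0)
        with pytest.raises(ValueError, match="v01"):
            epoch_by_events(rec, {"v01": 60.0})


class TestBadChannels:
    def test_identical_copies_are_clean(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(1024)
        ep = make_epoch(np.tile(row, (len(DEFAULT_CHANNELS), 1)))
        assert detect_bad_channels(ep) == frozenset()

    def test_high_amplitude_noise_channel_flagged(self):
        rng = np.random.default_rng(1)
        shared = rng.standard_normal(2048)
        data = np.array([shared + 0.3 * rng.standard_normal(2048)
                         for _ in DEFAULT_CHANNELS])
        i = DEFAULT_CHANNELS.index("P3")
        data[i] = 10.0 * rng.standard_normal(2048)
        bads = detect_bad_channels(make_epoch(data))
        assert "P3" in bads

    def test_flat_channel_flagged_via_variance(self):
        rng = np.random.default_rng(2)
        shared = rng.standard_normal(2048)
        data = np.array([shared + 0.3 * rng.standard_normal(2048)
                         for _ in DEFAULT_CHANNELS])
        data[DEFAULT_CHANNELS.index("O1")] = 0.0
        assert "O1" in detect_bad_channels(make_epoch(data))

    def test_eog_never_flagged(self):
        rng = np.random.default_rng(3)
        shared = rng.standard_normal(2048)
        data = np.array([shared + 0.3 * rng.standard_normal(2048)
                         for _ in DEFAULT_CHANNELS])
        data[DEFAULT_CHANNELS.index("EOG")] = 0.0  # flat EOG
        assert "EOG" not in detect_bad_channels(make_epoch(data))


class TestInterpolation:
    def test_no_bads_is_identity(self):
        ep = make_epoch(np.random.default_rng(0).standard_normal((20, 512)))
        out = interpolate_bad_channels(ep, frozenset())
        np.testing.assert_array_equal(out.data, ep.data)

    def test_f3_is_mean_of_neighbors(self):
        data = np.zeros((20, 512))
        for ch, val in {"Fp1": 1.0, "F7": 2.0, "Fz": 3.0, "C3": 4.0}.items():
            data[DEFAULT_CHANNELS.index(ch)] = val
        data[DEFAULT_CHANNELS.index("F3")] = 99.0
        out = interpolate_bad_channels(make_epoch(data), {"F3"})
        np.testing.assert_allclose(out.data[DEFAULT_CHANNELS.index("F3")], 2.5)
        assert out.bad_channels == frozenset({"F3"})

    def test_interpolated_variance_bounded_by_neighbors(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((20, 1024)) * rng.uniform(0.5, 2.0, (20, 1))
        ep = make_epoch(data)
        out = interpolate_bad_channels(ep, {"Cz"})
        from neuroforecast.montage import neighbors
        nbr_var = max(ep.data[DEFAULT_CHANNELS.index(c)].var()
                      for c in neighbors("Cz"))
        assert out.data[DEFAULT_CHANNELS.index("Cz")].var() <= nbr_var

    def test_all_bad_is_unrecoverable(self):
        ep = make_epoch(np.zeros((20, 512)))
        with pytest.raises(ValueError, match="subset|unrecoverable"):
            interpolate_bad_channels(ep, set(DEFAULT_CHANNELS))


class TestEOGRemoval:
    def test_silent_eog_leaves_eeg_unchanged(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((20, 4096))
        data[DEFAULT_CHANNELS.index("EOG")] = 0.0
        ep = make_epoch(data)
        out = remove_eog(ep)
        assert "EOG" not in out.channels
        np.testing.assert_array_equal(
            out.data[out.channel_index("Cz")], ep.data[ep.channel_index("Cz")])

    def test_contaminated_channel_is_cleaned(self):
        rng = np.random.default_rng(6)
        n = 8192
        eog = rng.standard_normal(n)
        data = rng.standard_normal((20, n))
        data[DEFAULT_CHANNELS.index("EOG")] = eog
        i_fp1 = DEFAULT_CHANNELS.index("Fp1")
        data[i_fp1] = 0.8 * eog + 0.6 * rng.standard_normal(n)
        out = remove_eog(make_epoch(data))
        r = np.corrcoef(out.data[out.channel_index("Fp1")], eog)[0, 1]
        assert abs(r) < 0.05

    def test_independent_channel_untouched(self):
        rng = np.random.default_rng(7)
        n = 1000
        data = rng.standard_normal((20, n))
        ep = make_epoch(data)
        out = remove_eog(ep)
        # at least one channel must be exactly untouched (|z| < 1.96 gate)
        kept = [c for c in out.channels]
        untouched = sum(
            np.array_equal(out.data[out.channel_index(c)],
                           ep.data[ep.channel_index(c)]) for c in kept)
        assert untouched >= 1

    def test_missing_eog_raises(self):
        ep = make_epoch(np.zeros((19, 512)), channels=DEFAULT_CHANNELS[:-1])
        with pytest.raises(ValueError, match="EOG"):
            remove_eog(ep)


class TestBaseline:
    def test_constant_channel_becomes_zero(self):
        ep = make_epoch(np.full((20, 512), 3.14))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_idempotent(self):
        ep = make_epoch(np.random.default_rng(8).standard_normal((20, 512)))
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_baseline_window_mean_is_zero(self):
        ep = make_epoch(np.random.default_rng(9).standard_normal((20, 512)))
        out = baseline_correct(ep)
        mask = (out.times >= -0.2) & (out.times < 0.0)
        np.testing.assert_allclose(out.data[:, mask].mean(axis=1), 0.0, atol=1e-12)

    def test_empty_window_raises(self):
        ep = make_epoch(np.zeros((20, 512)))
        with pytest.raises(ValueError, match="empty"):
            baseline_correct(ep, (0.0, 0.0))


class TestFullPipeline:
    def test_pipeline_output_is_clean_and_ordered(self, tiny_study, tiny_config):
        recs, tables, _ = tiny_study
        durations = dict(zip(tables.videos.video_id, tables.videos.duration_s))
        epochs, prov = preprocess_recording(recs[0], durations)
        assert len(epochs) == tiny_config.n_videos
        for ep in epochs:
            assert ep.fs == recs[0].fs
            assert ep.channels == recs[0].eeg_channels  # EOG dropped, order kept
            assert np.isfinite(ep.data).all()
            assert ep.cleaned
        assert prov["pipeline"] == ["bandpass", "epoch", "bad_channels",
                                    "eog_regression", "baseline"]

    def test_eog_regression_reduces_blink_leakage(self, tiny_study):
        # blink-injected data: mean |Fp1-EOG correlation| must drop
        recs, tables, _ = tiny_study
        durations = dict(zip(tables.videos.video_id, tables.videos.duration_s))
        rec = bandpass(recs[1])
        before_all, after_all = [], []
        for ep in epoch_by_events(rec, durations):
            eog = ep.data[ep.channel_index("EOG")]
            fp1 = ep.data[ep.channel_index("Fp1")]
            before_all.append(abs(np.corrcoef(fp1, eog)[0, 1]))
            clean = remove_eog(ep)
            after_all.append(abs(np.corrcoef(
                clean.data[clean.channel_index("Fp1")], eog)[0, 1]))
        assert np.mean(after_all) < np.mean(before_all)
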