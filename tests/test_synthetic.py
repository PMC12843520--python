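"""Generator contract: determinism, validity, and injected signal structure."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from neuroforecast import SimConfig, generate_study, inject_blinks, synthesize_channel_signal
from neuroforecast.synthetic import ConfigError, pink_noise, shared_envelope


class TestSimConfigValidation:
    @pytest.mark.parametrize("kwargs, field", [
        ({"n_subjects": 1}, "n_subjects"),
        ({"n_videos": 2, "video_durations": (63.0, 50.0)}, "video_durations"),
        ({"alpha_band": (8.0, 60.0)}, "alpha_band"),
        ({"fs": 20.0}, "fs"),
        ({"pop_n": 0}, "pop_n"),
        ({"ramp_shape": "log"}, "ramp_shape"),
    ])
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs)

    def test_duration_count_must_match(self):
        with pytest.raises(ConfigError, match="video_durations"):
            SimConfig(n_videos=3, video_durations=(63.0, 64.0))


class TestDeterminism:
    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig.small(n_subjects=2, n_videos=4, seed=7)
        recs_a, tab_a, truth_a = generate_study(cfg)
        recs_b, tab_b, truth_b = generate_study(cfg)
        for ra, rb in zip(recs_a, recs_b):
            assert ra.data.tobytes() == rb.data.tobytes()
            assert ra.events == rb.events
        pd.testing.assert_frame_equal(tab_a.ratings, tab_b.ratings)
        pd.testing.assert_frame_equal(tab_a.outcomes, tab_b.outcomes)
        np.testing.assert_array_equal(truth_a.interest, truth_b.interest)

    def test_different_seeds_differ(self):
        a, _, _ = generate_study(SimConfig.small(n_subjects=2, n_videos=4, seed=1))
        b, _, _ = generate_study(SimConfig.small(n_subjects=2, n_videos=4, seed=2))
        assert a[0].data.tobytes() != b[0].data.tobytes()


class TestStudyStructure:
    def test_tables_and_truth_shape(self, tiny_study, tiny_config):
        recs, tables, truth = tiny_study
        cfg = tiny_config
        assert len(recs) == cfg.n_subjects
        assert len(tables.population) == cfg.n_videos
        items = tables.ratings[[f"q{i}" for i in range(1, 6)]].to_numpy()
        assert items.min() >= 1 and items.max() <= 7
        assert np.all((truth.amount > 0) == (truth.deal == 1))
        # interest is standardized
        assert abs(truth.interest.mean()) < 1e-9
        assert abs(truth.interest.std() - 1.0) < 1e-9

    def test_each_recording_contains_all_videos(self, tiny_study, tiny_config):
        recs, _, truth = tiny_study
        for rec in recs:
            assert sorted(v for v, _ in rec.events) == sorted(truth.video_ids)
            # randomized order is recorded in the truth
            assert [v for v, _ in rec.events] == truth.video_order[rec.subject_id]

    def test_truncated_subject_sees_ten_videos(self):
        cfg = SimConfig.small(n_subjects=2, n_videos=11,
                              truncate_one_subject=True, seed=3)
        recs, tables, _ = generate_study(cfg)
        assert len(recs[-1].events) == 10
        assert len(recs[0].events) == 11
        # ratings only exist for watched videos
        last = tables.ratings[tables.ratings.subject_id == recs[-1].subject_id]
        assert len(last) == 10


class TestChannelSynthesis:
    def test_zero_amplitude_zero_noise_is_silent(self):
        sig = synthesize_channel_signal(2.0, 256.0, alpha_amp=0.0, noise_sd=0.0)
        assert np.all(sig == 0.0)

    def test_alpha_band_dominates_for_pure_tone(self):
        # FFT periodogram oracle: alpha vs theta/beta/gamma band power
        sig = synthesize_channel_signal(8.0, 256.0, alpha_amp=1.0, noise_sd=0.0)
        f, p = periodogram(sig, fs=256.0)
        def band(lo, hi):
            return p[(f >= lo) & (f <= hi)].sum()
        alpha = band(8, 13)
        for other in [(4, 7.5), (13.5, 30), (30, 45)]:
            assert alpha > 100 * band(*other)

    def test_band_power_monotone_in_amplitude(self):
        from scipy.signal import welch
        powers = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            sig = synthesize_channel_signal(4.0, 256.0, alpha_amp=amp, noise_sd=0.0)
            f, p = welch(sig, fs=256.0, nperseg=512)
            powers.append(p[(f >= 8) & (f <= 13)].mean())
        assert np.all(np.diff(powers) > 0)

    def test_shared_envelope_couples_two_subjects(self):
        # kappa = 1, identical shared(t), no noise: alpha-power envelopes align
        fs, dur = 256.0, 20.0
        n = int(dur * fs)
        rng = np.random.default_rng(0)
        sh = shared_envelope(n, fs, rng)
        sigs = [synthesize_channel_signal(dur, fs, 1.0, shared=sh, coupling=1.0,
                                          noise_sd=0.0, seed=s) for s in (1, 2)]
        from scipy.signal import hilbert
        envs = [np.abs(hilbert(s)) for s in sigs]
        sl = slice(int(fs), -int(fs))  # trim edges
        r = np.corrcoef(envs[0][sl], envs[1][sl])[0, 1]
        assert r > 0.99

    def test_invalid_fs_raises(self):
        with pytest.raises(ValueError, match="fs"):
            synthesize_channel_signal(1.0, 0.0)


class TestPinkNoise:
    def test_spectrum_slope_negative(self):
        x = pink_noise(2 ** 15, 1, 1.0, 1.0, np.random.default_rng(0))[0]
        f, p = periodogram(x, fs=1.0)
        low = p[(f > 0.001) & (f < 0.01)].mean()
        high = p[(f > 0.1) & (f < 0.4)].mean()
        assert low > 10 * high

    def test_rms_normalization(self):
        x = pink_noise(4096, 3, 1.0, 2.5, np.random.default_rng(1))
        np.testing.assert_allclose(x.std(axis=1), 2.5, rtol=1e-6)


class TestEffectSizeMonotonicity:
    """Downstream effect strength is non-decreasing in the injected gains."""

    N_SEEDS = 6

    def test_faa_interest_correlation_increases_with_gain(self):
        from neuroforecast import analyze_study
        from neuroforecast.pipeline import AnalysisParams, forecast_population_interest
        params = AnalysisParams(metrics=("faa",), whole_video_faa=False)
        means = []
        for a1 in (0.0, 0.1, 0.35):
            rs = []
            for seed in range(self.N_SEEDS):
                cfg = SimConfig.small(n_subjects=4, n_videos=6,
                                      faa_gain=a1, seed=400 + seed)
                recs, tables, _ = generate_study(cfg)
                an = analyze_study(recs, tables, params)
                df = forecast_population_interest(an, tables).frame
                rs.append(df[df.window_start <= 8.0].r.mean())
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]
        assert abs(means[0]) < 0.4  # null level

    def test_late_isc_gap_increases_with_deal_coupling(self):
        from neuroforecast import analyze_study
        from neuroforecast.pipeline import AnalysisParams
        params = AnalysisParams(metrics=("isc",), whole_video_faa=False)
        gaps = []
        for k1 in (0.0, 0.9):
            per_seed = []
            for seed in range(self.N_SEEDS):
                cfg = SimConfig.small(n_subjects=4, n_videos=6,
                                      isc_deal_gain=k1, seed=500 + seed)
                recs, tables, _ = generate_study(cfg)
                an = analyze_study(recs, tables, params)
                deal = tables.outcomes.set_index("video_id").loc[
                    an.video_ids, "deal"].to_numpy()
                late = an.isc_windows[an.isc_windows.shape[0] // 2:]
                per_seed.append(late[:, deal == 1].mean() - late[:, deal == 0].mean())
            gaps.append(np.mean(per_seed))
        assert gaps[1] > gaps[0]
        assert abs(gaps[0]) < 0.05  # no contrast without coupling


class TestBlinks:
    def test_zero_rate_is_identity(self, tiny_study):
        rec = tiny_study[0][0]
        out = inject_blinks(rec, rate=0.0, seed=0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_poisson_event_count(self, sinusoid_recording):
        out, times = inject_blinks(sinusoid_recording, rate=15.0, seed=4,
                                   return_times=True)
        # 15/min on a 20 s recording: expectation 5 events
        assert 0 < len(times) < 16
        assert not np.array_equal(out.data, sinusoid_recording.data)

    def test_blinks_hit_eog_and_frontal_pole_only(self, sinusoid_recording):
        rec = sinusoid_recording
        out = inject_blinks(rec, rate=30.0, seed=5)
        diff = np.abs(out.data - rec.data).max(axis=1)
        for ch in ("EOG", "Fp1", "Fp2"):
            assert diff[rec.channel_index(ch)] > 1.0
        for i, ch in enumerate(rec.channels):
            if ch not in ("EOG", "Fp1", "Fp2"):
                assert diff[i] == 0.0

    def test_missing_eog_raises(self, sinusoid_recording):
        from dataclasses import replace
        rec = sinusoid_recording
        no_eog = replace(rec, channels=rec.channels[:-1], data=rec.data[:-1])
        with pytest.raises(ValueError, match="EOG"):
            inject_blinks(no_eog, rate=10.0)
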