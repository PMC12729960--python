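"""Denoising chain: filter responses, SNR screen, segmentation."""

import numpy as np
import pytest

from fatiguecg.data_model import ECGRecord, FatigueClass
from fatiguecg.preprocess import (
    FilterSpec,
    bandpass,
    clean_signal,
    estimate_snr,
    moving_average_filter,
    reject_segment,
    remove_baseline,
    segment_record,
)
from fatiguecg.synth import NoiseParams, SynthClassParams, generate_rr_series, synthesize_ecg

FS = 200.0


def _sine(freq, fs=FS, duration=4.0, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


def _steady_amp(x, fs=FS):
    """Peak amplitude away from filter edge transients."""
    n = len(x)
    return np.abs(x[n // 4 : 3 * n // 4]).max()


class TestMovingAverage:
    def test_constant_unchanged(self):
        for n in (1, 2, 5, 8):
            np.testing.assert_allclose(moving_average_filter(np.full(50, 3.3), n), 3.3)

    def test_n1_identity(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_array_equal(moving_average_filter(x, 1), x)

    def test_50hz_gain_is_dirichlet_value(self):
        """|sin(pi 50x5/200)/(5 sin(pi 50/200))| = 0.2 exactly."""
        y = moving_average_filter(_sine(50.0), 5)
        assert _steady_amp(y) == pytest.approx(0.200, abs=0.005)

    def test_n4_nulls_50hz(self):
        y = moving_average_filter(_sine(50.0), 4)
        assert _steady_amp(y) < 0.01

    @pytest.mark.parametrize("freq, n", [(10.0, 5), (25.0, 5), (20.0, 4)])
    def test_gain_matches_closed_form(self, freq, n):
        expected = abs(np.sin(np.pi * freq * n / FS) / (n * np.sin(np.pi * freq / FS)))
        y = moving_average_filter(_sine(freq), n)
        assert _steady_amp(y) == pytest.approx(expected, abs=0.01)

    def test_length_preserved_and_edges_shrink(self):
        x = np.arange(10.0)
        y = moving_average_filter(x, 5)
        assert y.shape == x.shape
        assert y[0] == pytest.approx(np.mean(x[:3]))  # centred window clipped at edge

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            moving_average_filter(np.zeros(4), 5)


class TestRemoveBaseline:
    @pytest.mark.parametrize("method", ["highpass", "median-subtract"])
    def test_drift_attenuated(self, method):
        x = _sine(0.3, duration=30.0)
        y = remove_baseline(x, FS, FilterSpec(baseline_method=method))
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(y) <= 0.1 * rms(x)

    def test_passband_preserved_within_1db(self):
        x = _sine(1.0, duration=30.0)
        y = remove_baseline(x, FS)
        assert 20 * np.log10(_steady_amp(y)) > -1.0

    def test_zero_in_zero_out(self):
        np.testing.assert_allclose(remove_baseline(np.zeros(1000), FS), 0.0, atol=1e-12)

    def test_r_peak_positions_unchanged(self):
        """Zero-phase: R-peak argmax positions shift by at most 1 sample."""
        rr = generate_rr_series(SynthClassParams(60.0, 20.0, 1.0), 20, seed=0)
        rec, truth = synthesize_ecg(rr, fs=FS, noise=NoiseParams.silent())
        y = remove_baseline(rec.samples, FS)
        for rt in truth.r_times_s:
            idx = int(round(rt * FS))
            lo = idx - 20
            assert abs(np.argmax(y[lo : idx + 20]) + lo - idx) <= 1


class TestBandpass:
    def test_in_band_preserved(self):
        # long signal: the 0.5 Hz corner's edge transients settle slowly
        y = bandpass(_sine(10.0, duration=30.0), FS)
        assert _steady_amp(y) == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_attenuated(self):
        y = bandpass(_sine(60.0, duration=30.0), FS)
        assert _steady_amp(y) <= 0.1

    def test_dc_rejected(self):
        y = bandpass(np.full(2000, 1.0), FS)
        assert abs(y.mean()) < 0.01

    def test_band_validation(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, lo=40.0, hi=0.5)
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, lo=0.5, hi=150.0)

    def test_passband_idempotence(self):
        """Applying the full chain twice changes a pass-band sinusoid's
        amplitude by < 2% relative to one application."""
        x = _sine(3.0, duration=30.0)
        once = clean_signal(x, FS)
        twice = clean_signal(once, FS)
        assert abs(_steady_amp(twice) - _steady_amp(once)) / _steady_amp(once) < 0.02

    def test_chain_preserves_length(self, rng):
        x = rng.normal(size=4321)
        assert clean_signal(x, FS).shape == x.shape


class TestEstimateSNR:
    def test_identical_signals_capped(self, rng):
        x = rng.normal(size=1000)
        assert estimate_snr(x, x) == 99.0

    def test_constructed_zero_db(self, rng):
        cleaned = _sine(5.0, duration=50.0)  # power 0.5
        noise = rng.normal(scale=np.sqrt(0.5), size=cleaned.size)
        assert estimate_snr(cleaned + noise, cleaned) == pytest.approx(0.0, abs=0.5)

    def test_zero_cleaned_floor(self, rng):
        raw = rng.normal(size=500)
        assert estimate_snr(raw, np.zeros(500)) == -99.0

    def test_zero_length_error(self):
        with pytest.raises(ValueError):
            estimate_snr(np.array([]), np.array([]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            estimate_snr(np.zeros(5), np.zeros(6))


class TestRejectSegment:
    def test_clean_segment_kept(self):
        rr = generate_rr_series(SynthClassParams(65.0, 40.0, 1.0), 30, seed=1)
        rec, _ = synthesize_ecg(rr, fs=FS, noise=NoiseParams.silent())
        cleaned = bandpass(remove_baseline(rec.samples, FS), FS)
        entry = reject_segment(rec.samples, cleaned)
        assert entry.keep and entry.reason is None

    def test_amplitude_burst_rejected_first(self):
        x = _sine(5.0)
        x[300:320] += 10.0  # 10 mV artifact
        entry = reject_segment(x, np.zeros_like(x))
        assert not entry.keep and entry.reason == "amplitude"

    def test_low_snr_rejected(self, rng):
        cleaned = _sine(5.0, duration=30.0)
        noisy = cleaned + rng.normal(scale=np.sqrt(0.5 / 10**0.5), size=cleaned.size)
        entry = reject_segment(noisy, cleaned)  # ~5 dB by construction
        assert not entry.keep and entry.reason == "snr"
        assert entry.snr_db == pytest.approx(5.0, abs=1.0)


class TestSegmentRecord:
    @staticmethod
    def _record(duration_s):
        return ECGRecord(samples=np.zeros(int(duration_s * FS)), fs=FS,
                         subject_id="s1", borg_score=8)

    @pytest.mark.parametrize("window, expected", [(30.0, 20), (120.0, 5), (7.0, 85)])
    def test_counts_floor(self, window, expected):
        assert len(segment_record(self._record(600.0), window)) == expected

    def test_partial_window_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            segments = segment_record(self._record(29.0), 30.0)
        assert segments == []

    def test_segments_inherit_session_label(self):
        segments = segment_record(self._record(90.0), 30.0)
        assert [s.label for s in segments] == [FatigueClass.normal] * 3
        assert [s.provenance[3] for s in segments] == [0, 1, 2]


class TestStudyRejectionRate:
    def test_zero_noise_rejection_is_zero(self):
        from fatiguecg.preprocess import preprocess_study
        from fatiguecg.synth import generate_study

        manifest, _ = generate_study(n_subjects=1, n_days=1, seed=2,
                                     noise=NoiseParams.silent())
        _, report = preprocess_study(manifest)
        assert report.rejection_rate == 0.0
        assert len(report.entries) == 60  # 3 sessions x 20 segments

    def test_default_noise_rejection_bounded(self, small_segments):
        _, report = small_segments
        assert 0.0 <= report.rejection_rate <= 0.25
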