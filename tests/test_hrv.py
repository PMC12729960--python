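"""R-peak detection and HRV features against independent oracles.

The time-domain and Poincare oracles below are deliberately naive
per-element loops, written independently of the vectorised library path.
"""

import math

import numpy as np
import pytest

from fatiguecg.data_model import FatigueClass, Segment
from fatiguecg.hrv import (
    RRSeries,
    UnusableSegmentError,
    extract_features,
    frequency_domain_features,
    pan_tompkins,
    poincare_features,
    rr_from_peaks,
    time_domain_features,
)
from fatiguecg.preprocess import clean_signal
from fatiguecg.synth import NoiseParams, SynthClassParams, generate_rr_series, synthesize_ecg

FS = 200.0


# ---------------------------------------------------------------------------
# naive-loop oracles

def oracle_time_domain(rr):
    n = len(rr)
    mean = sum(rr) / n
    var = sum((x - mean) ** 2 for x in rr) / n
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    return mean, math.sqrt(var), rmssd, pnn50, 60000.0 / mean


def oracle_poincare(rr):
    n = len(rr)
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    dmean = sum(diffs) / len(diffs)
    dvar = sum((d - dmean) ** 2 for d in diffs) / len(diffs)
    sd1 = math.sqrt(dvar / 2.0)
    mean = sum(rr) / n
    sdnn2 = sum((x - mean) ** 2 for x in rr) / n
    sd2 = math.sqrt(max(0.0, 2.0 * sdnn2 - sd1 * sd1))
    return sd1, sd2


def _series(values):
    values = np.asarray(values, dtype=float)
    return RRSeries(values_ms=values, times_s=np.cumsum(values) / 1000.0)


def _modulated_series(freq_hz, amp_ms=30.0, duration_s=300.0, base_ms=1000.0):
    rr, times, t = [], [], 0.0
    while t < duration_s:
        interval = base_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t)
        rr.append(interval)
        t += interval / 1000.0
        times.append(t)
    return RRSeries(values_ms=np.array(rr), times_s=np.array(times))


class TestTimeDomainAndPoincare:
    def test_constant_series(self):
        td = time_domain_features(_series([800.0] * 3))
        assert (td.MeanRR, td.SDNN, td.RMSSD, td.pNN50) == (800.0, 0.0, 0.0, 0.0)
        assert td.MeanHR == pytest.approx(75.0)
        pc = poincare_features(_series([800.0] * 3))
        assert (pc.SD1, pc.SD2) == (0.0, 0.0)

    def test_single_difference_rmssd(self):
        assert time_domain_features(_series([800.0, 850.0])).RMSSD == pytest.approx(50.0)

    def test_alternating_series_sd1_closed_form(self):
        rr = _series([800.0, 850.0] * 100)
        assert poincare_features(rr).SD1 == pytest.approx(50.0 / np.sqrt(2), rel=1e-2)

    def test_oracle_equivalence_on_random_series(self, rng):
        """All five time-domain features and both Poincare features agree
        with the naive-loop oracle to 1e-9 relative on 1000 random series;
        SD1^2 + SD2^2 = 2 SDNN^2 holds identically."""
        for _ in range(1000):
            n = int(rng.integers(5, 120))
            rr = rng.uniform(400.0, 1500.0, size=n)
            series = _series(rr)
            td = time_domain_features(series)
            np.testing.assert_allclose(
                [td.MeanRR, td.SDNN, td.RMSSD, td.pNN50, td.MeanHR],
                oracle_time_domain(rr.tolist()), rtol=1e-9)
            pc = poincare_features(series)
            np.testing.assert_allclose([pc.SD1, pc.SD2], oracle_poincare(rr.tolist()),
                                       rtol=1e-9)
            if pc.SD2 > 0:  # identity's domain: SD2 not clipped at zero
                np.testing.assert_allclose(pc.SD1**2 + pc.SD2**2, 2 * td.SDNN**2,
                                           rtol=1e-9)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError, match="2"):
            time_domain_features(_series([800.0]))
        with pytest.raises(ValueError, match="3"):
            poincare_features(_series([800.0, 810.0]))


class TestFrequencyDomain:
    def test_constant_series_has_no_power(self):
        fd = frequency_domain_features(_series([1000.0] * 120))
        assert fd.LF < 1e-6 and fd.HF < 1e-6

    def test_hf_modulation_dominates(self):
        fd = frequency_domain_features(_modulated_series(0.25))
        assert fd.HF / (fd.LF + fd.HF) >= 0.9

    def test_lf_modulation_dominates(self):
        fd = frequency_domain_features(_modulated_series(0.10))
        assert fd.LF / (fd.LF + fd.HF) >= 0.9

    def test_short_span_refused(self):
        with pytest.raises(ValueError, match="20"):
            frequency_domain_features(_series([1000.0] * 10))


class TestPanTompkins:
    def test_noiseless_60bpm_count_and_timing(self):
        rr = generate_rr_series(SynthClassParams(60.0, 20.0, 1.0), 30, seed=2)
        rec, truth = synthesize_ecg(rr, fs=FS, noise=NoiseParams.silent())
        peaks = pan_tompkins(rec.samples, FS)
        assert 29 <= len(peaks) <= 31
        for rt in truth.r_times_s:
            assert np.abs(peaks.times_s - rt).min() < 0.020

    def test_zero_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="flat"):
            peaks = pan_tompkins(np.zeros(int(10 * FS)), FS)
        assert len(peaks) == 0

    def test_refractory_merges_close_bumps(self):
        """Two R-like bumps 150 ms apart yield exactly one detection."""
        t = np.arange(0, 4.0, 1 / FS)
        x = np.zeros_like(t)
        for beat in (0.8, 1.8, 2.8):  # regular rhythm to seed thresholds
            x += np.exp(-0.5 * ((t - beat) / 0.012) ** 2)
        x += np.exp(-0.5 * ((t - 2.95) / 0.012) ** 2)  # 150 ms after the last beat
        peaks = pan_tompkins(x, FS)
        in_window = (peaks.times_s > 2.7) & (peaks.times_s < 3.1)
        assert in_window.sum() == 1

    def test_stage_arrays_exposed(self):
        rr = generate_rr_series(SynthClassParams(60.0, 0.0, 1.0), 10, seed=0)
        rec, _ = synthesize_ecg(rr, fs=FS, noise=NoiseParams.silent())
        peaks = pan_tompkins(rec.samples, FS)
        for stage in ("bandpassed", "derivative", "squared", "integrated"):
            assert peaks.stages[stage].shape == rec.samples.shape


class TestRRFromPeaks:
    @staticmethod
    def _peaks(times_s):
        from fatiguecg.hrv import RPeakSeries

        return RPeakSeries(indices=(np.asarray(times_s) * FS).astype(int), fs=FS)

    def test_successive_differences(self):
        rr = rr_from_peaks(self._peaks([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(rr.values_ms, [1000.0, 1000.0])

    def test_gating_removes_long_interval(self):
        rr = rr_from_peaks(self._peaks([0.0, 1.0, 3.5]))
        np.testing.assert_allclose(rr.values_ms, [1000.0])
        assert rr.n_gated == 1

    def test_insufficient_beats(self):
        with pytest.raises(ValueError, match="insufficient"):
            rr_from_peaks(self._peaks([1.0]))

    def test_gated_mean_matches_generator(self):
        """End to end on 300 s of synthetic signal the detected RR mean is
        within 1% of the generator's ground-truth RR mean."""
        rrg = generate_rr_series(SynthClassParams(70.0, 50.0, 2.0), 300, seed=9)
        rec, truth = synthesize_ecg(rrg, fs=FS, noise=NoiseParams())
        peaks = pan_tompkins(clean_signal(rec.samples, FS), FS)
        rr = rr_from_peaks(peaks)
        assert rr.values_ms.mean() == pytest.approx(truth.rr_ms.mean(), rel=0.01)


class TestExtractFeatures:
    @staticmethod
    def _segment(samples, label=FatigueClass.normal):
        return Segment(samples=samples, fs=FS, label=label,
                       provenance=("s1", 1, "morning", 0))

    def test_noiseless_segment_recovers_hr(self):
        rr = generate_rr_series(SynthClassParams(60.0, 20.0, 1.0), 30, seed=4)
        rec, _ = synthesize_ecg(rr, fs=FS, noise=NoiseParams.silent())
        f = extract_features(self._segment(rec.samples[: int(30 * FS)]))
        assert f.MeanHR == pytest.approx(60.0, abs=1.0)

    def test_deterministic(self):
        rr = generate_rr_series(SynthClassParams(80.0, 40.0, 2.0), 30, seed=5)
        rec, _ = synthesize_ecg(rr, fs=FS, noise=NoiseParams())
        seg = self._segment(rec.samples[: int(30 * FS)])
        a, b = extract_features(seg), extract_features(seg)
        np.testing.assert_array_equal(a.to_array(), b.to_array())

    def test_flat_segment_flagged_unusable(self):
        with pytest.raises(UnusableSegmentError), pytest.warns(UserWarning):
            extract_features(self._segment(np.zeros(int(30 * FS))))

    def test_parameter_recovery_from_noiseless_synthetic(self):
        """Features recover mean HR within 1 bpm and SDNN within 10% of the
        generator parameters for a 300 s noiseless series."""
        params = SynthClassParams(72.0, 55.0, 1.5)
        rr = generate_rr_series(params, 300, seed=6)
        rec, _ = synthesize_ecg(rr, fs=FS, noise=NoiseParams.silent())
        peaks = pan_tompkins(rec.samples, FS)
        td = time_domain_features(rr_from_peaks(peaks))
        assert td.MeanHR == pytest.approx(params.mean_hr_bpm, abs=1.0)
        assert td.SDNN == pytest.approx(params.sdnn_target_ms, rel=0.10)

    def test_class_monotone_mean_hr_through_pipeline(self, small_features):
        """End to end: mean MeanHR rises monotonically across the three
        synthetic fatigue classes."""
        table, unusable = small_features
        assert len(unusable) == 0
        by_class = table.groupby("label")["MeanHR"].mean()
        assert by_class.loc[0] < by_class.loc[1] < by_class.loc[2]
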