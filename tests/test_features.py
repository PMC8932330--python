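"""Feature definitions against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguefuse import synthgen
from fatiguefuse.features import (
    RRSeries,
    band_powers_from_tachogram,
    detect_r_peaks,
    ecg_mean,
    extract_features,
    hrv_band_powers,
    iemg,
    mf,
    mpf,
    rms,
)
from fatiguefuse.records import (
    FEATURE_NAMES,
    QualityError,
    SignalRecord,
    UndefinedFeatureError,
)

FS = 2000.0


def synthetic_ecg(beat_times, fs=FS, duration=None):
    """Independent ECG construction: narrow Gaussian R spikes only."""
    duration = duration or (beat_times[-1] + 0.5)
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    for bt in beat_times:
        x += np.exp(-0.5 * ((t - bt) / 0.012) ** 2)
    return x


class TestRPeakDetection:
    def test_constant_rr_recovered(self):
        truth = np.arange(0.5, 59.5, 1.0)
        peaks = detect_r_peaks(synthetic_ecg(truth), FS)
        assert len(peaks) == len(truth)
        assert np.max(np.abs(peaks - truth)) <= 0.020

    def test_alternating_rr_recovered(self):
        rr = np.tile([0.8, 1.2], 15)
        truth = 0.5 + np.concatenate([[0], np.cumsum(rr[:-1])])
        peaks = detect_r_peaks(synthetic_ecg(truth), FS)
        assert len(peaks) == len(truth)
        rec_rr = np.diff(peaks)
        assert np.max(np.abs(rec_rr - rr[: len(rec_rr)])) <= 0.020

    def test_flat_signal_raises_quality_error(self):
        with pytest.raises(QualityError):
            detect_r_peaks(np.zeros(int(10 * FS)), FS)

    def test_short_window_rejected(self):
        with pytest.raises(QualityError):
            detect_r_peaks(np.ones(100), FS)

    def test_generator_ground_truth_recovered(self):
        rec = synthgen.generate_ecg(synthgen.SynthParams(duration_s=60.0, seed=4))
        peaks = detect_r_peaks(rec.channel("ecg"), rec.fs)
        truth = rec.ground_truth["r_peak_times"]
        assert len(peaks) == len(truth)
        assert np.max(np.abs(peaks - truth)) <= 0.020


class TestEcgMean:
    def test_arithmetic_mean(self):
        rr = RRSeries(beat_times=np.concatenate([[0], np.cumsum([0.8, 1.0, 1.2])]))
        assert ecg_mean(rr) == pytest.approx(1.0)

    def test_single_interval(self):
        assert ecg_mean(RRSeries([0.0, 0.75])) == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecg_mean(RRSeries([0.5]))


class TestHrvBandPowers:
    @staticmethod
    def modulated_beats(freq, amp=0.05, n=400):
        """Beat times whose RR series is 1.0 + amp·sin(2π·freq·t)."""
        beats = [0.0]
        for _ in range(n):
            t = beats[-1]
            beats.append(t + 1.0 + amp * np.sin(2 * np.pi * freq * t))
        return np.asarray(beats)

    def test_lf_modulated_tachogram_matches_parseval(self):
        # RR = 1.0 + 0.05 sin(2π·0.1·t): LF power = A²/2 by Parseval
        t = np.cumsum(np.full(400, 1.0))
        rr_vals = 1.0 + 0.05 * np.sin(2 * np.pi * 0.1 * t)
        lf, hf = band_powers_from_tachogram(t, rr_vals)
        assert lf == pytest.approx(0.05**2 / 2, rel=0.10)
        assert hf < 0.1 * lf
        lf2, hf2, ratio = hrv_band_powers(RRSeries(self.modulated_beats(0.1)))
        assert ratio > 10

    def test_hf_modulated_tachogram_gives_small_ratio(self):
        _, _, ratio = hrv_band_powers(RRSeries(self.modulated_beats(0.3)))
        assert ratio < 0.1

    def test_constant_tachogram_ratio_undefined(self):
        beats = np.concatenate([[0.0], np.cumsum(np.full(60, 1.0))])
        with pytest.raises(UndefinedFeatureError):
            hrv_band_powers(RRSeries(beats))

    def test_too_few_intervals_rejected(self):
        beats = np.arange(10) * 1.0
        with pytest.raises(ValueError):
            hrv_band_powers(RRSeries(beats))


class TestAmplitudeFeatures:
    def test_iemg_constant(self):
        assert iemg(np.full(2000, 2.0), 2000.0) == pytest.approx(2.0)

    def test_iemg_zeros_and_single_sample(self):
        assert iemg(np.zeros(100), 2000.0) == 0.0
        assert iemg(np.array([3.0]), 2000.0) == pytest.approx(0.0015)

    def test_iemg_empty_rejected(self):
        with pytest.raises(ValueError):
            iemg(np.array([]), 2000.0)

    def test_rms_sine_amplitude(self):
        t = np.arange(4000) / FS
        x = 2.0 * np.sin(2 * np.pi * 50 * t)  # whole periods
        assert rms(x) == pytest.approx(2.0 / np.sqrt(2), rel=1e-3)

    def test_rms_constant_sign(self):
        assert rms(np.full(10, -3.0)) == pytest.approx(3.0)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_rms_iemg_match_bruteforce(self, values):
        x = np.asarray(values)
        assert rms(x) == pytest.approx(
            float(np.sqrt(np.mean(x**2))), abs=1e-12)
        assert iemg(x, FS) == pytest.approx(
            float(np.sum(np.abs(x)) / FS), abs=1e-12)


class TestSpectralFeatures:
    def test_pure_tone(self):
        t = np.arange(2**14) / FS
        x = np.sin(2 * np.pi * 80 * t)
        assert mpf(x, FS) == pytest.approx(80.0, abs=1.0)
        assert mf(x, FS) == pytest.approx(80.0, abs=1.0)

    def test_two_equal_tones_centroid(self):
        t = np.arange(2**14) / FS
        x = np.sin(2 * np.pi * 40 * t) + np.sin(2 * np.pi * 120 * t)
        assert mpf(x, FS) == pytest.approx(80.0, abs=1.0)
        assert 40.0 <= mf(x, FS) <= 120.0

    def test_bandlimited_white_noise_centroid(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2**16)
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(len(x), 1 / FS)
        spec[f > 500] = 0.0
        x = np.fft.irfft(spec, n=len(x))
        assert mpf(x, FS) == pytest.approx(250.0, rel=0.05)
        assert mf(x, FS) == pytest.approx(250.0, rel=0.05)

    def test_mf_matches_cumulative_sum_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8192)
        from fatiguefuse.features import psd

        f, p = psd(x, FS)
        cum = np.concatenate(
            [[0.0], np.cumsum(np.diff(f) * (p[1:] + p[:-1]) / 2)])
        expected = np.interp(cum[-1] / 2, cum, f)
        assert mf(x, FS) == pytest.approx(expected, abs=1e-9)

    def test_zero_signal_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            mpf(np.zeros(4096), FS)
        with pytest.raises(UndefinedFeatureError):
            mf(np.zeros(4096), FS)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            mpf(np.ones(100), FS)


@pytest.fixture(scope="module")
def window():
    return synthgen.generate_window(
        synthgen.SynthParams(duration_s=30.0, seed=21, state=0))


class TestExtractFeatures:

    def test_feature_order_is_stable(self, window):
        fv1 = extract_features(window)
        fv2 = extract_features(window)
        np.testing.assert_array_equal(fv1.values, fv2.values)
        assert tuple(fv1.as_dict()) == FEATURE_NAMES
        assert fv1.label == 0

    def test_all_features_finite(self, window):
        fv = extract_features(window)
        assert np.all(np.isfinite(fv.values))
        assert fv.values[5] > 0 and fv.values[5] < window.fs / 2  # MPF range

    def test_flat_ecg_error_names_channel(self, window):
        bad = SignalRecord(
            samples={"ecg": np.zeros(window.n_samples),
                     "semg_r": window.channel("semg_r"),
                     "semg_l": window.channel("semg_l")},
            fs=window.fs, label=0)
        with pytest.raises(QualityError, match="ECG"):
            extract_features(bad)

    def test_semg_scale_invariance(self, window):
        """×k scales IEMG and RMS by k; MPF/MF move < 0.5 Hz."""
        k = 3.7
        scaled = SignalRecord(
            samples={"ecg": window.channel("ecg"),
                     "semg_r": k * window.channel("semg_r"),
                     "semg_l": window.channel("semg_l")},
            fs=window.fs, label=window.label)
        a = extract_features(window).values
        b = extract_features(scaled).values
        assert b[3] == pytest.approx(k * a[3], rel=1e-9)  # IEMG
        assert b[4] == pytest.approx(k * a[4], rel=1e-9)  # RMS
        assert abs(b[5] - a[5]) < 0.5  # MPF
        assert abs(b[6] - a[6]) < 0.5  # MF

    def test_time_shift_changes_spectral_features_little(self, window):
        x = window.channel("semg_r")
        shifted = np.roll(x, len(x) // 3)
        assert mpf(shifted, window.fs) == pytest.approx(
            mpf(x, window.fs), rel=0.01)
        assert mf(shifted, window.fs) == pytest.approx(
            mf(x, window.fs), rel=0.01)

    def test_relaxed_vs_tired_spectral_compression(self, study_default):
        """Batch means: tired windows show lower MPF than relaxed ones."""
        X, y = study_default
        mpf_r = X[:, 5]
        assert mpf_r[y == -1].mean() > mpf_r[y == 1].mean() + 10
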