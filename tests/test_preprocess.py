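"""Preprocessing chain: smoothing, baseline, noise, detection, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepdiscover.preprocess import (
    PreprocessError,
    PreprocessParams,
    detect_peaks,
    estimate_baseline,
    estimate_noise,
    normalize_tic,
    preprocess_spectrum,
    smooth,
    subtract_baseline,
)
from pepdiscover.spectra import Spectrum


def _spec(intensity, mz=None):
    intensity = np.asarray(intensity, float)
    if mz is None:
        mz = 1000.0 + np.arange(len(intensity))
    return Spectrum(np.asarray(mz, float), intensity, "t")


class TestSmooth:
    def test_truncated_window_hand_computed(self):
        out = smooth(_spec([0, 0, 10, 0, 0]), 5)
        np.testing.assert_allclose(out.intensity, [10 / 3, 10 / 4, 2, 10 / 4, 10 / 3])

    def test_window_one_is_identity(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        np.testing.assert_array_equal(smooth(_spec(x), 1).intensity, x)

    def test_constant_spectrum_unchanged(self):
        out = smooth(_spec(np.full(20, 7.0)), 5)
        np.testing.assert_allclose(out.intensity, 7.0)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(PreprocessError):
            smooth(_spec([1, 2, 3]), window)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 40))
        lhs = smooth(_spec(a * x + b * y), 5).intensity
        rhs = a * smooth(_spec(x), 5).intensity + b * smooth(_spec(y), 5).intensity
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestBaseline:
    def test_flat_spectrum_baseline_is_that_constant(self):
        s = _spec(np.full(500, 3.5))
        np.testing.assert_allclose(estimate_baseline(s, 100.0), 3.5)

    def test_single_impulse_on_zero_background(self):
        x = np.zeros(500)
        x[250] = 100.0
        np.testing.assert_allclose(estimate_baseline(_spec(x), 100.0), 0.0)

    def test_two_peaks_on_linear_ramp(self):
        mz = 1000.0 + np.arange(1001)
        ramp = 0.01 * (mz - 1000.0)
        peaks = 100.0 * (np.exp(-0.5 * ((mz - 1400) / 5) ** 2)
                         + np.exp(-0.5 * ((mz - 1600) / 5) ** 2))
        baseline = estimate_baseline(_spec(ramp + peaks, mz), 800.0)
        valley = (mz >= 1450) & (mz <= 1550)
        assert np.max(np.abs(baseline[valley] - ramp[valley])) < 1.0  # < height/100

    def test_window_wider_than_span_flat_minimum(self):
        s = _spec([5.0, 3.0, 4.0, 6.0])
        with pytest.warns(UserWarning, match="wider"):
            baseline = estimate_baseline(s, 1000.0)
        np.testing.assert_allclose(baseline, 3.0)

    def test_baseline_never_exceeds_spectrum_maximum(self, rng):
        x = rng.gamma(2.0, 10.0, size=2000)
        baseline = estimate_baseline(_spec(x), 100.0)
        assert baseline.max() <= x.max() + 1e-12
        assert len(baseline) == 2000


class TestSubtractBaseline:
    def test_subtract_own_values_gives_zero(self):
        s = _spec([1.0, 5.0, 2.0])
        np.testing.assert_array_equal(subtract_baseline(s, s.intensity).intensity, 0.0)

    def test_zero_baseline_is_identity(self):
        s = _spec([1.0, 5.0, 2.0])
        np.testing.assert_array_equal(subtract_baseline(s, np.zeros(3)).intensity,
                                      s.intensity)

    def test_clamped_at_zero(self):
        out = subtract_baseline(_spec([5.0, 5.0]), np.array([7.0, 3.0]))
        np.testing.assert_array_equal(out.intensity, [0.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(PreprocessError, match="length"):
            subtract_baseline(_spec([1.0, 2.0]), np.zeros(3))


class TestNoise:
    def test_gaussian_noise_level_recovered(self, rng):
        s = _spec(rng.normal(0.0, 1.0, size=8000))
        level = estimate_noise(s, 100.0)
        assert 0.9 < np.median(level) < 1.1

    def test_all_zero_spectrum_gives_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no local variation"):
            level = estimate_noise(_spec(np.zeros(300)), 100.0)
        np.testing.assert_array_equal(level, 0.0)

    def test_scale_equivariance(self, rng):
        x = rng.normal(0.0, 1.0, size=2000)
        one = estimate_noise(_spec(x), 100.0)
        two = estimate_noise(_spec(2.0 * x), 100.0)
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-12)


class TestDetectPeaks:
    def test_flat_spectrum_no_peaks(self):
        s = _spec(np.full(100, 2.0))
        assert len(detect_peaks(s, np.ones(100), 5.0)) == 0

    def test_single_gaussian_snr_and_centroid(self):
        mz = 1000.0 + np.arange(200)
        x = 10.0 * np.exp(-0.5 * ((mz - 1100.0) / 3.0) ** 2)
        peaks = detect_peaks(_spec(x, mz), np.ones(200), 5.0)
        assert len(peaks) == 1
        assert peaks.peaks[0].snr == pytest.approx(10.0)
        assert abs(peaks.peaks[0].mz - 1100.0) <= 0.5

    @pytest.mark.parametrize("height,expected", [(5.0, 1), (4.99, 0)])
    def test_snr_cutoff_boundary_inclusive(self, height, expected):
        mz = 1000.0 + np.arange(100)
        x = height * np.exp(-0.5 * ((mz - 1050.0) / 3.0) ** 2)
        assert len(detect_peaks(_spec(x, mz), np.ones(100), 5.0)) == expected

    def test_plateau_resolved_to_leftmost_point(self):
        x = np.array([0.0, 0, 8, 8, 8, 0, 0])
        peaks = detect_peaks(_spec(x), np.ones(7), 5.0)
        assert len(peaks) == 1
        # centroid over the plateau, not the right edge
        assert peaks.peaks[0].mz == pytest.approx(1003.0)

    def test_monotone_in_cutoff(self, rng):
        mz = 1000.0 + np.arange(3000)
        x = np.abs(rng.normal(0, 1, size=3000))
        for center, h in [(1200, 8), (1800, 20), (2500, 4)]:
            x += h * np.exp(-0.5 * ((mz - center) / 3.0) ** 2)
        noise = np.ones(3000)
        previous = None
        for cutoff in [2.0, 4.0, 6.0, 10.0, 20.0]:
            mzs = set(np.round(detect_peaks(_spec(x, mz), noise, cutoff).mzs, 6))
            if previous is not None:
                assert mzs <= previous, "raising the cut-off must never add a peak"
            previous = mzs

    def test_zero_noise_gives_infinite_snr(self):
        x = np.array([0.0, 0, 5, 0, 0])
        peaks = detect_peaks(_spec(x), np.zeros(5), 5.0)
        assert len(peaks) == 1
        assert np.isinf(peaks.peaks[0].snr)


class TestNormalizeTic:
    def test_simple_proportions(self):
        out = normalize_tic(_spec([1.0, 3.0]))
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])

    def test_sum_is_one(self, rng):
        out = normalize_tic(_spec(rng.gamma(2.0, 5.0, size=500)))
        assert abs(out.intensity.sum() - 1.0) < 1e-12

    def test_idempotent(self, rng):
        s = _spec(rng.gamma(2.0, 5.0, size=50))
        once = normalize_tic(s)
        twice = normalize_tic(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(PreprocessError, match="TIC"):
            normalize_tic(_spec(np.zeros(10)))


class TestPreprocessChain:
    def test_noiseless_single_peak_detected(self):
        mz = 1000.0 + np.arange(2000)
        x = 50.0 * np.exp(-0.5 * ((mz - 1500.0) / 2.0) ** 2) + 5.0
        _, peaks = preprocess_spectrum(
            Spectrum(mz, x, "p"), PreprocessParams(mz_min=1000, mz_max=3000)
        )
        assert len(peaks) == 1
        assert abs(peaks.peaks[0].mz - 1500.0) < 1.0

    def test_pure_function(self, small_cohort):
        s = small_cohort.spectra[0]
        out1, peaks1 = preprocess_spectrum(s, PreprocessParams())
        out2, peaks2 = preprocess_spectrum(s, PreprocessParams())
        np.testing.assert_array_equal(out1.intensity, out2.intensity)
        assert peaks1.peaks == peaks2.peaks

    def test_processing_log_records_every_step(self, small_cohort):
        out, _ = preprocess_spectrum(small_cohort.spectra[0], PreprocessParams())
        joined = ";".join(out.processing_log)
        for step in ("crop", "smooth", "subtract_baseline", "normalize_tic",
                     "detect_peaks"):
            assert step in joined

    def test_planted_peak_recall_and_centroid_accuracy(self, small_cohort):
        """Strong planted peaks (S/N >= 10) are recovered within one grid step."""
        step = small_cohort.truth.sampling_step
        params = PreprocessParams()
        total = matched = 0
        centroid_errors = []
        for s in small_cohort.spectra[:10]:
            _, peaks = preprocess_spectrum(s, params)
            detected = peaks.mzs
            truth = small_cohort.ground_truth
            rows = truth[(truth.sample_id == s.sample_id) & (truth.planted_snr >= 10.0)]
            for apex in rows.apex_mz:
                total += 1
                err = np.min(np.abs(detected - apex)) if len(detected) else np.inf
                if err <= step:
                    matched += 1
                    centroid_errors.append(err)
        assert total > 100
        assert matched / total >= 0.95
        assert np.median(centroid_errors) <= 0.5 * step
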