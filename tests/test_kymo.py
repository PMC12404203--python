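"""Kymograph construction, extrema detection, oscillation features."""

import dataclasses

import numpy as np
import pytest

import somitoclock as sc
from somitoclock.axis import AxisPath, axis_from_mask, build_axis
from somitoclock.kymo import (
    Kymograph,
    build_kymograph,
    compare_cohorts,
    detect_extrema,
    directionality_score,
    extract_anterior_trace,
    filter_movie,
    summarize_oscillation,
)
from somitoclock.preprocess import Mask, Movie


def straight_axis(mask: Mask) -> AxisPath:
    rows = np.flatnonzero(mask.data.any(axis=1))
    cols = np.flatnonzero(mask.data.any(axis=0))
    mid = (rows[0] + rows[-1]) / 2.0
    centers = np.array([[mid, cols[0] + 2.0], [mid, cols[-1] - 2.0]])
    return build_axis(centers, mask, orientation="keep")


class TestFilterMovie:
    def test_salt_pixel_removed(self):
        frame = np.full((15, 15), 10.0)
        frame[7, 7] = 1000.0
        movie = Movie(data=frame[None].repeat(2, axis=0), frame_interval_min=10)
        out = filter_movie(movie, gaussian_sigma=0.0)
        assert out.data[0, 7, 7] == pytest.approx(10.0)

    def test_constant_frame_unchanged(self):
        movie = Movie(data=np.full((2, 16, 16), 5.0), frame_interval_min=10)
        np.testing.assert_allclose(filter_movie(movie).data, 5.0)

    def test_matches_reference_median_then_gaussian(self):
        """Direct filter oracle: hand-rolled 3x3 median (sorted-neighbourhood,
        nearest-edge padding) then explicit Gaussian convolution."""
        rng = np.random.default_rng(5)
        frame = rng.uniform(0, 100, size=(20, 20))
        movie = Movie(data=frame[None].repeat(2, axis=0), frame_interval_min=10)
        out = filter_movie(movie)

        # symmetric boundary reflection matches the filters' default handling
        padded = np.pad(frame, 1, mode="symmetric")
        med = np.empty_like(frame)
        for r in range(20):
            for c in range(20):
                med[r, c] = np.sort(padded[r:r + 3, c:c + 3].ravel())[4]
        # separable Gaussian, sigma=1, kernel reach 4 sigma
        radius = 4
        x = np.arange(-radius, radius + 1)
        kern = np.exp(-x**2 / 2.0)
        kern /= kern.sum()
        smooth = np.apply_along_axis(
            lambda v: np.convolve(np.pad(v, radius, mode="symmetric"), kern, "valid"),
            0, med)
        smooth = np.apply_along_axis(
            lambda v: np.convolve(np.pad(v, radius, mode="symmetric"), kern, "valid"),
            1, smooth)
        np.testing.assert_allclose(out.data[0], smooth, atol=1e-6)


class TestBuildKymograph:
    def test_constant_band_gives_constant_kymograph(self, straight_band_mask):
        data = np.full((4, 256, 256), 7.0)
        movie = Movie(data=data, frame_interval_min=10)
        kymo = build_kymograph(movie, straight_axis(straight_band_mask),
                               straight_band_mask, smooth_sigma=0)
        np.testing.assert_allclose(kymo.data, 7.0, atol=1e-6)

    def test_row_equals_direct_column_mean(self, straight_band_mask):
        """Column-mean oracle on a straight horizontal band: each kymograph
        entry equals the mean of the band's in-mask column values."""
        rng = np.random.default_rng(11)
        data = np.zeros((3, 256, 256))
        data[:, 103:153, 38:218] = rng.uniform(50, 150, size=(3, 50, 180))
        movie = Movie(data=data, frame_interval_min=10)
        axis = straight_axis(straight_band_mask)
        kymo = build_kymograph(movie, axis, straight_band_mask, smooth_sigma=0)
        for t in range(3):
            for i in (0, 50, -1):
                col = int(round(axis.polyline[i][1]))
                expected = data[t, 103:153, col].mean()
                assert kymo.data[i, t] == pytest.approx(expected, rel=0.02)

    def test_wave_ridge_advances_monotonically(self, small_analysis):
        """Generator phase model: within a cycle, the per-row time of peak
        increases from the posterior row to the anterior row."""
        _, _, _, inter = small_analysis
        kymo = inter["kymograph"]
        n = kymo.n_rows
        rows = [int(n * f) for f in (0.15, 0.35, 0.55, 0.75)]
        period_frames = 26
        first_peaks = [int(np.argmax(kymo.data[r, :period_frames])) for r in rows]
        assert (np.diff(first_peaks) > 0).all()


class TestAnteriorTrace:
    def test_window_rows(self):
        kymo = Kymograph(data=np.arange(100)[:, None].repeat(4, 1).astype(float),
                         s_step=1, t_step=10)
        trace = extract_anterior_trace(kymo, 0.8)
        # rows 77..81 centred on round(0.8 * 99) = 79
        assert trace[0] == pytest.approx(np.mean([77, 78, 79, 80, 81]))

    def test_constant_kymograph_gives_constant_trace(self):
        kymo = Kymograph(data=np.full((50, 8), 3.0), s_step=1, t_step=10)
        np.testing.assert_allclose(extract_anterior_trace(kymo), 3.0)

    def test_noiseless_trace_period(self, wt_preset):
        movie, truth = sc.generate_somitoid_movie(
            dataclasses.replace(wt_preset, noise_sd=0.0))
        _, inter = sc.pipeline.analyze_movie(movie)
        trace = inter["trace"]
        spec = np.abs(np.fft.rfft(trace - trace.mean()))
        k = int(np.argmax(spec[1:])) + 1
        assert len(trace) * 10.0 / k == pytest.approx(258.0, abs=10.0)


class TestDetectExtrema:
    def _sinusoid(self, period_min, dt=10.0, n=157, phase=0.3):
        t = np.arange(n) * dt
        return np.cos(2 * np.pi * t / period_min - phase)

    def test_peak_gaps_frame_quantized(self):
        """Frame-quantised sinusoid oracle: a 258-min period sampled at 10 min
        yields successive peak gaps of 250 or 260 min."""
        trace = self._sinusoid(258.0)
        peaks, _ = detect_extrema(trace, 10.0)
        gaps = np.diff(peaks) * 10.0
        assert set(gaps) <= {250.0, 260.0}
        assert np.mean(gaps) == pytest.approx(258.0, abs=10.0)

    @pytest.mark.parametrize("period_h", [3.5, 4.3, 5.0, 6.0])
    def test_error_at_most_one_frame_across_periods(self, period_h):
        trace = self._sinusoid(period_h * 60.0, n=400)
        peaks, troughs = detect_extrema(trace, 10.0)
        assert np.mean(np.diff(peaks)) * 10.0 == pytest.approx(
            period_h * 60.0, abs=10.0)
        assert np.mean(np.diff(troughs)) * 10.0 == pytest.approx(
            period_h * 60.0, abs=10.0)

    def test_short_period_suppressed_by_min_period(self):
        trace = self._sinusoid(120.0)
        peaks, _ = detect_extrema(trace, 10.0, min_period_h=3.0)
        if peaks.size >= 2:
            assert (np.diff(peaks) * 10.0 >= 180.0).all()

    def test_monotone_ramp_has_no_peaks(self):
        peaks, troughs = detect_extrema(np.linspace(0, 1, 157), 10.0)
        assert peaks.size == 0

    def test_extrema_interleave(self):
        rng = np.random.default_rng(3)
        trace = self._sinusoid(258.0) + rng.normal(0, 0.05, 157)
        peaks, troughs = detect_extrema(trace, 10.0)
        merged = sorted([(p, "p") for p in peaks] + [(t, "t") for t in troughs])
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestSummarize:
    def test_period_arithmetic(self):
        trace = np.zeros(100)
        peaks = np.array([6, 36, 66])
        troughs = np.array([21, 51])
        s = summarize_oscillation(trace, (peaks, troughs), 10.0)
        np.testing.assert_allclose(s.periods, [300.0, 300.0])
        assert s.mean_period == pytest.approx(300.0)
        assert s.n_peaks == 3

    def test_noiseless_wt_recovers_period(self, wt_preset):
        movie, _ = sc.generate_somitoid_movie(
            dataclasses.replace(wt_preset, noise_sd=0.0))
        summary, _ = sc.pipeline.analyze_movie(movie)
        assert summary.mean_period == pytest.approx(258.0, abs=10.0)

    def test_fewer_than_two_peaks_flagged(self):
        trace = np.zeros(100)
        s = summarize_oscillation(trace, (np.array([5]), np.array([], dtype=int)), 10.0)
        assert np.isnan(s.mean_period) and s.periods.size == 0

    def test_damped_cohort_peak_count(self):
        """Damped mutant preset: the wave falls below detection prominence
        after the third peak in at least 80% of movies."""
        cohort = sc.generate_cohort(sc.PRESETS["s2513a_embedded_damped"], 5, 21)
        counts = []
        for movie, _ in cohort:
            summary, _ = sc.pipeline.analyze_movie(movie)
            counts.append(summary.n_peaks)
        assert np.mean(np.array(counts) <= 3) >= 0.8

    def test_affine_intensity_equivariance(self):
        """trace -> a*trace + c scales amplitude by a and maps troughs
        affinely."""
        t = np.arange(157) * 10.0
        trace = 100 + 50 * np.cos(2 * np.pi * t / 258.0 - 1.0)
        ext = detect_extrema(trace, 10.0)
        s0 = summarize_oscillation(trace, ext, 10.0)
        a, c = 2.5, 30.0
        s1 = summarize_oscillation(a * trace + c, detect_extrema(a * trace + c, 10.0), 10.0)
        assert s1.amplitude == pytest.approx(a * s0.amplitude, rel=1e-9)
        assert s1.trough_intensity == pytest.approx(a * s0.trough_intensity + c, rel=1e-9)


class TestDirectionality:
    def test_posterior_wave_scores_three(self, small_analysis):
        _, _, summary, _ = small_analysis
        assert summary.directionality_score == 3

    def test_center_origin_scores_at_most_one(self, small_preset):
        movie, _ = sc.generate_somitoid_movie(
            dataclasses.replace(small_preset, origin="center", seed=13))
        summary, _ = sc.pipeline.analyze_movie(movie)
        assert summary.directionality_score <= 1

    def test_flat_movie_scores_zero(self, straight_band_mask):
        rng = np.random.default_rng(2)
        data = np.full((40, 256, 256), 5.0) + rng.normal(0, 0.1, (40, 256, 256))
        data[:, 103:153, 38:218] = 100.0 + rng.normal(0, 0.1, (40, 50, 180))
        kymo = build_kymograph(
            Movie(data=data, frame_interval_min=30),
            straight_axis(straight_band_mask), straight_band_mask)
        assert directionality_score(kymo) == 0

    def test_reversed_axis_flips_direction(self, small_movie):
        """Reversing the axis orientation turns the P->A wave into an A->P
        wave: the score drops from 3 to 1."""
        movie, truth = small_movie
        cfg = sc.pipeline.PipelineConfig(orientation="reverse")
        summary, inter = sc.pipeline.analyze_movie(movie, cfg)
        # with auto orientation this movie scores 3 (small_analysis fixture)
        assert summary.directionality_score == 1


class TestCompareCohorts:
    def test_identical_cohorts_ratio_100(self):
        vals = [250.0, 260.0, 258.0, 262.0]
        summaries = []
        for v in vals:
            s = summarize_oscillation(
                np.zeros(80), (np.array([0, int(v // 10)]), np.array([], int)), 10.0)
            summaries.append(s)
        c = compare_cohorts(summaries, summaries, "mean_period", seed=0)
        assert c.ratio_percent == pytest.approx(100.0)
        assert c.difference == pytest.approx(0.0)
        assert c.ci_low <= 0.0 <= c.ci_high

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_cohorts([], [], "mean_period")
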