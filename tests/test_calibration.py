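"""Threshold calibration: dark statistics, gains, dose, common mode."""

import numpy as np
import pytest
from scipy import stats

from recode.calibration import (
    CalibrationFrame,
    area_filter,
    build_calibration_frame,
    calibrate_on_the_fly,
    common_mode_correct,
    estimate_dose_per_pixel,
    estimate_global_threshold,
    pixel_dark_levels,
    pixel_gains,
    sigma_to_rate,
)
from recode.analysis import count_frames
from recode.reduction import label_components
from recode.simulator import ShapeLibrary, SimulationConfig, simulate_frames


def _sample_with_moments(mu, sd, n=200, seed=0):
    """Sample with *exactly* the requested mean and ddof=1 standard deviation."""
    z = np.random.default_rng(seed).normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mu + sd * z


class TestGlobalThreshold:
    def test_three_sigma_tail(self):
        sample = _sample_with_moments(100.0, 10.0)
        thr = estimate_global_threshold(sample, r=sigma_to_rate(3.0))
        assert thr == pytest.approx(130.0, abs=1e-9)

    def test_half_rate_gives_the_mean(self):
        sample = _sample_with_moments(77.0, 5.0)
        assert estimate_global_threshold(sample, r=0.5) == pytest.approx(77.0)

    def test_matches_inverse_cdf_on_fitted_normal(self):
        # frozen oracle: N(50, 4^2) at r=0.0227 has its (1-r) quantile near 58
        sample = np.random.default_rng(5).normal(50.0, 4.0, size=20000)
        thr = estimate_global_threshold(sample, r=0.0227)
        oracle = float(stats.norm(sample.mean(), sample.std(ddof=1)).isf(0.0227))
        assert thr == pytest.approx(oracle, abs=1e-9)
        assert thr == pytest.approx(58.0, abs=0.5)  # Monte-Carlo margin

    def test_raising_rate_lowers_threshold(self):
        sample = _sample_with_moments(100.0, 4.0)
        rates = [0.0005, 0.005, 0.05, 0.3]
        thresholds = [estimate_global_threshold(sample, r) for r in rates]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_global_threshold(np.array([1.0]), r=0.1)
        with pytest.raises(ValueError):
            estimate_global_threshold(np.array([1.0, np.nan]), r=0.1)
        with pytest.raises(ValueError):
            estimate_global_threshold(np.array([1.0, 2.0]), r=0.7)


class TestDarkLevels:
    def test_median_robust_to_rare_events(self):
        trace = np.full((100, 1, 1), 100.0)
        trace[17] = 500.0  # one electron hit in 100 frames
        assert pixel_dark_levels(trace)[0, 0] == 100.0

    def test_small_trace_median(self):
        trace = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        assert pixel_dark_levels(trace)[0, 0] == 2.0

    def test_matches_sorting_oracle(self, rng):
        frames = rng.normal(100, 5, size=(31, 6, 6))
        med = pixel_dark_levels(frames)
        oracle = np.sort(frames, axis=0)[15]
        assert np.allclose(med, oracle)

    def test_single_frame_warns(self):
        with pytest.warns(UserWarning, match="single-frame"):
            out = pixel_dark_levels(np.full((1, 2, 2), 7.0))
        assert np.all(out == 7.0)


class TestGains:
    def test_median_of_top_values(self):
        trace = np.array([0.0, 0.0, 0.0, 50.0, 60.0]).reshape(5, 1, 1)
        g = pixel_gains(trace, total_dose=2, dark_level=np.zeros((1, 1)))
        assert g[0, 0] == 55.0

    def test_all_zero_trace(self):
        trace = np.zeros((5, 1, 1))
        g = pixel_gains(trace, total_dose=1, dark_level=np.zeros((1, 1)))
        assert g[0, 0] == 0.0

    def test_dose_exceeding_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            pixel_gains(np.zeros((5, 1, 1)), total_dose=5)

    def test_recovers_single_electron_amplitude(self):
        # ~1% of frames carry a 120-ADU hit; median of the top-N values
        # across frames recovers the amplitude
        rng = np.random.default_rng(3)
        n_frames = 1000
        frames = rng.normal(100, 3, size=(n_frames, 8, 8))
        hits = rng.random((n_frames, 8, 8)) < 0.01
        frames[hits] += 120.0
        dark = pixel_dark_levels(frames)
        g = pixel_gains(frames, total_dose=10, dark_level=dark)
        assert np.median(g) == pytest.approx(120.0, rel=0.05)


class TestDoseEstimate:
    def test_single_puddle_at_only_possible_center(self):
        # an 11x11 frame admits exactly one 11x11 patch, centered at (5,5)
        frames = np.random.default_rng(0).normal(100, 2, size=(50, 11, 11))
        frames[9, 5, 5] += 80.0
        est = estimate_dose_per_pixel(frames, n_patches=4, patch_size=11, rng_seed=0)
        assert est.dose_per_pixel == 1.0

    def test_zero_signal_stack(self):
        frames = np.random.default_rng(1).normal(100, 2, size=(40, 16, 16))
        est = estimate_dose_per_pixel(frames, n_patches=8, patch_size=5, rng_seed=1)
        assert est.dose_per_pixel <= 0.3  # only rare noise exceedances

    def test_patch_larger_than_frame_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            estimate_dose_per_pixel(np.zeros((5, 8, 8)), patch_size=11)

    def test_even_patch_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            estimate_dose_per_pixel(np.zeros((5, 16, 16)), patch_size=10)

    def test_recovers_simulated_dose(self):
        # 0.005 e/pixel/frame over 200 frames = 1.0 e/pixel total
        cfg = SimulationConfig(
            dose_rate=0.005,
            shape=(96, 96),
            n_frames=200,
            shape_library=ShapeLibrary.fixed_1px(),
            amp_mean=60.0,
            amp_sigma=0.0,
            seed=21,
        )
        stack, _ = simulate_frames(cfg)
        est = estimate_dose_per_pixel(stack, n_patches=64, patch_size=11, rng_seed=2)
        assert abs(est.dose_per_pixel - 1.0) <= 3 * est.standard_error + 0.05


class TestBuildCalibrationFrame:
    def test_pixel_matching_global_gets_global_threshold(self):
        calib = build_calibration_frame(130.0, 100.0, 50.0,
                                        np.full((2, 2), 100.0), np.full((2, 2), 50.0))
        assert np.all(calib.threshold == 130.0)

    def test_dark_shift(self):
        calib = build_calibration_frame(130.0, 100.0, 50.0,
                                        np.full((1, 1), 105.0), np.full((1, 1), 50.0))
        assert calib.threshold[0, 0] == 135.0

    def test_gain_scaling(self):
        # margin 30, double gain, dark 80 -> 80 + 30*2 = 140
        calib = build_calibration_frame(110.0, 80.0, 50.0,
                                        np.full((1, 1), 80.0), np.full((1, 1), 100.0))
        assert calib.threshold[0, 0] == 140.0

    def test_dead_pixel_flagged(self):
        gain = np.array([[50.0, 0.0]])
        calib = build_calibration_frame(130.0, 100.0, 50.0, np.full((1, 2), 100.0), gain)
        assert calib.threshold[0, 0] == 130.0
        assert np.isinf(calib.threshold[0, 1])
        assert calib.dead_pixel_mask[0, 1]


class TestCommonMode:
    def test_constant_block_offset_removed(self):
        dark = np.random.default_rng(0).normal(100, 1, size=(8, 512))
        frame = dark.copy()
        frame[0:4, 0:256] += 7.5  # correlated offset on one readout block
        out = common_mode_correct(frame, dark, block_shape=(4, 256))
        assert np.allclose(out, dark, atol=1e-9)

    def test_zero_frame_unchanged(self):
        z = np.zeros((8, 512))
        assert np.allclose(common_mode_correct(z, z), 0.0)

    def test_random_block_offsets_cancel(self, rng):
        dark = rng.normal(100, 2, size=(16, 512))
        frame = dark.copy()
        offsets = rng.uniform(-5, 5, size=(4, 2))
        for i in range(4):
            for j in range(2):
                frame[4 * i : 4 * (i + 1), 256 * j : 256 * (j + 1)] += offsets[i, j]
        out = common_mode_correct(frame, dark, block_shape=(4, 256))
        resid = out - dark
        for i in range(4):
            for j in range(2):
                blk = resid[4 * i : 4 * (i + 1), 256 * j : 256 * (j + 1)]
                assert abs(np.median(blk)) < 1e-9

    def test_signal_pixels_excluded_from_offset(self):
        dark = np.full((4, 256), 100.0)
        frame = dark.copy()
        frame[0, :200] = 400.0  # bright puddle pixels must not bias the median
        thr = np.full((4, 256), 120.0)
        out = common_mode_correct(frame, dark, threshold=thr, block_shape=(4, 256))
        assert np.allclose(out[1], 100.0)

    def test_all_signal_block_warns(self):
        dark = np.full((4, 4), 100.0)
        frame = np.full((4, 4), 500.0)
        with pytest.warns(UserWarning, match="no noise pixels"):
            out = common_mode_correct(frame, dark, threshold=np.full((4, 4), 120.0),
                                      block_shape=(4, 4))
        assert np.all(out == 500.0)


class TestAreaFilter:
    @staticmethod
    def _pset():
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True  # area 1
        mask[2, 2:4] = True  # area 2
        mask[5:7, 5:8] = True
        mask[7, 5] = True  # area 7
        return label_components(mask)

    def test_band_filter(self):
        kept = area_filter(self._pset(), max_area=6, min_area=2)
        assert [p.area for p in kept.puddles] == [2]
        assert set(np.unique(kept.labels)) == {0, kept.puddles[0].label}

    def test_identity_band(self):
        pset = self._pset()
        kept = area_filter(pset, max_area=10**9, min_area=1)
        assert kept.n_puddles == pset.n_puddles

    def test_matches_brute_force(self, rng):
        mask = rng.random((64, 64)) < 0.1
        pset = label_components(mask)
        kept = area_filter(pset, max_area=3, min_area=2)
        brute = [p for p in pset.puddles if 2 <= p.area <= 3]
        assert kept.n_puddles == len(brute)


class TestEndToEndCalibration:
    def test_recovered_thresholds_track_true_dark_and_gain(self):
        rng = np.random.default_rng(8)
        dark_true = rng.uniform(95, 105, size=(32, 32))
        gain_true = rng.uniform(0.9, 1.1, size=(32, 32))
        cfg = SimulationConfig(
            dose_rate=0.02, shape=(32, 32), n_frames=1000,
            shape_library=ShapeLibrary.fixed_1px(),
            amp_mean=60.0, amp_sigma=0.0,
            dark_mean=dark_true, dark_sd=3.0, gain=gain_true, seed=17,
        )
        stack, _ = simulate_frames(cfg)
        calib = calibrate_on_the_fly(stack, rng_seed=3)
        assert calib.shape == (32, 32)
        # dark map recovered tightly; threshold margins follow true gain
        # (rank correlation: a few low-hit-count pixels have noisy gains)
        assert np.median(np.abs(calib.dark_level - dark_true) / dark_true) < 0.01
        assert np.isfinite(calib.threshold).all()
        margin = calib.threshold - calib.dark_level
        rho = stats.spearmanr(margin.ravel(), gain_true.ravel()).statistic
        assert rho > 0.8
        rel_gain = np.abs(calib.gain - 60.0 * gain_true) / (60.0 * gain_true)
        assert np.median(rel_gain) < 0.05

    def test_recalibration_after_common_mode_correction_is_idempotent(self):
        # on pure dark data the corrected stack recalibrates to within 1 ADU
        rng = np.random.default_rng(4)
        frames = rng.normal(100, 4, size=(1200, 16, 16))
        a = calibrate_on_the_fly(frames, rng_seed=0)
        corrected = np.stack([
            common_mode_correct(f, a.dark_level, a.threshold, block_shape=(4, 16))
            for f in frames
        ])
        b = calibrate_on_the_fly(corrected, rng_seed=0)
        assert np.mean(np.abs(a.threshold - b.threshold)) < 1.0

    def test_fine_calibration_counts_no_more_than_fast(self):
        # stricter tail + area filter can only remove events
        cfg = SimulationConfig(
            dose_rate=0.005, shape=(128, 128), n_frames=50,
            shape_library=ShapeLibrary.fixed_2x2(),
            amp_mean=60.0, amp_sigma=0.1, dark_mean=100.0, dark_sd=4.0, seed=9,
        )
        stack, _ = simulate_frames(cfg)
        fast_thr = np.full((128, 128), 100.0 + 3 * 4.0)
        fine_thr = np.full((128, 128), 100.0 + 4 * 4.0)
        _, fast_counts = count_frames(stack, fast_thr)
        fine_total = 0
        for f in range(stack.n_frames):
            pset = label_components(stack.frames[f] > fine_thr)
            fine_total += area_filter(pset, max_area=256, min_area=2).n_puddles
        assert fine_total <= fast_counts.sum()


def test_calibration_frame_invariants():
    with pytest.raises(ValueError, match="dark"):
        CalibrationFrame(threshold=np.full((2, 2), 90.0), dark_level=np.full((2, 2), 100.0))
    with pytest.raises(ValueError, match="r must"):
        CalibrationFrame(threshold=np.full((2, 2), 120.0), r=0.7)
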