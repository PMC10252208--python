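"""Growth-cone preprocessing, center location and velocity estimation."""

import numpy as np
import pytest

from axoquant import (
    GrowthConeSceneConfig,
    axotomy_scene_check,
    generate_growth_cone_movie,
    locate_center,
    percentile_threshold,
    preprocess_roi,
    track_growth_cone,
)
from axoquant.growthcone import rolling_ball_background
from axoquant.synthetic import true_mean_step_speed


def _blob_frame(cx, cy, r=8.0, shape=(128, 128), bg=200.0, depth=120.0, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    blob = ((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2
    return bg - depth * blob + rng.normal(0, 2.0, shape)


class TestPreprocess:
    def test_single_dark_blob_recovered(self):
        frame = _blob_frame(60.0, 70.0)
        mask, _ = preprocess_roi(frame)
        from skimage.measure import label

        lab = label(mask)
        assert lab.max() == 1
        yy, xx = np.mgrid[0:128, 0:128]
        true = ((xx - 60.0) ** 2 + (yy - 70.0) ** 2) <= 8.0**2
        overlap = (mask & true).sum() / true.sum()
        assert overlap >= 0.8

    def test_blank_frame_empty_mask(self):
        mask, _ = preprocess_roi(np.full((64, 64), 200.0))
        assert not mask.any()

    def test_illumination_gradient_removed(self):
        """A slow gradient plus blob: rolling ball leaves one component."""
        yy, xx = np.mgrid[0:128, 0:128]
        frame = _blob_frame(64.0, 64.0) - 0.3 * xx  # slow shading
        mask, _ = preprocess_roi(frame)
        from skimage.measure import label

        assert label(mask).max() == 1

    def test_rolling_ball_oracle_on_known_gradient(self):
        """Fast (shrunken) ball tracks the exact ball on a smooth background."""
        from skimage import restoration

        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[0:96, 0:96]
        img = 50.0 + 0.4 * xx + 0.2 * yy + rng.normal(0, 1.0, (96, 96))
        fast = rolling_ball_background(img, radius=20, shrink=4)
        exact = restoration.rolling_ball(img, radius=20)
        assert np.abs(fast - exact).mean() < 3.5

    def test_percentile_threshold_definition(self):
        img = np.arange(100.0).reshape(10, 10)
        thr = percentile_threshold(img, 0.5)
        assert (img <= thr).mean() >= 0.5
        assert (img <= thr - 1.0).mean() < 0.5


class TestLocateCenter:
    def test_centered_disc(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = ((xx - 30) ** 2 + (yy - 40) ** 2) <= 7**2
        c = locate_center(mask)
        assert c == pytest.approx((30.0, 40.0), abs=0.5)

    def test_two_components_choose_nearest_previous(self):
        yy, xx = np.mgrid[0:64, 0:128]
        a = ((xx - 30) ** 2 + (yy - 30) ** 2) <= 6**2
        b = ((xx - 100) ** 2 + (yy - 30) ** 2) <= 6**2
        c = locate_center(a | b, previous_center=(35.0, 28.0), search_radius=20.0)
        assert c == pytest.approx((30.0, 30.0), abs=0.5)
        c2 = locate_center(a | b, previous_center=(95.0, 30.0), search_radius=20.0)
        assert c2 == pytest.approx((100.0, 30.0), abs=0.5)

    def test_crescent_matches_pixel_sum_oracle(self):
        yy, xx = np.mgrid[0:64, 0:64]
        outer = ((xx - 32) ** 2 + (yy - 32) ** 2) <= 15**2
        inner = ((xx - 38) ** 2 + (yy - 32) ** 2) <= 10**2
        crescent = outer & ~inner
        intensity = (xx + yy).astype(float)
        c = locate_center(crescent, intensity)
        w = intensity[crescent]
        expected = ((xx[crescent] * w).sum() / w.sum(), (yy[crescent] * w).sum() / w.sum())
        assert c == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_no_detection(self):
        assert locate_center(np.zeros((32, 32), dtype=bool)) is None


class TestTracking:
    def test_rigid_translation_exact_speed(self, cone_calib):
        """A rigid blob moving 2 px/frame: speed = 2 * pixel_size / interval."""
        frames = np.stack([_blob_frame(30.0 + 2 * t, 64.0, seed=0) for t in range(25)])
        traj = track_growth_cone(frames, calib=cone_calib)
        expected = cone_calib.speed_um_per_s(2.0)
        assert traj.mean_speed_um_s == pytest.approx(expected, rel=0.03)

    def test_stationary_deformable_blob_near_zero(self, cone_calib):
        cfg = GrowthConeSceneConfig(
            drift_speed_mean_um_s=0.0, shape_fluctuation_amplitude=1.0, n_frames=40, seed=6
        )
        stack, _ = generate_growth_cone_movie(cfg, cone_calib)
        traj = track_growth_cone(stack.data, calib=cone_calib)
        bound = 2.0 * cfg.shape_fluctuation_amplitude * cone_calib.pixel_size_um / cone_calib.frame_interval_s
        assert traj.mean_speed_um_s < bound

    def test_synthetic_cone_recovery_within_10pct(self, cone_calib):
        cfg = GrowthConeSceneConfig(
            drift_speed_mean_um_s=0.0666, drift_speed_sd_um_s=0.0, n_frames=120, seed=17
        )
        stack, gt = generate_growth_cone_movie(cfg, cone_calib)
        traj = track_growth_cone(stack.data, calib=cone_calib)
        true = true_mean_step_speed(gt, cone_calib)
        assert traj.mean_speed_um_s == pytest.approx(true, rel=0.10)

    def test_translation_equivariance(self, cone_calib):
        """Translating the movie translates the trajectory, speed unchanged."""
        frames = np.stack([_blob_frame(30.0 + 1.5 * t, 40.0, shape=(96, 160), seed=0) for t in range(15)])
        shifted = np.stack(
            [_blob_frame(30.0 + 10 + 1.5 * t, 40.0 + 20, shape=(96, 160), seed=0) for t in range(15)]
        )
        t1 = track_growth_cone(frames, calib=cone_calib)
        t2 = track_growth_cone(shifted, calib=cone_calib)
        assert t2.mean_speed_um_s == pytest.approx(t1.mean_speed_um_s, rel=0.05)
        dx = (t2.positions.x - t1.positions.x).to_numpy()
        dy = (t2.positions.y - t1.positions.y).to_numpy()
        assert np.allclose(dx, 10.0, atol=1.0) and np.allclose(dy, 20.0, atol=1.0)

    def test_intensity_scaling_invariance(self, cone_calib):
        frames = np.stack([_blob_frame(30.0 + 2 * t, 50.0, seed=0) for t in range(12)])
        t1 = track_growth_cone(frames, calib=cone_calib)
        t2 = track_growth_cone(frames * 3.7, calib=cone_calib)
        assert t2.mean_speed_um_s == pytest.approx(t1.mean_speed_um_s, rel=1e-6)

    def test_speed_regression_slope_near_unity(self, cone_calib):
        """Across the physiological speed range, recovered ~ true with slope in [0.9, 1.1]."""
        true_v, rec_v = [], []
        for i, v in enumerate((0.02, 0.05, 0.08, 0.1)):
            cfg = GrowthConeSceneConfig(
                drift_speed_mean_um_s=v, drift_speed_sd_um_s=0.0, n_frames=90, seed=40 + i
            )
            stack, gt = generate_growth_cone_movie(cfg, cone_calib)
            traj = track_growth_cone(stack.data, calib=cone_calib)
            true_v.append(true_mean_step_speed(gt, cone_calib))
            rec_v.append(traj.mean_speed_um_s)
        slope = np.polyfit(true_v, rec_v, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_untrackable_rejected(self, cone_calib):
        with pytest.raises(ValueError, match="untrackable"):
            track_growth_cone(np.full((5, 64, 64), 200.0), calib=cone_calib)


class TestAxotomyCheck:
    def test_blank_post_passes(self):
        pre = _blob_frame(40.0, 40.0, r=12)
        post = np.full((128, 128), 200.0)
        report = axotomy_scene_check(pre, post)
        assert report["post_foreground_fraction"] == pytest.approx(0.0, abs=1e-3)
        assert report["passed"]

    def test_unchanged_post_fails(self):
        pre = _blob_frame(40.0, 40.0, r=20)
        report = axotomy_scene_check(pre, pre)
        assert report["post_foreground_fraction"] == pytest.approx(report["pre_foreground_fraction"])
        assert not report["passed"]

    def test_partial_clearance_fraction(self):
        """30% of the pre foreground remaining: residual fraction ~ 0.3 x pre."""
        yy, xx = np.mgrid[0:128, 0:128]
        full = ((xx - 64) ** 2 + (yy - 64) ** 2) <= 30**2
        kept = full & (xx < 64 - 12)  # keep ~30% of the disc
        pre = 200.0 - 120.0 * full
        post = 200.0 - 120.0 * kept
        report = axotomy_scene_check(pre, post)
        ratio = report["post_foreground_fraction"] / report["pre_foreground_fraction"]
        assert ratio == pytest.approx(kept.sum() / full.sum(), abs=0.05)
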