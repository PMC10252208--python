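"""Spot detection, linking, track parameters and shape analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from axoquant import (
    Calibration,
    OrganelleSceneConfig,
    classify_moving,
    compute_track_parameters,
    detect_spots,
    generate_organelle_movie,
    link_tracks,
    max_intensity_projection,
    shape_analysis,
    track_movie,
)
from conftest import gaussian_frame


class TestDetection:
    def test_recovers_well_separated_spots(self, organelle_calib):
        centers = [(30.0, 30.0), (80.0, 40.0), (130.0, 90.0), (200.0, 20.0), (220.0, 100.0)]
        frame = gaussian_frame(centers)
        spots = detect_spots(frame, organelle_calib)
        assert len(spots) == 5
        for cx, cy in centers:
            d = np.hypot(spots.x - cx, spots.y - cy)
            assert d.min() < 1.0

    def test_blank_and_noise_frames(self, organelle_calib):
        assert len(detect_spots(np.zeros((64, 64)), organelle_calib)) == 0
        rng = np.random.default_rng(0)
        noise = rng.normal(100, 10, (128, 128))
        assert len(detect_spots(noise, organelle_calib, quality_threshold_sd=8.0)) == 0

    def test_close_spots_suppressed(self, organelle_calib):
        """Two spots inside one blob radius: non-maximum rule leaves <= 2."""
        r_px = 0.4 * 1000 / organelle_calib.pixel_size_nm
        frame = gaussian_frame([(64.0, 64.0), (64.0 + 0.8 * r_px, 64.0)])
        spots = detect_spots(frame, organelle_calib)
        assert 1 <= len(spots) <= 2


class TestLinking:
    @staticmethod
    def _det(rows):
        return pd.DataFrame(rows, columns=["frame", "x", "y"]).assign(quality=10.0)

    def test_single_slow_spot_single_track(self, organelle_calib):
        rows = [(t, 10.0 + 0.5 * t, 20.0) for t in range(10)]
        linked = link_tracks(self._det(rows), organelle_calib)
        assert linked.track_id.nunique() == 1

    def test_distant_parallel_spots_never_swap(self, organelle_calib):
        rows = []
        for t in range(10):
            rows += [(t, 10.0 + t, 10.0), (t, 10.0 + t, 100.0)]
        linked = link_tracks(self._det(rows), organelle_calib)
        assert linked.track_id.nunique() == 2
        for _, tr in linked.groupby("track_id"):
            assert tr.y.nunique() == 1  # no swaps across corridors

    def test_jump_splits_track(self, organelle_calib):
        max_px = 1.0 * 1000 / organelle_calib.pixel_size_nm
        rows = [(0, 10.0, 10.0), (1, 10.0 + 3 * max_px, 10.0)]
        linked = link_tracks(self._det(rows), organelle_calib)
        assert linked.track_id.nunique() == 2

    def test_greedy_matches_optimal_assignment(self, organelle_calib):
        """For <=4 spots/frame with separations >> step, greedy equals the
        exhaustive minimal-total-distance assignment."""
        rng = np.random.default_rng(7)
        max_px = 1.0 * 1000 / organelle_calib.pixel_size_nm
        base = np.array([[20.0, 20.0], [150.0, 30.0], [60.0, 180.0], [200.0, 200.0]])
        steps = rng.uniform(-0.3 * max_px, 0.3 * max_px, size=(6, 4, 2))
        pos = np.cumsum(np.concatenate([base[None], steps]), axis=0)
        rows = [(t, *pos[t, i]) for t in range(7) for i in range(4)]
        linked = link_tracks(self._det(rows), organelle_calib)
        assert linked.track_id.nunique() == 4
        # oracle: per consecutive frame pair, exhaustively minimal assignment
        for t in range(6):
            prev, cur = pos[t], pos[t + 1]
            best = min(
                itertools.permutations(range(4)),
                key=lambda p: sum(np.hypot(*(cur[p[i]] - prev[i])) for i in range(4)),
            )
            assert best == (0, 1, 2, 3)  # well-separated: identity is optimal
            got = linked[linked.frame == t + 1].sort_values("track_id")[["x", "y"]].to_numpy()
            np.testing.assert_allclose(got, cur)


class TestTrackParameters:
    @staticmethod
    def _track(xy, calib, frames=None):
        frames = frames if frames is not None else range(len(xy))
        return pd.DataFrame(
            {"frame": list(frames), "x": [p[0] for p in xy], "y": [p[1] for p in xy], "track_id": 0}
        )

    def test_constant_speed_closed_form(self):
        calib = Calibration(pixel_size_nm=1000.0, frame_interval_s=0.3)
        xy = [(float(i), 0.0) for i in range(5)]  # 1 µm per frame
        p = compute_track_parameters(self._track(xy, calib), calib)
        v = 1.0 / 0.3
        assert p.mean_speed == pytest.approx(v) == p.max_speed == p.min_speed == p.median_speed
        assert p.speed_sd == 0.0
        assert p.track_length == pytest.approx(p.track_displacement) == pytest.approx(4.0)
        assert p.track_duration == pytest.approx(4 * 0.3)
        assert p.direction == "anterograde"

    def test_back_and_forth_zero_displacement(self):
        calib = Calibration(pixel_size_nm=1000.0, frame_interval_s=1.0)
        xy = [(0.0, 0.0), (1.0, 0.0), (0.0, 0.0), (1.0, 0.0), (0.0, 0.0)]
        p = compute_track_parameters(self._track(xy, calib), calib)
        assert p.track_displacement == 0.0
        assert p.track_length == pytest.approx(4.0)
        assert p.direction == "none"
        assert not p.moving

    def test_random_walk_matches_spreadsheet_oracle(self, organelle_calib):
        """All 8 motility parameters equal an independent per-step recomputation."""
        rng = np.random.default_rng(21)
        xy = np.cumsum(rng.normal(0, 2.0, size=(15, 2)), axis=0) + 50
        track = self._track([tuple(p) for p in xy], organelle_calib)
        p = compute_track_parameters(track, organelle_calib)
        # oracle: plain per-step arithmetic on the spot table
        um = organelle_calib.pixel_size_um
        dt = organelle_calib.frame_interval_s
        d = [np.hypot(*(xy[i + 1] - xy[i])) * um for i in range(14)]
        v = [di / dt for di in d]
        assert p.track_duration == pytest.approx(14 * dt)
        assert p.track_displacement == pytest.approx(np.hypot(*(xy[-1] - xy[0])) * um)
        assert p.track_length == pytest.approx(sum(d))
        assert p.mean_speed == pytest.approx(np.mean(v))
        assert p.max_speed == pytest.approx(max(v))
        assert p.min_speed == pytest.approx(min(v))
        assert p.median_speed == pytest.approx(np.median(v))
        assert p.speed_sd == pytest.approx(np.std(v, ddof=1))

    def test_speed_order_invariant(self, organelle_calib):
        rng = np.random.default_rng(3)
        for _ in range(20):
            xy = np.cumsum(rng.normal(0, 1.5, size=(8, 2)), axis=0) + 30
            p = compute_track_parameters(self._track([tuple(q) for q in xy], organelle_calib), organelle_calib)
            assert p.min_speed <= p.median_speed <= p.max_speed
            assert p.track_length >= p.track_displacement - 1e-12

    def test_moving_threshold_inclusive(self):
        assert not classify_moving(0.0)
        assert classify_moving(1.0)  # boundary included
        assert classify_moving(2.5, moving_threshold_um=2.5)

    def test_gap_steps_use_elapsed_time(self, organelle_calib):
        track = self._track([(0.0, 0.0), (4.0, 0.0)], organelle_calib, frames=[0, 2])
        p = compute_track_parameters(track, organelle_calib)
        expected = 4.0 * organelle_calib.pixel_size_um / (2 * organelle_calib.frame_interval_s)
        assert p.mean_speed == pytest.approx(expected)


class TestShapes:
    def test_disc_feret_diameter(self, organelle_calib):
        """A rendered 1.0 µm disc: Feret diameter within one pixel-equivalent."""
        r_px = 0.5 / organelle_calib.pixel_size_um
        yy, xx = np.mgrid[0:64, 0:64]
        img = 10.0 + 100.0 * (((xx - 32) ** 2 + (yy - 32) ** 2) <= r_px**2)
        out = shape_analysis(img, organelle_calib, "lyso", threshold=50.0)
        assert len(out) == 1
        assert out.feret_diameter_um.iloc[0] == pytest.approx(1.0, abs=organelle_calib.pixel_size_um)

    def test_ellipse_aspect_ratio(self, organelle_calib):
        """A rendered 4:1 ellipse recovers its axis ratio within 5%."""
        yy, xx = np.mgrid[0:128, 0:256]
        a, b = 40.0, 10.0
        img = 10.0 + 100.0 * ((((xx - 128) / a) ** 2 + ((yy - 64) / b) ** 2) <= 1.0)
        out = shape_analysis(img, organelle_calib, "mito", threshold=50.0)
        assert out.aspect_ratio.iloc[0] == pytest.approx(4.0, rel=0.05)

    def test_circle_aspect_is_one(self, organelle_calib):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 10.0 + 100.0 * (((xx - 32) ** 2 + (yy - 32) ** 2) <= 12**2)
        out = shape_analysis(img, organelle_calib, "mito", threshold=50.0)
        assert out.aspect_ratio.iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_empty_frame(self, organelle_calib):
        assert len(shape_analysis(np.zeros((32, 32)), organelle_calib, "lyso")) == 0


class TestProjection:
    def test_single_frame_identity(self):
        frame = np.arange(12.0).reshape(1, 3, 4)
        np.testing.assert_array_equal(max_intensity_projection(frame), frame[0])

    def test_all_zero(self):
        assert max_intensity_projection(np.zeros((5, 8, 8))).sum() == 0

    def test_moving_spot_leaves_streak(self, organelle_calib):
        cfg = OrganelleSceneConfig(
            n_processive=1, speed_mean_um_s=1.0, speed_sd_um_s=0.0,
            anterograde_fraction=1.0, n_frames=20, width=256, height=64, seed=2, snr=20,
        )
        stack, gt = generate_organelle_movie(cfg, organelle_calib)
        mip = max_intensity_projection(stack.data)
        bright = mip > cfg.background_level + 5 * np.sqrt(cfg.background_level)
        xs = np.nonzero(bright.any(axis=0))[0]
        x0, x1 = gt.positions.x_px.min(), gt.positions.x_px.max()
        assert xs.min() == pytest.approx(x0, abs=4)
        assert xs.max() == pytest.approx(x1, abs=4)


class TestRecovery:
    def test_percent_moving_matches_ground_truth_fraction(self, organelle_calib):
        """40% configured processive fraction recovered within sampling error."""
        cfg = OrganelleSceneConfig(
            n_organelles=80, moving_fraction=0.4, n_frames=40,
            width=512, height=256, seed=31,
        )
        stack, gt = generate_organelle_movie(cfg, organelle_calib)
        _, params, summary = track_movie(stack.data, organelle_calib, "lyso")
        true_frac = (gt.objects["class"] == "processive").mean()
        # binomial-scale tolerance on the recovered percentage
        assert summary["percent_moving"] == pytest.approx(100 * true_frac, abs=15.0)

    def test_mean_speed_recovery_within_5pct(self, organelle_calib):
        """Parameter recovery: speed_sd=0 movies recover the configured speed
        within 5% at SNR >= 5."""
        for snr in (5, 10):
            rec = []
            for seed in (0, 1):
                cfg = OrganelleSceneConfig(
                    n_processive=8, n_frames=50, width=512, height=256,
                    speed_mean_um_s=0.8, speed_sd_um_s=0.0, snr=snr, seed=seed,
                )
                stack, _ = generate_organelle_movie(cfg, organelle_calib)
                _, params, _ = track_movie(stack.data, organelle_calib, "lyso")
                rec += [p.mean_speed for p in params if p.moving]
            assert np.mean(rec) == pytest.approx(0.8, rel=0.05)
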