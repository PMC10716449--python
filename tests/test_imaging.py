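"""Imaging pipeline: background, detection, fitting, registration, filtering."""

import numpy as np
import pytest

from smtrace import imaging, simkit
from smtrace.simkit import gaussian_spot_image

from conftest import grid_positions


class TestSubtractBackground:
    def test_constant_offset_removed(self):
        frame = np.full((32, 32), 150.0)
        out = imaging.subtract_background(frame, radius_px=5)
        assert abs(out.mean()) < 1.0

    def test_all_zero_frame_unchanged(self):
        frame = np.zeros((16, 16))
        assert np.array_equal(imaging.subtract_background(frame, 5), frame)

    def test_spot_amplitude_preserved_on_tilted_plane(self):
        yy, xx = np.mgrid[0:48, 0:48]
        plane = 50.0 + 0.8 * xx + 0.5 * yy
        spot = gaussian_spot_image((48, 48), 24.0, 24.0, 1.0, 3000.0)
        out = imaging.subtract_background(plane + spot, radius_px=5)
        fit = imaging.fit_spot_gaussian(out, (24.0, 24.0))
        true_peak = spot.max()
        assert fit.fit_ok
        assert fit.amplitude == pytest.approx(true_peak, rel=0.05)

    def test_small_radius_warns(self):
        with pytest.warns(UserWarning):
            imaging.subtract_background(np.zeros((16, 16)), radius_px=1,
                                        psf_sigma_px=1.5)


class TestDetectSpots:
    def test_all_separated_spots_found_no_false_positives(self):
        hits, extra = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pos = grid_positions(20, seed=seed)
            frame = np.zeros((72, 72))
            for x, y in pos:
                frame += gaussian_spot_image((72, 72), x, y, 1.0, 2000.0)
            frame = rng.poisson(frame + 100).astype(float)
            frame = imaging.subtract_background(frame, 5)
            spots = imaging.detect_spots(frame, threshold_sd=5)
            found = np.array([[s.x, s.y] for s in spots]) if spots else np.empty((0, 2))
            for x, y in pos:
                if found.size and np.min(np.hypot(found[:, 0] - x,
                                                  found[:, 1] - y)) < 1.0:
                    hits += 1
            extra += max(len(spots) - 20, 0)
        assert hits >= 0.95 * 20 * 20
        assert extra == 0

    def test_blank_noise_frame_rare_false_positives(self):
        n_fp = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            frame = rng.normal(0, 10, (64, 64))
            n_fp += len(imaging.detect_spots(frame, threshold_sd=5))
        assert n_fp <= 2  # <= 1 per 10 frames

    def test_two_spots_eight_sigma_apart_both_recovered(self):
        frame = (gaussian_spot_image((48, 48), 16.0, 24.0, 1.0, 3000.0)
                 + gaussian_spot_image((48, 48), 24.0, 24.0, 1.0, 3000.0))
        rng = np.random.default_rng(0)
        frame = rng.poisson(frame + 50).astype(float) - 50
        spots = imaging.detect_spots(frame, min_separation_px=4, threshold_sd=5)
        assert len(spots) == 2
        xs = sorted(s.x for s in spots)
        assert xs[0] == pytest.approx(16.0, abs=0.2)
        assert xs[1] == pytest.approx(24.0, abs=0.2)

    def test_wide_cluster_rejected_by_psf_width(self):
        frame = gaussian_spot_image((48, 48), 24.0, 24.0, 4.0, 20000.0)
        spots = imaging.detect_spots(frame, threshold_sd=5, psf_max_px=2.5,
                                     window_px=6)
        assert spots == []


class TestFitSpotGaussian:
    def test_noiseless_center_recovery(self):
        frame = gaussian_spot_image((32, 32), 15.3, 16.7, 1.2, 5000.0)
        spot = imaging.fit_spot_gaussian(frame, (15.0, 17.0))
        assert spot.fit_ok
        assert spot.x == pytest.approx(15.3, abs=1e-3)
        assert spot.y == pytest.approx(16.7, abs=1e-3)

    def test_flat_window_not_ok(self):
        spot = imaging.fit_spot_gaussian(np.full((32, 32), 7.0), (16.0, 16.0))
        assert not spot.fit_ok

    def test_localization_precision_at_snr10(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = gaussian_spot_image((32, 32), 16.0, 16.0, 1.0, 2000.0)
            frame = frame + rng.normal(0, frame.max() / 10, frame.shape)
            spot = imaging.fit_spot_gaussian(frame, (16.0, 16.0))
            errs.append([spot.x - 16.0, spot.y - 16.0])
        per_axis_rms = np.sqrt(np.mean(np.square(errs), axis=0))
        assert np.all(per_axis_rms < 0.1)

    def test_window_off_frame_rejected(self):
        spot = imaging.fit_spot_gaussian(np.zeros((16, 16)), (1.0, 1.0))
        assert not spot.fit_ok


class TestEstimateTransform:
    def test_identity_on_identical_points(self):
        pts = np.array([[1.0, 2.0], [5.0, 7.0], [9.0, 3.0], [4.0, 8.0]])
        t = imaging.estimate_transform(pts, pts)
        assert np.allclose(t.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)
        assert t.residual_rms < 1e-12

    def test_exact_recovery_of_known_affine(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 60, (6, 2))
        theta = np.deg2rad(1.0)
        mat = np.array([[np.cos(theta), -np.sin(theta), 3.2],
                        [np.sin(theta), np.cos(theta), -1.7]])
        dst = src @ mat[:, :2].T + mat[:, 2]
        t = imaging.estimate_transform(src, dst)
        assert np.allclose(t.matrix, mat, atol=1e-9)
        # apply o estimate is the identity on training points
        assert np.allclose(t.apply(src), dst, atol=1e-9)

    def test_jitter_reflected_in_residual(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 60, (6, 2))
        dst = src + rng.normal(0, 0.1, src.shape)
        t = imaging.estimate_transform(src, dst)
        assert 0.02 < t.residual_rms < 0.25

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            imaging.estimate_transform(src, src)

    def test_inverse_roundtrip(self):
        t = imaging.AffineTransform(np.array([[1.1, 0.1, 3.0], [-0.05, 0.9, -2.0]]))
        pts = np.array([[3.0, 4.0], [10.0, 20.0]])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)


def _reference_movie(drift_per_frame=(0.0, 0.0), n_ref=10, seed=0):
    """Two-channel movie: bright immobilized far-red spots + orange traces."""
    pos = grid_positions(16, lo=10, hi=60, spacing=12, seed=seed)
    drift = np.outer(np.arange(n_ref * 10), np.asarray(drift_per_frame))
    sched = simkit.IlluminationSchedule(t_on=0.1, t_off=0.0,
                                        cycle=("farred",) + ("orange",) * 9,
                                        n_repeats=n_ref)
    spots = [(x, y, np.full(n_ref * 9, 1500.0)) for x, y in pos]
    photo = simkit.PhotophysicsParams(total_intensity=6000.0, background_mean=100.0,
                                      background_sd=10.0)
    stack, reg = simkit.render_movie(spots, (72, 72), 1.0, sched=sched,
                                     drift_path=drift, photo=photo, seed=seed)
    return stack, reg, drift


class TestCorrectDrift:
    def test_zero_drift(self):
        stack, _, _ = _reference_movie()
        ref = stack.channel_frames("farred")
        off = imaging.correct_drift(ref, stack.channel_indices("farred"),
                                    stack.n_frames)
        assert np.all(np.abs(off) < 0.05)

    def test_linear_drift_slope_recovered(self):
        stack, _, drift = _reference_movie(drift_per_frame=(0.05, 0.0))
        ref = stack.channel_frames("farred")
        off = imaging.correct_drift(ref, stack.channel_indices("farred"),
                                    stack.n_frames)
        slope = np.polyfit(np.arange(stack.n_frames), off[:, 0], 1)[0]
        assert slope == pytest.approx(0.05, rel=0.1)

    def test_step_drift_localized_to_cycle(self):
        stack, _, _ = _reference_movie()
        ref = stack.channel_frames("farred").copy()
        # shift reference frames 5.. by 2 px in x
        ref[5:] = np.roll(ref[5:], 2, axis=2)
        idx = stack.channel_indices("farred")
        off = imaging.correct_drift(ref, idx, stack.n_frames)
        assert np.all(np.abs(off[:idx[4] + 1, 0]) < 0.3)
        assert np.all(np.abs(off[idx[5]:, 0] - 2.0) < 0.3)


class TestExtractTraces:
    def test_background_only_field_sums_area_times_mean(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(100.0, 1.0, (20, 32, 32))
        traces, edge = imaging.extract_traces(frames, [[16.0, 16.0]], radius_px=2.0)
        n_px = 13  # pixels with centers within 2 px of a pixel center
        assert traces.shape == (1, 20)
        assert traces.mean() == pytest.approx(n_px * 100.0, rel=0.01)
        assert not edge[0]

    def test_noiseless_spot_mass_within_radius(self):
        frame = gaussian_spot_image((32, 32), 16.0, 16.0, 1.0, 2000.0)
        traces, _ = imaging.extract_traces(frame, [[16.0, 16.0]], radius_px=2.0)
        in_disk = 2000.0 * (1 - np.exp(-(2.0**2) / (2 * 1.0**2)))
        assert traces[0, 0] == pytest.approx(in_disk, rel=0.04)

    def test_radius_zero_is_single_pixel(self):
        frame = np.arange(64.0).reshape(8, 8)
        traces, _ = imaging.extract_traces(frame, [[3.0, 2.0]], radius_px=0.0)
        assert traces[0, 0] == frame[2, 3]

    def test_edge_position_flagged(self):
        frames = np.zeros((2, 16, 16))
        _, edge = imaging.extract_traces(frames, [[1.0, 8.0]], radius_px=2.0)
        assert edge[0]


class TestCkFilter:
    def test_constant_trace_unchanged(self):
        x = np.full(100, 42.0)
        assert np.array_equal(imaging.ck_filter(x, window=8), x)

    def test_clean_step_preserved_with_smooth_plateaus(self):
        x = np.concatenate([np.zeros(100), np.full(100, 1000.0)])
        y = imaging.ck_filter(x, window=8, p_exponent=2.0)
        # transition spread <= 2 frames
        crossing = np.flatnonzero((y > 50) & (y < 950))
        assert crossing.size <= 2
        assert np.all(np.abs(y[:95]) < 10.0)
        assert np.all(np.abs(y[105:] - 1000.0) < 10.0)
        # no overshoot beyond 5% of the step height
        assert y.max() < 1050.0 and y.min() > -50.0

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 5000)
        y = imaging.ck_filter(x, window=8, p_exponent=2.0)
        assert np.var(y) < 0.25 * np.var(x)

    def test_idempotent_on_noiseless_piecewise_constant(self):
        x = np.concatenate([np.zeros(50), np.full(70, 500.0), np.full(40, 100.0)])
        y1 = imaging.ck_filter(x, window=8)
        y2 = imaging.ck_filter(y1, window=8)
        assert np.allclose(y1, y2, atol=1e-9)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            imaging.ck_filter(np.zeros(10), window=8)


class TestEndToEnd:
    def test_render_detect_extract_recovers_molecules(self):
        stack, reg, _ = _reference_movie(seed=1)
        sub = imaging.subtract_background(stack, 5)
        ref0 = sub.channel_frames("farred")[0]
        spots = imaging.detect_spots(ref0, threshold_sd=5)
        truth = np.array([[r["x_ref"], r["y_ref"]] for r in reg])
        found = np.array([[s.x, s.y] for s in spots])
        matched = 0
        for x, y in truth:
            if np.min(np.hypot(found[:, 0] - x, found[:, 1] - y)) < 1.0:
                matched += 1
        assert matched >= 0.95 * len(truth)

        orange = sub.channel_frames("orange")
        traces, _ = imaging.extract_traces(orange, truth, radius_px=2.0)
        # oracle: the same movie rendered without noise, extracted identically
        spots = [(r["x_ref"], r["y_ref"], r["trace"]) for r in reg]
        sched = simkit.IlluminationSchedule(t_on=0.1, t_off=0.0,
                                            cycle=("farred",) + ("orange",) * 9,
                                            n_repeats=10)
        clean, _ = simkit.render_movie(
            spots, (72, 72), 1.0, sched=sched,
            photo=simkit.PhotophysicsParams.noiseless(6000.0), noise=False, seed=0)
        clean_traces, _ = imaging.extract_traces(clean.channel_frames("orange"),
                                                 truth, radius_px=2.0)
        rel = traces.mean(axis=1) / clean_traces.mean(axis=1) - 1
        assert np.all(np.abs(rel) < 0.1)
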