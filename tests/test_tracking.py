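"""Template extraction, the Gauss-Newton solver, sequence tracking and
camera calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scgvision.errors import (
    DegenerateTextureError,
    DomainError,
    OutOfViewError,
    RoiBoundsError,
    UnitsError,
    UntrackableTemplateError,
)
from scgvision.synthetic import make_texture
from scgvision.tracking import (
    FrameSequence,
    TrackerConfig,
    apply_calibration,
    extract_template,
    scaling_factor_from_intrinsics,
    scaling_factor_from_target,
    solve_warp_increment,
    track_sequence,
    warp_sample,
)


def _noise_frames(n=2, size=128, seed=0, fps=60.0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 1, (size, size))
    return FrameSequence(frames=np.repeat(base[None], n, axis=0), frame_rate=fps)


class TestExtractTemplate:
    def test_identity_crop(self):
        frames = _noise_frames()
        roi = (10, 20, 64, 64)
        tmpl = extract_template(frames, roi)
        assert np.array_equal(tmpl.patch, frames.frames[0, 20:84, 10:74])
        assert tmpl.origin == (10, 20)
        assert tmpl.xs[0, 0] == 10 and tmpl.ys[0, 0] == 20

    def test_roi_past_edge_rejected(self):
        with pytest.raises(RoiBoundsError):
            extract_template(_noise_frames(), (100, 0, 64, 64))

    def test_uniform_region_untrackable(self):
        frames = FrameSequence(frames=np.full((2, 64, 64), 0.5), frame_rate=60.0)
        with pytest.raises(UntrackableTemplateError):
            extract_template(frames, (8, 8, 32, 32))


class TestWarpSample:
    def test_identity_warp(self):
        frames = _noise_frames()
        tmpl = extract_template(frames, (10, 20, 64, 64))
        sampled = warp_sample(frames.frames[0], (0.0, 0.0), tmpl)
        assert np.array_equal(sampled, tmpl.patch)

    def test_integer_shift_needs_no_interpolation(self):
        frames = _noise_frames()
        tmpl = extract_template(frames, (10, 20, 32, 32))
        sampled = warp_sample(frames.frames[0], (3.0, -2.0), tmpl)
        assert np.allclose(sampled, frames.frames[0, 18:50, 13:45])

    def test_half_pixel_on_ramp_is_neighbor_mean(self):
        # bilinear interpolation is exact on a linear ramp
        size = 32
        ramp = np.tile(np.linspace(0, 1, size), (size, 1))
        frames = FrameSequence(frames=np.repeat(ramp[None], 2, axis=0),
                               frame_rate=60.0)
        tmpl = extract_template(frames, (4, 4, 16, 16))
        sampled = warp_sample(frames.frames[0], (0.5, 0.0), tmpl)
        expected = 0.5 * (ramp[4:20, 4:20] + ramp[4:20, 5:21])
        assert np.allclose(sampled, expected)

    def test_out_of_view_raises(self):
        frames = _noise_frames()
        tmpl = extract_template(frames, (10, 20, 64, 64))
        with pytest.raises(OutOfViewError):
            warp_sample(frames.frames[0], (60.0, 0.0), tmpl)


class TestSolveWarpIncrement:
    def test_zero_residual_gives_zero_increment(self):
        frames = _noise_frames()
        tmpl = extract_template(frames, (10, 20, 64, 64))
        du, state = solve_warp_increment(frames.frames[0], tmpl, (0.0, 0.0))
        assert np.allclose(du, 0.0)
        assert state.error == 0.0

    def test_one_step_recovers_subpixel_shift(self):
        # smooth texture shifted 0.3 px by closed-form bilinear resampling;
        # one Gauss-Newton step from the unshifted estimate must land
        # within 0.05 px of the true shift
        from scipy import ndimage
        tex = make_texture(128, seed=5, smooth_px=3.0)
        rows, cols = np.mgrid[0:128, 0:128].astype(float)
        shifted = ndimage.map_coordinates(tex, [rows, cols - 0.3], order=1,
                                          mode="nearest")
        frames = FrameSequence(frames=np.stack([tex, shifted]), frame_rate=60.0)
        tmpl = extract_template(frames, (24, 24, 64, 64))
        du, _ = solve_warp_increment(frames.frames[1], tmpl, (0.0, 0.0))
        assert abs(du[0] - 0.3) < 0.05
        assert abs(du[1]) < 0.05

    def test_uniform_frame_degenerate(self):
        frames = _noise_frames()
        tmpl = extract_template(frames, (10, 20, 32, 32))
        with pytest.raises(DegenerateTextureError):
            solve_warp_increment(np.full((128, 128), 0.5), tmpl, (0.0, 0.0))

    def test_hessian_equals_general_form(self):
        # with dW/du = I the Hessian must equal the structure tensor built
        # from the general [grad I * J] products
        frames = _noise_frames(seed=9)
        tmpl = extract_template(frames, (30, 40, 48, 48))
        _, state = solve_warp_increment(frames.frames[0], tmpl, (0.0, 0.0))
        from scipy import ndimage
        gy, gx = np.gradient(frames.frames[0])
        coords = [tmpl.ys, tmpl.xs]
        ix = ndimage.map_coordinates(gx, coords, order=1, mode="nearest")
        iy = ndimage.map_coordinates(gy, coords, order=1, mode="nearest")
        jac = np.eye(2)
        h_general = np.zeros((2, 2))
        grads = np.stack([ix.ravel(), iy.ravel()], axis=1)  # rows: grad I
        for g in grads:
            gj = g @ jac
            h_general += np.outer(gj, gj)
        assert np.allclose(state.hessian, h_general, rtol=1e-10)


class TestTrackSequence:
    def test_static_video_zero_trajectory(self):
        frames = _noise_frames(n=10)
        tmpl = extract_template(frames, (10, 20, 64, 64))
        traj = track_sequence(frames, tmpl)
        assert np.array_equal(traj.ux, np.zeros(10))
        assert np.array_equal(traj.uy, np.zeros(10))
        assert np.allclose(traj.per_frame_error, 0.0)

    def test_integer_shift_sequence_recovered(self):
        rng = np.random.default_rng(2)
        big = rng.uniform(0, 1, (96, 140))
        shifts = [0, 1, 2, 3, 4]
        stack = np.stack([big[:, 10 - s:10 - s + 96] for s in shifts])
        frames = FrameSequence(frames=stack, frame_rate=60.0)
        tmpl = extract_template(frames, (16, 16, 64, 64))
        cfg = TrackerConfig(epsilon=1e-8, max_iterations=100)
        traj = track_sequence(frames, tmpl, cfg)
        assert np.allclose(traj.ux, shifts, atol=1e-6)
        assert np.allclose(traj.uy, 0.0, atol=1e-6)

    def test_subpixel_sinusoid_rmse(self, sinusoid_scene):
        scene = sinusoid_scene
        tmpl = extract_template(scene.frames, (40, 40, 64, 64))
        traj = track_sequence(scene.frames, tmpl)
        truth = scene.truth_disp_px["x"].values
        rmse = np.sqrt(np.mean((traj.ux - truth) ** 2))
        assert rmse <= 0.05

    def test_error_never_increases_over_start(self, sinusoid_scene):
        # Gauss-Newton sanity: the converged SSD never exceeds the warm
        # start's SSD beyond the interpolation-noise headroom the solver
        # itself enforces
        tmpl = extract_template(sinusoid_scene.frames, (40, 40, 64, 64))
        traj = track_sequence(sinusoid_scene.frames, tmpl)
        assert np.all(traj.per_frame_error
                      <= 1.10 * traj.initial_error + 1e-12)

    def test_translation_equivariance(self, sinusoid_scene):
        # shifting every frame (and the ROI) by a constant integer offset
        # leaves the recovered trajectory bit-identical
        base = sinusoid_scene.frames.frames[:40]
        pad = np.pad(base, ((0, 0), (5, 5), (5, 5)), mode="edge")
        shifted = pad[:, 2:2 + base.shape[1], 9:9 + base.shape[2]]
        fa = FrameSequence(frames=base, frame_rate=60.0)
        fb = FrameSequence(frames=shifted, frame_rate=60.0)
        roi_a = (40, 40, 64, 64)
        # base pixel (y, x) sits at (y + 3, x - 4) in the shifted stack
        roi_b = (40 - 4, 40 + 3, 64, 64)
        ta = track_sequence(fa, extract_template(fa, roi_a))
        tb = track_sequence(fb, extract_template(fb, roi_b))
        # identical up to round-off in the integer-offset pixel coordinates
        assert np.allclose(ta.ux, tb.ux, atol=1e-12)
        assert np.allclose(ta.uy, tb.uy, atol=1e-12)

    def test_drift_corrected_template_matches_truth(self, cardiac_scene):
        scene = cardiac_scene
        tmpl = extract_template(scene.frames, (40, 40, 64, 64))
        cfg = TrackerConfig(template_update="drift_corrected",
                            update_period_frames=30)
        traj = track_sequence(scene.frames, tmpl, cfg)
        truth = scene.truth_disp_px["x"].values
        rmse = np.sqrt(np.mean((traj.ux - truth) ** 2))
        assert rmse <= 0.05

    def test_too_few_frames(self):
        frames = _noise_frames(n=1)
        tmpl = extract_template(frames, (10, 20, 64, 64))
        with pytest.raises(DomainError):
            track_sequence(frames, tmpl)


class TestCalibration:
    def test_target_dimension_formula(self):
        cal = scaling_factor_from_target(25.0, 250.0)
        assert cal.sf == pytest.approx(0.1)
        assert cal.method == "target_dimension"
        assert scaling_factor_from_target(10.0, 10.0).sf == pytest.approx(1.0)

    def test_target_dimension_guards(self):
        with pytest.raises(DomainError):
            scaling_factor_from_target(25.0, 0.0)

    def test_intrinsics_formula(self):
        cal = scaling_factor_from_intrinsics(500.0, 2.0, 5.0)
        assert cal.sf == pytest.approx(0.2)
        # d = f cancels: sf = p in mm
        assert scaling_factor_from_intrinsics(7.7, 1.0, 7.7).sf == pytest.approx(1e-3)
        with pytest.raises(DomainError):
            scaling_factor_from_intrinsics(500.0, 2.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(d_mm=st.floats(0.1, 1e3), d_px=st.floats(0.1, 1e4),
           k=st.floats(1e-3, 1e3))
    def test_scaling_factor_homogeneous(self, d_mm, d_px, k):
        sf1 = scaling_factor_from_target(d_mm, d_px).sf
        sf2 = scaling_factor_from_target(k * d_mm, k * d_px).sf
        assert sf2 == pytest.approx(sf1, rel=1e-9)

    def test_apply_calibration_scales_and_flips_units(self, sinusoid_scene):
        tmpl = extract_template(sinusoid_scene.frames, (40, 40, 64, 64))
        traj = track_sequence(sinusoid_scene.frames, tmpl)
        cal = scaling_factor_from_target(10.0, 100.0)
        mm = apply_calibration(traj, cal)
        assert mm.units == "mm"
        assert np.allclose(mm.ux, traj.ux * 0.1)
        with pytest.raises(UnitsError):
            apply_calibration(mm, cal)
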