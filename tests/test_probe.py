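"""Tracked-probe geometry: PnP marker pose, pivot calibration, tip
computation and projection, probe-tip error protocol, px-to-mm conversion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neurofuse.phantom import simulate_pivot_sequence
from neurofuse.probe import (BehindCamera, MarkerPose, PivotConditioningWarning,
                             PoseEstimationError, ProbeModel,
                             UnderdeterminedError, compute_probe_tip,
                             estimate_marker_pose, pivot_calibrate,
                             pixel_error_to_mm, probe_tip_error_protocol,
                             project_biopsy_site, square_marker_corners,
                             load_poses, save_poses, load_probe, save_probe)
from neurofuse.stereo import (CameraIntrinsics, Pixel, Point3D, StereoRig,
                              project_points, rotation_angle_between)


def _cam(fx=2500.0, cx=479.5, cy=539.5):
    return CameraIntrinsics(np.array([[fx, 0, cx], [0, fx, cy], [0, 0, 1]]))


def _identity_rig(fx=968.0, cx=144.5, cy=137.0):
    cam = CameraIntrinsics(np.array([[fx, 0, cx], [0, fx, cy], [0, 0, 1]]))
    return StereoRig(cam, cam, np.eye(3), np.zeros(3))


class TestMarkerPose:
    CORNERS = np.concatenate([square_marker_corners(20.0),
                              square_marker_corners(12.0)])

    def test_noiseless_render_and_recover(self):
        cam = _cam()
        R = Rotation.from_rotvec([0.4, -0.3, 0.2]).as_matrix()
        t = np.array([12.0, -8.0, 310.0])
        px = project_points(self.CORNERS @ R.T + t, cam)
        pose = estimate_marker_pose(px, self.CORNERS, cam)
        assert np.abs(pose.t_m - t).max() < 1e-4
        assert rotation_angle_between(pose.R_m, R) < 1e-6

    def test_centered_marker_on_axis(self):
        cam = _cam()
        depth = 300.0
        px = project_points(self.CORNERS + [0, 0, depth], cam)
        pose = estimate_marker_pose(px, self.CORNERS, cam)
        assert np.allclose(pose.t_m, [0, 0, depth], atol=1e-6)
        assert rotation_angle_between(pose.R_m, np.eye(3)) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_gross_outliers_rejected(self, seed):
        """~30% corrupted corners are excluded and the pose still recovered."""
        rng = np.random.default_rng(seed)
        cam = _cam()
        R = Rotation.from_rotvec(rng.normal(0, 0.3, 3)).as_matrix()
        t = np.array([5.0, -5.0, 320.0])
        px = project_points(self.CORNERS @ R.T + t, cam)
        bad = rng.choice(len(px), size=2, replace=False)
        px[bad] += rng.uniform(40, 80, (2, 2)) * rng.choice([-1, 1], (2, 2))
        pose = estimate_marker_pose(px, self.CORNERS, cam, seed=seed)
        assert pose.n_inliers == len(px) - 2
        assert np.abs(pose.t_m - t).max() < 1e-2

    def test_too_few_points(self):
        cam = _cam()
        with pytest.raises(PoseEstimationError):
            estimate_marker_pose(np.zeros((3, 2)), np.zeros((3, 3)), cam)

    def test_collinear_points_rejected(self):
        cam = _cam()
        pts3 = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(PoseEstimationError, match="collinear"):
            estimate_marker_pose(np.zeros((4, 2)), pts3, cam)


class TestPivotCalibration:
    def test_noiseless_recovery_of_long_offset(self, probe):
        truth = ProbeModel(T_probe=np.array([0.0, 0.0, 120.0]))
        poses = simulate_pivot_sequence(truth, 20, 0.0, seed=1)
        est, pivot = pivot_calibrate(poses)
        assert np.abs(est.T_probe - truth.T_probe).max() < 1e-9
        assert np.abs(pivot.as_array() - [0, 0, 300.0]).max() < 1e-9
        assert est.rms_residual < 1e-9

    @pytest.mark.parametrize("offset", [(1, 2, 3), (-50, 80, 250), (0, 0, 500)])
    def test_recovery_any_offset(self, offset):
        truth = ProbeModel(T_probe=np.array(offset, dtype=float))
        poses = simulate_pivot_sequence(truth, 8, 0.0, seed=3)
        est, _ = pivot_calibrate(poses)
        assert np.abs(est.T_probe - truth.T_probe).max() < 1e-8

    def test_identical_poses_underdetermined(self):
        pose = MarkerPose(np.eye(3), np.array([0, 0, 200.0]))
        with pytest.raises(UnderdeterminedError):
            pivot_calibrate([pose] * 10)

    def test_too_few_poses(self):
        pose = MarkerPose(np.eye(3), np.array([0, 0, 200.0]))
        with pytest.raises(UnderdeterminedError):
            pivot_calibrate([pose, pose])

    def test_single_axis_rotation_warns(self, probe):
        poses = simulate_pivot_sequence(probe, 15, 0.0, seed=2, single_axis=True)
        with pytest.warns(PivotConditioningWarning):
            pivot_calibrate(poses)

    def test_noisy_residual_tracks_injected_noise(self, probe):
        """Translation noise sigma = 0.1 mm leaves an RMS residual of the
        same order, across seeds."""
        resids = []
        for seed in range(10):
            poses = simulate_pivot_sequence(probe, 20, 0.1, seed=seed)
            est, _ = pivot_calibrate(poses)
            resids.append(est.rms_residual)
        assert 0.05 <= np.mean(resids) <= 0.2


class TestComputeProbeTip:
    def test_identity_probe_gives_marker_origin(self):
        pose = MarkerPose(Rotation.from_rotvec([0.1, 0.2, 0.3]).as_matrix(),
                          np.array([10.0, 20.0, 300.0]))
        tip = compute_probe_tip(pose, ProbeModel())
        assert np.allclose(tip.as_array(), pose.t_m)

    def test_pure_offset_from_aligned_marker(self):
        pose = MarkerPose(np.eye(3), np.zeros(3))
        tip = compute_probe_tip(pose, ProbeModel(T_probe=np.array([0, 0, 120.0])))
        assert np.allclose(tip.as_array(), [0, 0, 120.0])

    def test_matches_homogeneous_matrix_chain(self, rng):
        """Independent oracle: compose 4x4 homogeneous transforms."""
        for _ in range(20):
            R_m = Rotation.random(random_state=rng).as_matrix()
            t_m = rng.uniform(-100, 100, 3)
            t_tip = rng.uniform(-200, 200, 3)
            pose = MarkerPose(R_m, t_m)
            probe = ProbeModel(T_probe=t_tip)
            M = np.eye(4)
            M[:3, :3] = R_m
            M[:3, 3] = t_m
            expected = (M @ np.array([*t_tip, 1.0]))[:3]
            tip = compute_probe_tip(pose, probe)
            assert np.allclose(tip.as_array(), expected, atol=1e-12)


class TestProjectBiopsySite:
    def test_identity_rig_on_axis_hits_principal_point(self):
        rig = _identity_rig()
        pixel, in_view = project_biopsy_site(Point3D(0, 0, 300.0, "left"), rig)
        assert (pixel.u, pixel.v) == (144.5, 137.0)
        assert in_view

    def test_matches_direct_render(self, rig, rng):
        for _ in range(20):
            p_r = rng.uniform([-20, -20, 250], [20, 20, 380])
            tip = Point3D.from_array(rig.R.T @ (p_r - rig.T), "left")
            pixel, _ = project_biopsy_site(tip, rig)
            direct = project_points(p_r[None, :], rig.right)[0]
            assert abs(pixel.u - direct[0]) < 1e-6
            assert abs(pixel.v - direct[1]) < 1e-6

    def test_behind_camera_propagates(self):
        rig = _identity_rig()
        with pytest.raises(BehindCamera):
            project_biopsy_site(Point3D(0, 0, -50.0, "left"), rig)

    def test_out_of_bounds_flagged_not_clamped(self):
        rig = _identity_rig()
        pixel, in_view = project_biopsy_site(Point3D(100.0, 0, 300.0, "left"),
                                             rig, image_shape=(275, 290))
        assert not in_view
        assert pixel.u > 290          # untouched coordinates


class TestProbeTipErrorProtocol:
    def test_perfect_chain_zero_error(self, rig, probe):
        rng = np.random.default_rng(5)
        events = []
        for _ in range(8):
            R_m = Rotation.random(random_state=rng).as_matrix()
            t_m = rng.uniform([-10, -10, 280], [10, 10, 330])
            pose = MarkerPose(R_m, t_m)
            tip = compute_probe_tip(pose, probe)
            pixel, _ = project_biopsy_site(tip, rig)
            events.append((pose, pixel))
        mean, sd = probe_tip_error_protocol(events, probe, rig)
        assert mean < 1e-9
        assert sd < 1e-9

    def test_three_four_five_offset(self, rig, probe):
        pose = MarkerPose(np.eye(3), np.array([0, 0, 300.0]))
        tip = compute_probe_tip(pose, probe)
        pixel, _ = project_biopsy_site(tip, rig)
        mean, sd = probe_tip_error_protocol(
            [(pose, Pixel(pixel.u + 3, pixel.v + 4))], probe, rig)
        assert mean == pytest.approx(5.0)
        assert sd == 0.0

    def test_error_scales_linearly_with_miscalibration(self, rig, probe):
        """Injecting 2x the tip-offset error doubles the pixel error."""
        rng = np.random.default_rng(9)
        events = []
        for _ in range(10):
            R_m = Rotation.random(random_state=rng).as_matrix()
            t_m = rng.uniform([-10, -10, 280], [10, 10, 330])
            pose = MarkerPose(R_m, t_m)
            pixel, _ = project_biopsy_site(compute_probe_tip(pose, probe), rig)
            events.append((pose, pixel))
        errs = []
        for delta in (1.0, 2.0):
            bad = ProbeModel(T_probe=probe.T_probe + np.array([delta, 0, 0]))
            mean, _ = probe_tip_error_protocol(events, bad, rig)
            errs.append(mean)
        assert errs[1] / errs[0] == pytest.approx(2.0, rel=1e-3)

    def test_invariant_to_rigid_motion_of_scene(self, rig, probe):
        """Moving the whole scene (poses and geometry) rigidly in the left
        frame leaves the probe-tip error unchanged."""
        rng = np.random.default_rng(3)
        pose = MarkerPose(Rotation.random(random_state=rng).as_matrix(),
                          np.array([5.0, -5.0, 300.0]))
        pixel, _ = project_biopsy_site(compute_probe_tip(pose, probe), rig)
        bad = ProbeModel(T_probe=probe.T_probe + np.array([0.5, 0, 0]))
        base, _ = probe_tip_error_protocol([(pose, pixel)], bad, rig)

        G = Rotation.from_rotvec([0.05, -0.02, 0.1]).as_matrix()
        g = np.array([3.0, -7.0, 12.0])
        moved_pose = MarkerPose(G @ pose.R_m, G @ pose.t_m + g)
        moved_rig = StereoRig(rig.left, rig.right, rig.R @ G.T,
                              rig.T - rig.R @ G.T @ g)
        moved_pixel, _ = project_biopsy_site(
            compute_probe_tip(moved_pose, probe), moved_rig)
        assert np.allclose([moved_pixel.u, moved_pixel.v], [pixel.u, pixel.v],
                           atol=1e-8)
        moved, _ = probe_tip_error_protocol([(moved_pose, moved_pixel)], bad,
                                            moved_rig)
        assert moved == pytest.approx(base, abs=1e-6)

    def test_empty_events_rejected(self, rig, probe):
        with pytest.raises(ValueError):
            probe_tip_error_protocol([], probe, rig)


class TestPixelErrorToMM:
    def test_rgb_camera_conversion(self):
        full = pixel_error_to_mm(1.2, 0.12)
        assert full == pytest.approx(0.144)
        assert round(full, 2) == 0.14

    def test_zero_error(self):
        assert pixel_error_to_mm(0.0, 0.12) == 0.0

    def test_hsi_camera_conversion(self):
        assert pixel_error_to_mm(10.0, 0.31) == pytest.approx(3.1)

    def test_linearity(self, rng):
        for _ in range(20):
            e, s, k = rng.uniform(0.1, 10, 3)
            assert pixel_error_to_mm(k * e, s) == pytest.approx(
                k * pixel_error_to_mm(e, s))
            assert pixel_error_to_mm(e, k * s) == pytest.approx(
                k * pixel_error_to_mm(e, s))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pixel_error_to_mm(-1.0, 0.12)
        with pytest.raises(ValueError):
            pixel_error_to_mm(1.0, 0.0)


class TestProbeIO:
    def test_pose_json_roundtrip(self, tmp_path, probe):
        poses = simulate_pivot_sequence(probe, 5, 0.0, seed=4)
        save_poses(tmp_path / "poses.json", poses)
        back = load_poses(tmp_path / "poses.json")
        for a, b in zip(poses, back):
            assert np.array_equal(a.R_m, b.R_m)
            assert np.array_equal(a.t_m, b.t_m)

    def test_probe_yaml_roundtrip(self, tmp_path, probe):
        save_probe(tmp_path / "probe.yaml", probe)
        back = load_probe(tmp_path / "probe.yaml")
        assert np.array_equal(back.T_probe, probe.T_probe)
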