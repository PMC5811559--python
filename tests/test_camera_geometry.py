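"""Camera model, junction detection/labeling and calibration."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from panomap.camera_geometry import (
    CalibrationCuboid,
    CameraModel,
    JunctionObservations,
    adjust_camera_pose,
    calibrate_camera,
    detect_junctions,
    label_junctions,
    project_point,
    reprojection_rmse,
    world_to_camera,
)
from panomap.errors import (
    CalibrationError,
    LabelingError,
    UnprojectablePointError,
)


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


def _random_camera(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    return CameraModel(R=R, t=rng.normal(size=3), f=200 + 100 * rng.random(),
                       s=0.9 + 0.2 * rng.random(), u0=50.0, v0=60.0,
                       image_size=(128, 128))


class TestWorldToCamera:
    def test_identity_transform(self):
        cam = CameraModel(R=np.eye(3), t=np.zeros(3), f=100, s=1,
                          u0=50, v0=50, image_size=(100, 100))
        assert np.allclose(world_to_camera(cam, [1, 2, 3]), [1, 2, 3])

    def test_half_turn_about_z(self):
        cam = CameraModel(R=_rot_z(180), t=np.zeros(3), f=100, s=1,
                          u0=50, v0=50, image_size=(100, 100))
        assert np.allclose(world_to_camera(cam, [1, 0, 0]), [-1, 0, 0])

    def test_matches_homogeneous_matrix_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cam = _random_camera(rng)
            M = np.eye(4)
            M[:3, :3] = cam.R
            M[:3, 3] = cam.t
            pts = rng.normal(size=(50, 3))
            expect = (np.hstack([pts, np.ones((50, 1))]) @ M.T)[:, :3]
            assert np.allclose(world_to_camera(cam, pts), expect)

    def test_inverse_recovers_point(self):
        rng = np.random.default_rng(3)
        cam = _random_camera(rng)
        p = rng.normal(size=3)
        pc = world_to_camera(cam, p)
        assert np.allclose(cam.R.T @ (pc - cam.t), p)


class TestProjectPoint:
    def test_optical_axis_maps_to_principal_point(self):
        cam = CameraModel(R=np.eye(3), t=np.zeros(3), f=123, s=1.1,
                          u0=40, v0=60, image_size=(100, 100))
        for z in (0.5, 2.0, 77.0):
            assert np.allclose(project_point(cam, [0, 0, z]), [40, 60])

    def test_worked_example(self):
        cam = CameraModel(R=np.eye(3), t=np.zeros(3), f=100, s=1,
                          u0=50, v0=50, image_size=(200, 200))
        assert np.allclose(project_point(cam, [1, 0, 2]), [100, 50])

    def test_behind_camera_raises(self):
        cam = CameraModel(R=np.eye(3), t=np.zeros(3), f=100, s=1,
                          u0=50, v0=50, image_size=(100, 100))
        with pytest.raises(UnprojectablePointError):
            project_point(cam, [0, 0, -1])

    def test_radial_distortion_scalar_oracle(self):
        # independent step-by-step evaluation of the same model
        cam = CameraModel(R=np.eye(3), t=np.zeros(3), f=150, s=1.05,
                          u0=64, v0=48, k1=-0.12, image_size=(128, 96))
        p = np.array([0.3, -0.2, 1.7])
        x, y = p[0] / p[2], p[1] / p[2]
        r2 = x * x + y * y
        u = 150 * x * (1 - 0.12 * r2) + 64
        v = 1.05 * 150 * y * (1 - 0.12 * r2) + 48
        assert np.allclose(project_point(cam, p), [u, v], atol=1e-12)

    def test_matches_projection_matrix_for_zero_distortion(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            cam = _random_camera(rng)
            K = np.array([[cam.f, 0, cam.u0],
                          [0, cam.s * cam.f, cam.v0],
                          [0, 0, 1.0]])
            P = K @ np.hstack([cam.R, cam.t[:, None]])
            pts = rng.normal(size=(1000, 3))
            pc = world_to_camera(cam, pts)
            front = pc[:, 2] > 0.1
            h = np.hstack([pts[front], np.ones((front.sum(), 1))]) @ P.T
            expect = h[:, :2] / h[:, 2:3]
            assert np.allclose(project_point(cam, pts[front]), expect)


class TestDetectJunctions:
    def test_two_face_render_yields_64(self, calibration_scene):
        pts = detect_junctions(calibration_scene["image"],
                               calibration_scene["mask"])
        assert len(pts) == 64

    def test_detections_within_half_pixel_of_truth(self, calibration_scene):
        pts = detect_junctions(calibration_scene["image"],
                               calibration_scene["mask"])
        truth = calibration_scene["truth"].pixels
        d, idx = cKDTree(truth).query(pts)
        assert np.all(d < 0.5)
        assert len(np.unique(idx)) == len(pts)

    def test_blank_image_gives_empty_result(self):
        img = np.full((64, 64), 0.5)
        pts = detect_junctions(img, np.ones_like(img, dtype=bool))
        assert len(pts) == 0

    def test_empty_mask_warns(self):
        img = np.random.default_rng(0).random((32, 32))
        with pytest.warns(UserWarning, match="empty"):
            pts = detect_junctions(img, np.zeros_like(img, dtype=bool))
        assert len(pts) == 0


def _cuboid_symmetry_residual(cuboid, labels_a, labels_b):
    """Kabsch residual between two labelings of the same pixel set; 0 iff
    they differ by a rigid symmetry of the junction cloud."""
    A = cuboid.junction_coords[labels_a]
    B = cuboid.junction_coords[labels_b]
    H = B.T @ A
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1, 1, d]) @ U.T
    return np.abs(A - B @ R.T).max()


class TestLabelJunctions:
    def test_full_grid_matches_truth_up_to_cuboid_symmetry(
        self, calibration_scene
    ):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        obs = label_junctions(truth.pixels, cub)
        assert len(obs.labels) == 64
        assert _cuboid_symmetry_residual(cub, truth.labels, obs.labels) < 1e-9
        # and the labeling supports an essentially perfect calibration
        cam = calibrate_camera(obs, cub, image_size=(256, 256))
        assert reprojection_rmse(cam, obs, cub) < 1e-6

    def test_anchored_labels_match_truth_exactly(self, calibration_scene):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        s = truth.pixels.sum(axis=1)
        i_tl, i_br = int(np.argmin(s)), int(np.argmax(s))
        obs = label_junctions(
            truth.pixels, cub,
            anchors=[(truth.pixels[i_tl], int(truth.labels[i_tl])),
                     (truth.pixels[i_br], int(truth.labels[i_br]))],
        )
        assert np.array_equal(obs.labels, truth.labels)

    def test_single_point_with_self_anchor(self, cuboid):
        p = np.array([[10.0, 20.0]])
        obs = label_junctions(p, cuboid, anchors=[(p[0], 17)])
        assert list(obs.labels) == [17]

    def test_inconsistent_anchors_fail(self, calibration_scene):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        # anchors on opposite (non-adjacent) faces cannot share a view
        j_far = cub.junction_index(2, 0, 0)
        with pytest.raises(LabelingError):
            label_junctions(
                truth.pixels, cub,
                anchors=[(truth.pixels[0], int(truth.labels[0])),
                         (truth.pixels[-1], j_far)],
            )


class TestCalibration:
    def test_noiseless_recovery_is_exact(self, calibration_scene):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        true_cam = calibration_scene["camera"]
        cam = calibrate_camera(truth, cub, image_size=true_cam.image_size)
        assert reprojection_rmse(cam, truth, cub) <= 1e-6
        assert abs(cam.f - true_cam.f) / true_cam.f <= 1e-6
        assert abs(cam.s - true_cam.s) <= 1e-6
        assert abs(cam.u0 - true_cam.u0) / true_cam.u0 <= 1e-6
        assert abs(cam.v0 - true_cam.v0) / true_cam.v0 <= 1e-6
        assert np.abs(cam.R - true_cam.R).max() <= 1e-6
        assert np.abs(cam.t - true_cam.t).max() <= 1e-6

    def test_noisy_recovery_rmse_below_1px(self, calibration_scene):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        rmses = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = JunctionObservations(
                truth.pixels + rng.normal(0, 0.5, truth.pixels.shape),
                truth.labels,
            )
            cam = calibrate_camera(noisy, cub, image_size=(256, 256))
            rmses.append(reprojection_rmse(cam, noisy, cub))
        assert np.mean(rmses) <= 1.0

    def test_underdetermined_raises(self, calibration_scene, cuboid):
        truth = calibration_scene["truth"]
        small = JunctionObservations(truth.pixels[:5], truth.labels[:5])
        with pytest.raises(CalibrationError):
            calibrate_camera(small, cuboid)

    def test_optical_axis_points_at_target(self, calibration_scene):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        cam = calibrate_camera(truth, cub, image_size=(256, 256))
        assert cam.optical_axis @ (-cam.position) > 0


class TestReprojectionRmse:
    def test_zero_on_own_synthesis(self, calibration_scene):
        truth = calibration_scene["truth"]
        assert reprojection_rmse(
            calibration_scene["camera"], truth, calibration_scene["cuboid"]
        ) < 1e-9

    def test_uniform_shift_gives_unit_rmse(self, calibration_scene):
        truth = calibration_scene["truth"]
        shifted = JunctionObservations(truth.pixels + [1.0, 0.0],
                                       truth.labels)
        rmse = reprojection_rmse(calibration_scene["camera"], shifted,
                                 calibration_scene["cuboid"])
        assert np.isclose(rmse, 1.0)

    def test_matches_direct_formula(self, calibration_scene):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        cam = calibration_scene["camera"]
        rng = np.random.default_rng(5)
        pert = truth.pixels + rng.normal(0, 2.0, truth.pixels.shape)
        obs = JunctionObservations(pert, truth.labels)
        uv = project_point(cam, cub.junction_coords[truth.labels])
        expect = np.sqrt(np.mean(np.sum((uv - pert) ** 2, axis=1)))
        assert np.isclose(reprojection_rmse(cam, obs, cub), expect)

    def test_empty_observations_raise(self, cuboid, calibration_scene):
        empty = JunctionObservations(np.empty((0, 2)), np.empty(0, dtype=int))
        with pytest.raises(CalibrationError):
            reprojection_rmse(calibration_scene["camera"], empty, cuboid)


class TestAdjustCameraPose:
    def test_zero_deltas_identity(self, calibration_scene):
        cam = calibration_scene["camera"]
        out = adjust_camera_pose(cam, [0, 0, 0], [0, 0, 0])
        assert np.allclose(out.R, cam.R) and np.allclose(out.t, cam.t)

    def test_rotation_roundtrip(self, calibration_scene):
        cam = calibration_scene["camera"]
        out = adjust_camera_pose(cam, [1.0, 0, 0], [0, 0, 0])
        back = adjust_camera_pose(out, [-1.0, 0, 0], [0, 0, 0])
        assert np.allclose(back.R, cam.R, atol=1e-12)
        assert np.allclose(back.t, cam.t, atol=1e-12)

    def test_correction_restores_reprojection(self, calibration_scene):
        truth = calibration_scene["truth"]
        cub = calibration_scene["cuboid"]
        cam = calibration_scene["camera"]
        pert = adjust_camera_pose(cam, [0.5, -0.3, 0.2], [0.01, 0, -0.02])
        rmse_pert = reprojection_rmse(pert, truth, cub)
        # recovering the pose must undo the degradation
        fixed = adjust_camera_pose(pert, [0, 0, 0], [-0.01, 0, 0.02])
        fixed = adjust_camera_pose(fixed, [-0.5, 0.3, -0.2], [0, 0, 0])
        assert reprojection_rmse(fixed, truth, cub) < rmse_pert
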