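import numpy as np
import pytest

from divekin.calibration import (
    DLTCamera,
    calibrate_dlt,
    project,
    reconstruct_3d,
    reconstruct_series,
    self_reconstruction_error,
)
from divekin.errors import (
    BehindCameraError,
    DegenerateGeometryError,
    InsufficientPointsError,
    InsufficientViewsError,
)
from divekin.synthetic_data import ControlPointSet, make_camera_rig


def _working_volume_points(rng, n):
    """Random points where the goalkeeper moves: in front of the goal."""
    return np.column_stack(
        [rng.uniform(0.0, 2.5, n), rng.uniform(-3.0, 3.0, n), rng.uniform(0.0, 2.2, n)]
    )


class TestProject:
    def test_forward_formula_hand_value(self):
        # u = (X + 4) / (0.1 Z + 1), v = (2 Y + 8) / (0.1 Z + 1)
        cam = DLTCamera("hand", L=[1, 0, 0, 4, 0, 2, 0, 8, 0, 0, 0.1])
        uv = project(cam, np.array([2.0, 3.0, 10.0]))
        assert uv[0] == pytest.approx((2 + 4) / 2.0)
        assert uv[1] == pytest.approx((6 + 8) / 2.0)

    def test_numerator_scaling_is_linear_with_zero_denominator_terms(self):
        L = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 0, 0, 0])
        cam = DLTCamera("a", L=L)
        cam2 = DLTCamera("b", L=L * 3.0)  # denominator coefficients stay 0
        p = np.array([0.3, -0.2, 1.5])
        assert np.allclose(project(cam2, p), 3.0 * project(cam, p))

    def test_behind_camera_raises(self):
        cam = DLTCamera("c", L=[1, 0, 0, 0, 0, 1, 0, 0, 0, 0, -1.0])
        with pytest.raises(BehindCameraError):
            project(cam, np.array([0.0, 0.0, 2.0]))


class TestCalibrate:
    def test_exact_recovery_from_noiseless_projections(self, cameras, control_points):
        for cam in cameras:
            refit = calibrate_dlt(
                control_points.xyz, control_points.uv_per_camera[cam.camera_id],
                camera_id=cam.camera_id,
            )
            assert refit.reprojection_rmse < 1e-6

    def test_coplanar_control_points_rejected(self):
        # all points in the goal face plane (X = 0): no depth information
        rng = np.random.default_rng(0)
        xyz = np.column_stack(
            [np.zeros(11), rng.uniform(-3.6, 3.6, 11), rng.uniform(0, 2.4, 11)]
        )
        uv = rng.uniform(0, 1000, size=(11, 2))
        with pytest.raises(DegenerateGeometryError, match="singular-value ratio"):
            calibrate_dlt(xyz, uv)

    def test_fewer_than_six_points_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(InsufficientPointsError):
            calibrate_dlt(rng.uniform(0, 1, (5, 3)), rng.uniform(0, 1, (5, 2)))

    def test_invariant_to_control_point_relabeling(self, control_points, cameras):
        cam_id = cameras[0].camera_id
        xyz = control_points.xyz
        uv = control_points.uv_per_camera[cam_id]
        perm = np.random.default_rng(2).permutation(len(xyz))
        a = calibrate_dlt(xyz, uv)
        b = calibrate_dlt(xyz[perm], uv[perm])
        assert np.allclose(a.L, b.L, atol=1e-9)


class TestReconstruct:
    def test_noiseless_point_recovered_exactly(self, cameras):
        p = np.array([0.0, 0.0, 1.22])
        obs = [project(c, p) for c in cameras[:2]]
        rec = reconstruct_3d(cameras[:2], obs)
        assert np.max(np.abs(rec - p)) < 1e-9

    def test_roundtrip_1000_random_points(self, cameras, rng):
        pts = _working_volume_points(rng, 1000)
        for cams in (cameras[:2], cameras):
            uv = np.stack([project(c, pts) for c in cams])
            rec = reconstruct_series(cams, uv)
            assert np.max(np.abs(rec - pts)) < 1e-6

    def test_missing_view_falls_back_to_remaining_two(self, cameras):
        p = np.array([0.5, -1.0, 1.0])
        obs = [project(cameras[0], p), None, project(cameras[2], p)]
        rec = reconstruct_3d(cameras, obs)
        assert np.max(np.abs(rec - p)) < 1e-9

    def test_fewer_than_two_views_rejected(self, cameras):
        with pytest.raises(InsufficientViewsError):
            reconstruct_3d(cameras, [np.array([1.0, 2.0]), None, None])

    def test_noisy_rmse_matches_bruteforce_oracle(self, cameras, rng):
        # vectorized normal-equation solver vs a plain per-point lstsq loop
        pts = _working_volume_points(rng, 300)
        uv = np.stack([project(c, pts) for c in cameras])
        uv_noisy = uv + rng.normal(0, 2.0, uv.shape)
        rec = reconstruct_series(cameras, uv_noisy)

        oracle = np.empty_like(pts)
        for i in range(pts.shape[0]):
            rows_A, rows_b = [], []
            for c, cam in enumerate(cameras):
                L = cam.L
                u, v = uv_noisy[c, i]
                rows_A.append(L[0:3] - u * L[8:11])
                rows_A.append(L[4:7] - v * L[8:11])
                rows_b.extend([u - L[3], v - L[7]])
            oracle[i], *_ = np.linalg.lstsq(
                np.array(rows_A), np.array(rows_b), rcond=None
            )
        assert np.max(np.abs(rec - oracle)) < 1e-8
        rmse = np.sqrt(np.mean((rec - pts) ** 2, axis=0))
        rmse_oracle = np.sqrt(np.mean((oracle - pts) ** 2, axis=0))
        assert np.allclose(rmse, rmse_oracle, rtol=0.10)

    def test_more_cameras_do_not_hurt_under_noise(self, rng):
        cams4, _ = make_camera_rig(
            [("a", (16.0, 0.0, 1.5)), ("b", (9.0, 7.0, 2.2)),
             ("c", (9.0, -7.0, 2.2)), ("d", (12.0, 3.0, 3.0))]
        )
        pts = _working_volume_points(rng, 400)
        uv = np.stack([project(c, pts) for c in cams4])
        noise = rng.normal(0, 2.0, uv.shape)
        rec2 = reconstruct_series(cams4[1:3], uv[1:3] + noise[1:3])
        rec4 = reconstruct_series(cams4, uv + noise)
        rmse2 = np.sqrt(np.mean((rec2 - pts) ** 2))
        rmse4 = np.sqrt(np.mean((rec4 - pts) ** 2))
        assert rmse4 <= rmse2


class TestSelfReconstruction:
    def test_noiseless_rig_error_is_zero(self, cameras, control_points):
        err = self_reconstruction_error(cameras, control_points)
        assert np.max(err) < 1e-9

    def test_matches_independent_loop_recomputation(self, cameras, control_points, rng):
        noisy = ControlPointSet(
            ids=control_points.ids,
            xyz=control_points.xyz,
            uv_per_camera={
                k: v + rng.normal(0, 1.0, v.shape)
                for k, v in control_points.uv_per_camera.items()
            },
        )
        err = self_reconstruction_error(cameras, noisy)
        per_point = []
        for i in range(noisy.xyz.shape[0]):
            obs = [noisy.uv_per_camera[c.camera_id][i] for c in cameras]
            per_point.append(reconstruct_3d(cameras, obs) - noisy.xyz[i])
        oracle = np.mean(np.abs(per_point), axis=0)
        assert np.allclose(err, oracle, atol=1e-12)

    def test_depth_axis_error_inflation_with_narrow_baseline(self, rng):
        # two cameras in front of the goal with a small lateral baseline:
        # the anteroposterior (X) axis is close to both optical axes and its
        # triangulation error inflates relative to the mediolateral (Y) axis
        cams, points = make_camera_rig(
            [("a", (14.0, 2.0, 2.0)), ("b", (14.0, -2.0, 2.0))]
        )
        noisy = ControlPointSet(
            ids=points.ids,
            xyz=points.xyz,
            uv_per_camera={
                k: v + rng.normal(0, 2.0, v.shape)
                for k, v in points.uv_per_camera.items()
            },
        )
        err = self_reconstruction_error(cams, noisy)
        assert err[0] > err[1]
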