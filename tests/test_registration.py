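"""Registration: the nearest-neighbor objective and multi-start pose fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingkin.cloud import PointCloud3D
from wingkin.errors import EmptyInputError, IllPosedFitError
from wingkin.geometry import RigidTransform, unit
from wingkin.registration import (
    FitOptions,
    fit_all,
    fit_pose,
    fits_to_frame,
    frame_to_fits,
    mean_nn_distance,
    transform_points,
)
from wingkin.synthetic import FALCON_MOTION


def brute_force_mean_nn(moving, reference):
    """O(N·M) oracle: per moving point, scan every reference point."""
    total = 0.0
    for p in moving:
        total += min(np.linalg.norm(p - q) for q in reference)
    return total / len(moving)


class TestMeanNNDistance:
    def test_cloud_vs_itself_is_zero(self, rng):
        c = PointCloud3D(rng.normal(size=(30, 3)))
        assert mean_nn_distance(c, c) == 0.0

    def test_single_point_closed_form(self):
        moving = PointCloud3D([[0.0, 0.0, 0.0]])
        reference = PointCloud3D([[3.0, 4.0, 0.0], [10.0, 0.0, 0.0]])
        assert mean_nn_distance(moving, reference) == pytest.approx(5.0)

    def test_asymmetric_in_arguments(self):
        a = PointCloud3D([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        b = PointCloud3D([[0.0, 0.0, 0.0]])
        assert mean_nn_distance(a, b) != mean_nn_distance(b, a)

    def test_empty_cloud_rejected(self):
        c = PointCloud3D(np.zeros((0, 3)))
        d = PointCloud3D([[0.0, 0.0, 0.0]])
        with pytest.raises(EmptyInputError):
            mean_nn_distance(c, d)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        moving = PointCloud3D(rng.normal(size=(rng.integers(1, 50), 3)) * 10)
        reference = PointCloud3D(rng.normal(size=(rng.integers(1, 50), 3)) * 10)
        assert mean_nn_distance(moving, reference) == pytest.approx(
            brute_force_mean_nn(moving.points, reference.points), abs=1e-12)

    def test_squared_variant(self, rng):
        moving = PointCloud3D(rng.normal(size=(20, 3)))
        reference = PointCloud3D(rng.normal(size=(25, 3)))
        from scipy.spatial import cKDTree
        d, _ = cKDTree(reference.points).query(moving.points)
        assert mean_nn_distance(moving, reference, squared=True) == pytest.approx(
            float(np.mean(d ** 2)))


class TestTransformPoints:
    def test_identity(self, rng):
        c = PointCloud3D(rng.normal(size=(10, 3)))
        assert np.array_equal(transform_points(c, RigidTransform.identity()).points,
                              c.points)

    def test_pure_translation_shifts_z(self, rng):
        c = PointCloud3D(rng.normal(size=(10, 3)))
        out = transform_points(c, RigidTransform(np.eye(3), [0, 0, 1.0]))
        assert np.allclose(out.points[:, 2], c.points[:, 2] + 1.0)

    def test_measured_rotation_round_trip(self, rng):
        axis, angle = FALCON_MOTION["ulna"]["flexion"]
        tf = RigidTransform.from_axis_angle(unit(axis), angle,
                                            translation=[1.0, -4.0, 2.0])
        c = PointCloud3D(rng.normal(size=(40, 3)) * 20)
        back = transform_points(transform_points(c, tf), tf.inverse())
        assert np.allclose(back.points, c.points, atol=1e-9)


@pytest.fixture(scope="module")
def bone_cloud():
    from wingkin.synthetic import SyntheticSpec, generate_bone_cloud

    return generate_bone_cloud(SyntheticSpec(
        bone_name="b", n_points=600, length_mm=60.0, radius_mm=3.0,
        noise_sigma_mm=0.0, seed=5))


class TestFitPose:
    def test_self_fit_is_identity(self, bone_cloud):
        res = fit_pose(bone_cloud, bone_cloud, FitOptions(n_starts=4, seed=0))
        assert res.residual_mm < 1e-6
        assert res.transform.rotation_angle_deg() < 0.01

    def test_recovers_known_rotation(self, bone_cloud):
        """20 deg rotation, no noise, full overlap: angle within 0.05 deg."""
        tf = RigidTransform.from_axis_angle([0.1, 0.2, 0.97], 20.0)
        moving = transform_points(bone_cloud, tf)
        res = fit_pose(moving, bone_cloud, FitOptions(n_starts=8, seed=1))
        # recovered transform maps moving back onto the reference
        assert res.transform.rotation_angle_deg() == pytest.approx(20.0, abs=0.05)
        assert res.residual_mm < 1e-4

    def test_deterministic_given_seed(self, bone_cloud):
        tf = RigidTransform.from_axis_angle([0, 0, 1], 30.0)
        moving = transform_points(bone_cloud, tf)
        opts = FitOptions(n_starts=6, seed=42)
        a = fit_pose(moving, bone_cloud, opts)
        b = fit_pose(moving, bone_cloud, opts)
        assert np.array_equal(a.transform.rotation, b.transform.rotation)
        assert a.residual_mm == b.residual_mm

    def test_returned_rotation_is_orthonormal(self, bone_cloud):
        tf = RigidTransform.from_axis_angle([0.3, -0.2, 0.93], 50.0)
        moving = transform_points(bone_cloud, tf)
        res = fit_pose(moving, bone_cloud, FitOptions(n_starts=6, seed=2))
        r = res.transform.rotation
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_more_starts_never_worse(self, bone_cloud):
        """Best-of-k residual is monotone in k on the same seed stream."""
        tf = RigidTransform.from_axis_angle([0.2, -0.1, 0.97], 55.0)
        moving = transform_points(bone_cloud, tf)
        resids = [
            fit_pose(moving, bone_cloud,
                     FitOptions(n_starts=k, seed=9, polish=False)).residual_mm
            for k in (1, 4, 12)]
        # tolerance: ties at the numerical floor differ by float jitter only
        assert resids[0] >= resids[1] - 1e-9
        assert resids[1] >= resids[2] - 1e-9

    def test_rank_deficient_moving_cloud_rejected(self, bone_cloud):
        flat = PointCloud3D(np.column_stack([np.arange(10.0), np.arange(10.0),
                                             np.zeros(10)]))
        with pytest.raises(IllPosedFitError):
            fit_pose(flat, bone_cloud)


class TestFitAll:
    def test_count_contract(self, small_fits):
        assert len(small_fits) == 5
        for per_bone in small_fits.values():
            assert set(per_bone) == {"extension", "half_extension", "flexion"}
            ext = per_bone["extension"]
            assert ext.transform.rotation_angle_deg() == 0.0

    def test_residuals_near_noise_floor(self, base_clouds, truth_absolute):
        """At full overlap the fitted residual stays within 3x the noise sigma."""
        from wingkin.synthetic import pose_clouds

        clouds = pose_clouds(base_clouds, truth_absolute,
                             overlap_fraction=1.0, seed=4)
        fits = fit_all(clouds, FitOptions(n_starts=8, seed=4))
        for per_bone in fits.values():
            for posture in ("half_extension", "flexion"):
                assert per_bone[posture].residual_mm <= 3 * 0.2

    def test_table_round_trip(self, small_fits):
        df = fits_to_frame(small_fits)
        back = frame_to_fits(df)
        tf = small_fits["ulna"]["flexion"].transform
        assert np.allclose(back["ulna"]["flexion"].transform.rotation,
                           tf.rotation, atol=1e-12)
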