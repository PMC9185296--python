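"""Rigid landmark alignment, transform application, ICP, projective scale."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import berrycloud as bc
from berrycloud.alignment import DegenerateConfigurationError, alignment_rms, scale_about_origin

from conftest import random_rotation, sphere_surface_points


def random_transform(rng, trans_scale=50.0):
    return bc.RigidTransform(random_rotation(rng), rng.uniform(-trans_scale, trans_scale, 3))


class TestLandmarkAlign:
    def test_identity_on_equal_clouds(self, rng):
        X = rng.normal(size=(20, 3))
        t = bc.landmark_align(X, X)
        np.testing.assert_allclose(t.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.T, 0, atol=1e-12)
        assert alignment_rms(X, X, t) < 1e-12

    def test_recovers_known_transform_exactly(self, rng):
        for _ in range(20):
            X = rng.normal(scale=30, size=(15, 3))
            truth = random_transform(rng)
            Y = truth.apply(X)
            t = bc.landmark_align(X, Y)
            assert np.linalg.norm(t.R - truth.R) < 1e-9
            assert np.linalg.norm(t.T - truth.T) < 1e-9

    def test_mirrored_cloud_returns_proper_rotation(self, rng):
        X = rng.normal(size=(30, 3))
        Y = X * np.array([-1.0, 1.0, 1.0])   # reflection
        t = bc.landmark_align(X, Y)
        assert np.linalg.det(t.R) > 0
        assert alignment_rms(X, Y, t) > 1e-3

    def test_collinear_rejected(self):
        X = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            bc.landmark_align(X, X + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            bc.landmark_align(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_numeric_minimiser(self, rng):
        """Closed form equals a brute-force optimiser over Euler angles."""
        for _ in range(3):
            X = rng.normal(scale=20, size=(10, 3))
            Y = random_transform(rng).apply(X) + rng.normal(scale=0.5, size=(10, 3))
            t = bc.landmark_align(X, Y)

            def objective(params):
                R = Rotation.from_euler("xyz", params[:3]).as_matrix()
                return np.sum((Y - X @ R.T - params[3:]) ** 2)

            x0 = np.concatenate([Rotation.from_matrix(t.R).as_euler("xyz"), t.T])
            # perturbed restarts confirm the closed form is the global optimum
            best = min(
                minimize(objective, x0 + rng.normal(scale=0.1, size=6), method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000}).fun
                for _ in range(3)
            )
            closed = np.sum((Y - X @ t.R.T - t.T) ** 2)
            assert closed <= best + 1e-6


class TestApplyTransform:
    def test_identity(self, rng):
        cloud = bc.PointCloud(points=rng.normal(size=(10, 3)))
        out = bc.apply_transform(cloud, bc.RigidTransform.identity())
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_pure_translation_shifts_z(self, rng):
        cloud = bc.PointCloud(points=rng.normal(size=(10, 3)))
        t = bc.RigidTransform(np.eye(3), [0, 0, 10.0])
        np.testing.assert_allclose(bc.apply_transform(cloud, t).points[:, 2],
                                   cloud.points[:, 2] + 10.0)

    def test_inverse_composition_is_identity(self, rng):
        cloud = bc.PointCloud(points=rng.normal(scale=100, size=(50, 3)))
        t = random_transform(rng)
        t = bc.RigidTransform(t.R, t.T, s=1.3)
        back = bc.apply_transform(bc.apply_transform(cloud, t), t.inverse())
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-9)

    def test_normals_rotate_without_scale(self, rng):
        n = rng.normal(size=(5, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        cloud = bc.PointCloud(points=rng.normal(size=(5, 3)), normals=n)
        t = bc.RigidTransform(random_rotation(rng), np.zeros(3), s=2.0)
        out = bc.apply_transform(cloud, t)
        np.testing.assert_allclose(np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-12)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            bc.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestICP:
    def test_source_equals_target_converges_immediately(self, rng):
        cloud = bc.PointCloud(points=rng.normal(scale=50, size=(200, 3)))
        res = bc.icp_align(cloud, cloud)
        assert res.converged
        assert res.final_rms_mm < 1e-9
        np.testing.assert_allclose(res.transform.R, np.eye(3), atol=1e-9)

    def test_recovers_small_misalignment(self, rng):
        pts = np.vstack([sphere_surface_points(rng, c, 12.0, 800)
                         for c in ([0, 0, 600], [20, 5, 615], [-15, -10, 610])])
        target = bc.PointCloud(points=pts)
        R = Rotation.from_euler("y", 5, degrees=True).as_matrix()
        source = bc.PointCloud(points=(pts - [0, 0, 610]) @ R.T + [0, 0, 610] + [3, 0, 0])
        res = bc.icp_align(source, target, max_iterations=80)
        aligned = bc.apply_transform(source, res.transform)
        rms = bc.mean_error(bc.nearest_point_errors(aligned, target))
        assert rms < 0.1

    def test_zero_iterations_returns_init(self, rng):
        cloud = bc.PointCloud(points=rng.normal(size=(20, 3)))
        init = random_transform(rng)
        res = bc.icp_align(cloud, cloud, max_iterations=0, init=init)
        assert not res.converged
        assert res.iterations == 0
        np.testing.assert_array_equal(res.transform.R, init.R)

    def test_rms_monotone_non_increasing(self, rng):
        pts = sphere_surface_points(rng, [0, 0, 600], 13.0, 1000)
        target = bc.PointCloud(points=pts)
        source = bc.PointCloud(points=pts + rng.normal(scale=0.5, size=pts.shape) + [5, -3, 8])
        res = bc.icp_align(source, target, max_iterations=40, rms_tolerance_mm=0)
        diffs = np.diff(res.rms_history)
        assert np.all(diffs <= 1e-9)

    def test_empty_cloud_rejected(self):
        empty = bc.PointCloud(points=np.empty((0, 3)))
        with pytest.raises(ValueError):
            bc.icp_align(empty, empty)


class TestProjectiveScale:
    def test_identical_clouds_give_unity(self, rng):
        cloud = bc.PointCloud(points=sphere_surface_points(rng, [0, 0, 600], 13.0, 200))
        assert bc.projective_scale(cloud, cloud) == pytest.approx(1.0)

    def test_recovers_uniform_scale_about_origin(self, rng):
        ref = bc.PointCloud(points=sphere_surface_points(rng, [0, 0, 600], 13.0, 200))
        src = bc.PointCloud(points=ref.points * 1.02)
        assert bc.projective_scale(src, ref) == pytest.approx(1 / 1.02, abs=1e-9)

    def test_depth_biased_shell(self, rng):
        d = rng.normal(size=(500, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        d[:, 2] = np.abs(d[:, 2])
        ref = bc.PointCloud(points=600.0 * d)
        src = bc.PointCloud(points=608.0 * d)
        s = bc.projective_scale(src, ref)
        assert s == pytest.approx(600.0 / 608.0, abs=1e-9)
        scaled = bc.apply_transform(src, scale_about_origin(s))
        np.testing.assert_allclose(scaled.points, ref.points, atol=1e-9)
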