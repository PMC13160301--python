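"""Landmark alignment, SOR filtering, ICP, distance reports, map motion."""

import numpy as np
import pytest
import trimesh

from slnav.geometry import PointCloud, RigidTransform, angle_between_lines
from slnav.registration import (DistanceReport, ICPParams, LandmarkPairs,
                                cloud_to_mesh_distance, icp_refine,
                                register_map, rough_register, sor_filter)
from slnav.tracking import Channel, NavigationalMap


class TestRoughRegister:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.normal(size=(6, 3)) * 100
        t = rough_register(LandmarkPairs(pts, pts))
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_recovers_known_transform_from_four_pairs(self, rng):
        for _ in range(10):
            src = rng.normal(size=(4, 3)) * 100
            truth = RigidTransform.random(rng)
            t = rough_register(LandmarkPairs(src, truth.apply(src)))
            assert np.allclose(t.matrix, truth.matrix, atol=1e-9)

    def test_three_pairs_rejected(self, rng):
        pts = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="4"):
            LandmarkPairs(pts, pts)

    def test_collinear_landmarks_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            rough_register(LandmarkPairs(src, src + 1.0))

    def test_duplicate_landmarks_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        with pytest.raises(ValueError, match="duplicate"):
            LandmarkPairs(src, src)


def _grid_cloud(n=10, spacing=1.0):
    g = np.arange(n) * spacing
    gx, gy = np.meshgrid(g, g)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    return PointCloud(pts)


def _brute_force_sor_mask(points, k, mult):
    """Independent scalar re-implementation of the SOR criterion."""
    n = len(points)
    mean_knn = np.empty(n)
    for i in range(n):
        d = np.sort(np.linalg.norm(points - points[i], axis=1))
        mean_knn[i] = d[1:k + 1].mean()  # skip self
    thr = mean_knn.mean() + mult * mean_knn.std()
    return mean_knn <= thr


def _ring_cloud(n=120, radius=20.0):
    """Boundary-free homogeneous sampling (every point sees the same k-NN
    statistic, unlike a bounded grid whose corners are genuine outliers of
    the statistic)."""
    a = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return PointCloud(np.column_stack([radius * np.cos(a), radius * np.sin(a),
                                       np.zeros(n)]))


class TestSorFilter:
    def test_homogeneous_cloud_untouched(self):
        cloud = _ring_cloud()
        assert len(sor_filter(cloud, 6, 1.0)) == len(cloud)

    def test_displaced_point_removed(self):
        cloud = _grid_cloud()
        pts = cloud.points.copy()
        pts[37] = [1000.0, 1000.0, 1000.0]
        filtered = sor_filter(PointCloud(pts), 6, 1.0)
        expected = _brute_force_sor_mask(pts, 6, 1.0)
        assert np.array_equal(filtered.points, pts[expected])
        assert not expected[37]
        assert expected.sum() == len(pts) - 1

    def test_matches_brute_force_on_random_cloud(self, rng):
        pts = rng.normal(size=(400, 3)) * 20
        filtered = sor_filter(PointCloud(pts), 6, 1.0)
        expected = _brute_force_sor_mask(pts, 6, 1.0)
        assert np.array_equal(filtered.points, pts[expected])

    def test_idempotent_on_homogeneous_cloud(self):
        cloud = _ring_cloud()
        once = sor_filter(cloud, 6, 1.0)
        twice = sor_filter(once, 6, 1.0)
        assert np.array_equal(once.points, twice.points)

    def test_small_cloud_returned_with_warning(self, rng):
        cloud = PointCloud(rng.normal(size=(4, 3)))
        with pytest.warns(UserWarning):
            out = sor_filter(cloud, 6, 1.0)
        assert np.array_equal(out.points, cloud.points)


class TestICP:
    def test_already_aligned_noiseless(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=40.0)
        cloud = PointCloud(mesh.vertices[::2])
        res = icp_refine(cloud, mesh, RigidTransform.identity())
        assert res.rms <= 1e-6
        assert np.allclose(res.transform.matrix, np.eye(4), atol=1e-6)

    def test_empty_source_rejected(self):
        mesh = trimesh.creation.box(extents=(1, 1, 1))
        with pytest.raises(ValueError):
            icp_refine(PointCloud(np.zeros((0, 3))), mesh,
                       RigidTransform.identity())

    def test_cloud_target_recovery(self, rng):
        """Perturbed cloud against a cloud target recovers the pose."""
        pts = rng.normal(size=(500, 3)) * 30
        target = PointCloud(pts)
        truth = RigidTransform.from_rotvec_deg([0.5, -0.3, 0.2], [1.0, -0.5, 0.7])
        source = PointCloud(truth.invert().apply(pts))
        res = icp_refine(source, target, RigidTransform.identity(),
                         ICPParams(max_iterations=100))
        assert res.rms <= 1e-6
        assert np.allclose(res.transform.matrix, truth.matrix, atol=1e-5)


class TestCloudToMeshDistance:
    def test_points_on_surface(self, tiny_scene):
        mesh = tiny_scene.bones[0]
        samples, _ = trimesh.sample.sample_surface(mesh, 200, seed=1)
        report = cloud_to_mesh_distance(PointCloud(samples), mesh)
        assert report.mean_distance <= 1e-9

    def test_point_above_plane(self):
        plane = trimesh.Trimesh(
            vertices=[[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0.0]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False)
        h = 0.37
        report = cloud_to_mesh_distance(PointCloud([[0.2, 0.1, h]]), plane)
        assert report.mean_distance == pytest.approx(h, abs=1e-12)

    def test_mean_not_above_max(self, rng, tiny_scene):
        cloud = PointCloud(rng.normal(size=(50, 3)) * 40)
        report = cloud_to_mesh_distance(cloud, tiny_scene.bones[0])
        assert 0.0 <= report.mean_distance <= report.max_distance


class TestRegisterMap:
    def _map(self, scene):
        return NavigationalMap(skin=scene.skin, bones=list(scene.bones),
                               channels=list(scene.truth_trajectories),
                               frame="image")

    def _reg(self, t):
        from slnav.registration import RegistrationResult
        return RegistrationResult(transform=t, rms=0.0, iterations=1,
                                  converged=True, correspondence_count=4)

    def test_identity_flips_frame_only(self, tiny_scene):
        moved = register_map(self._map(tiny_scene),
                             self._reg(RigidTransform.identity()))
        assert moved.frame == "world"
        assert np.allclose(moved.skin.vertices, tiny_scene.skin.vertices)

    def test_double_application_rejected(self, tiny_scene):
        moved = register_map(self._map(tiny_scene),
                             self._reg(RigidTransform.identity()))
        with pytest.raises(ValueError, match="world"):
            register_map(moved, self._reg(RigidTransform.identity()))

    def test_self_consistency_of_distances(self, rng, tiny_scene):
        """Mean distance from the unmoved scan to the moved map's skin equals
        the pre-motion registration accuracy."""
        t_scan_to_model = RigidTransform.random(rng, max_angle_deg=20,
                                                max_translation=50)
        samples, _ = trimesh.sample.sample_surface(tiny_scene.skin, 150, seed=2)
        scan = PointCloud(t_scan_to_model.invert().apply(samples)
                          + rng.normal(0, 0.5, size=(150, 3)))
        pre = cloud_to_mesh_distance(scan.transformed(t_scan_to_model),
                                     tiny_scene.skin).mean_distance
        moved = register_map(self._map(tiny_scene), self._reg(t_scan_to_model))
        post = cloud_to_mesh_distance(scan, moved.skin).mean_distance
        assert post == pytest.approx(pre, abs=1e-9)

    def test_channel_angles_preserved(self, rng, tiny_scene):
        t = RigidTransform.random(rng)
        moved = register_map(self._map(tiny_scene), self._reg(t))
        for a0, a1 in zip(tiny_scene.truth_trajectories, moved.channels):
            pass
        chans0 = tiny_scene.truth_trajectories
        chans1 = moved.channels
        for i in range(len(chans0)):
            for j in range(i + 1, len(chans0)):
                assert angle_between_lines(chans0[i].direction, chans0[j].direction) \
                    == pytest.approx(
                        angle_between_lines(chans1[i].direction, chans1[j].direction),
                        abs=1e-9)
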