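"""Two-stage markerless registration of an intraoperative scan to the model.

Pipeline order is fixed: landmark rough alignment (at least 4 picked point
pairs, least-squares rigid), statistical outlier removal, then ICP fine
registration against the surface model with the root-mean-square (RMS)
correspondence distance of the final iteration reported.  The scalar
"registration accuracy" is the mean unsigned cloud-to-mesh distance of the
registered scan.  Finally the navigational map is carried into the camera
frame by the *inverse* of the scan-to-model transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import (PointCloud, RigidTransform, point_mesh_distances)
from .tracking import NavigationalMap

__all__ = [
    "LandmarkPairs",
    "ICPParams",
    "RegistrationResult",
    "DistanceReport",
    "rough_register",
    "sor_filter",
    "icp_refine",
    "cloud_to_mesh_distance",
    "register_map",
]

MIN_LANDMARK_PAIRS = 4


@dataclass(frozen=True)
class LandmarkPairs:
    """Ordered corresponding point pairs picked on scan and model."""

    source_points: np.ndarray  # on the scan
    target_points: np.ndarray  # on the model

    def __post_init__(self) -> None:
        src = np.asarray(self.source_points, dtype=float).reshape(-1, 3)
        tgt = np.asarray(self.target_points, dtype=float).reshape(-1, 3)
        if len(src) != len(tgt):
            raise ValueError("source and target landmark counts differ")
        if len(src) < MIN_LANDMARK_PAIRS:
            raise ValueError(
                f"landmark registration requires at least {MIN_LANDMARK_PAIRS} "
                f"equivalent point pairs, got {len(src)}")
        for name, pts in (("source", src), ("target", tgt)):
            if len(np.unique(pts, axis=0)) != len(pts):
                raise ValueError(f"duplicate {name} landmarks")
        object.__setattr__(self, "source_points", src)
        object.__setattr__(self, "target_points", tgt)


@dataclass(frozen=True)
class ICPParams:
    max_iterations: int = 300
    tolerance: float = 1e-8  # mm change in RMS between iterations
    sample_size: Optional[int] = None  # subsample source for speed; None = all
    seed: int = 0


@dataclass
class RegistrationResult:
    transform: RigidTransform  # maps scan (world) -> model (image) frame
    rms: float
    iterations: int
    converged: bool
    correspondence_count: int

    def to_dict(self) -> dict:
        return {"matrix": self.transform.to_list(), "rms": self.rms,
                "iterations": self.iterations, "converged": self.converged,
                "correspondence_count": self.correspondence_count}


@dataclass
class DistanceReport:
    mean_distance: float
    max_distance: float
    per_point: Optional[np.ndarray] = None


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform (rotation + translation, no scaling)."""
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    h = (source - cs).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) landmark configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform.from_rotation_translation(r, ct - r @ cs)


def rough_register(pairs: LandmarkPairs) -> RigidTransform:
    """Rigid transform minimising sum ||T s_i - t_i||^2 over the pairs."""
    return _kabsch(pairs.source_points, pairs.target_points)


def sor_filter(cloud: PointCloud, k_neighbors: int = 6,
               sigma_multiplier: float = 1.0) -> PointCloud:
    """Statistical outlier removal.

    Removes points whose mean distance to their ``k_neighbors`` nearest
    neighbours exceeds the global mean plus ``sigma_multiplier`` standard
    deviations of that statistic.  Survivor order is preserved.  Clouds
    with too few points are returned unchanged with a warning.
    """
    n = len(cloud)
    if n <= k_neighbors:
        warnings.warn(f"SOR skipped: {n} points <= k={k_neighbors}")
        return cloud
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)  # self included
    mean_knn = dists[:, 1:].mean(axis=1)
    threshold = mean_knn.mean() + sigma_multiplier * mean_knn.std()
    # relative epsilon keeps perfectly homogeneous clouds intact despite
    # float jitter in the statistic
    threshold += 1e-9 * max(abs(threshold), 1.0)
    return cloud.select(mean_knn <= threshold)


class _MeshCorrespondence:
    """Fast nearest-surface-point queries for ICP correspondence search.

    A k-d tree on triangle centroids proposes the k nearest candidate
    triangles per point; the exact point-to-triangle foot is evaluated on
    those.  For points near the surface (the ICP regime after rough
    alignment) the candidate set virtually always contains the true
    nearest triangle; the exhaustive search in
    :func:`slnav.geometry.point_mesh_distances` remains the exact path
    used for reported registration accuracy.
    """

    def __init__(self, mesh, k: int = 16, k_vertices: int = 4):
        from .geometry import _triangles_of
        self._tri = _triangles_of(mesh)
        self._centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._k = min(k, len(self._tri))
        # vertex-incidence candidates guard against sliver triangles whose
        # centroids are unrepresentative of their surface
        self._vtree = None
        if hasattr(mesh, "vertex_faces"):
            vf = np.asarray(mesh.vertex_faces)  # padded with -1
            if vf.size:
                self._vtree = cKDTree(np.asarray(mesh.vertices, dtype=float))
                self._vertex_faces = vf
                self._kv = min(k_vertices, vf.shape[0])

    def _candidates(self, points: np.ndarray) -> np.ndarray:
        _, idx = self._tree.query(points, k=self._k)
        if self._k == 1:
            idx = idx[:, None]
        if self._vtree is None:
            return idx
        _, vidx = self._vtree.query(points, k=self._kv)
        if self._kv == 1:
            vidx = vidx[:, None]
        incident = self._vertex_faces[vidx].reshape(len(points), -1)
        return np.concatenate([idx, incident], axis=1)

    def query(self, points: np.ndarray) -> np.ndarray:
        from .geometry import _point_triangle_sq_pairwise
        cand = self._candidates(points)
        n = len(points)
        best_d2 = np.full(n, np.inf)
        best_foot = np.empty((n, 3))
        for j in range(cand.shape[1]):
            col = cand[:, j]
            valid = col >= 0
            if not np.any(valid):
                continue
            d2, foot = _point_triangle_sq_pairwise(points,
                                                   self._tri[np.where(valid, col, 0)])
            d2 = np.where(valid, d2, np.inf)
            better = d2 < best_d2
            best_d2[better] = d2[better]
            best_foot[better] = foot[better]
        return best_foot


def _closest_points(points: np.ndarray, target) -> np.ndarray:
    if isinstance(target, PointCloud):
        tree = cKDTree(target.points)
        _, idx = tree.query(points)
        return target.points[idx]
    if isinstance(target, _MeshCorrespondence):
        return target.query(points)
    _, closest, _ = point_mesh_distances(points, target)
    return closest


def icp_refine(source: PointCloud, target, init: RigidTransform,
               params: Optional[ICPParams] = None) -> RegistrationResult:
    """Iterated Closest Points fine registration after rough alignment.

    Correspondences are nearest surface points on the reference (exact
    point-to-triangle feet when the target is a mesh; nearest neighbours
    when it is a cloud), followed by a least-squares rigid update, until
    the RMS change falls below ``params.tolerance`` or the iteration cap.
    The returned transform is the full scan-to-model map (fine update
    composed with ``init``); the RMS is over all retained source points at
    the final iteration.
    """
    params = params or ICPParams()
    if len(source) == 0:
        raise ValueError("cannot register an empty source cloud")
    pts_all = source.points
    if params.sample_size is not None and params.sample_size < len(pts_all):
        rng = np.random.default_rng(params.seed)
        idx = rng.choice(len(pts_all), size=params.sample_size, replace=False)
        pts_all = pts_all[np.sort(idx)]

    if not isinstance(target, (PointCloud, _MeshCorrespondence)):
        target = _MeshCorrespondence(target)
    total = init
    current = init.apply(pts_all)
    prev_rms = np.inf
    rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        corr = _closest_points(current, target)
        rms = float(np.sqrt(np.mean(np.sum((current - corr) ** 2, axis=1))))
        if abs(prev_rms - rms) < params.tolerance:
            converged = True
            break
        prev_rms = rms
        update = _kabsch(current, corr)
        total = update @ total
        current = update.apply(current)
    return RegistrationResult(transform=total, rms=rms, iterations=iterations,
                              converged=converged,
                              correspondence_count=len(pts_all))


def cloud_to_mesh_distance(cloud: PointCloud, mesh) -> DistanceReport:
    """Unsigned point-to-nearest-triangle distances: the registration
    accuracy scalar is the mean."""
    if len(cloud) == 0 or len(mesh.faces) == 0:
        raise ValueError("cloud and mesh must both be non-empty")
    d, _, _ = point_mesh_distances(cloud.points, mesh)
    return DistanceReport(mean_distance=float(d.mean()),
                          max_distance=float(d.max()), per_point=d)


def register_map(nav_map: NavigationalMap,
                 reg: RegistrationResult) -> NavigationalMap:
    """Move the navigational map into the camera (world) frame.

    ``reg.transform`` maps scan (world) to model (image); the map travels
    the other way, by the inverse transform, exactly as the software's
    inverse-transformation step does.  Applying it twice is an error.
    """
    if nav_map.frame == "world":
        raise ValueError("navigational map is already in the world frame")
    inv = reg.transform.invert()
    skin = nav_map.skin.copy()
    skin.apply_transform(inv.matrix)
    bones = []
    for bone in nav_map.bones:
        b = bone.copy()
        b.apply_transform(inv.matrix)
        bones.append(b)
    channels = [ch.transformed(inv, frame="world") for ch in nav_map.channels]
    return NavigationalMap(skin=skin, bones=bones, channels=channels, frame="world")
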