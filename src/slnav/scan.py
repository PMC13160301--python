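"""Simulated structured-light camera.

A pinhole perspective camera casts one ray per grid sample; each ray
returns at most one point, the first surface it meets (hidden surfaces are
never returned).  Points seen at grazing incidence beyond a cutoff are
dropped, Gaussian depth noise is applied along the viewing ray, and
uniform box outliers can be appended to exercise outlier filtering.  The
frustum half-angles are derived from the reference field of view
(800 x 605.8 mm at 1.5 m standoff) and returns are restricted to the
working range (0.9--2.9 m by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import trimesh

from .geometry import PointCloud, RigidTransform, first_hits

__all__ = ["CameraModel", "NoiseConfig", "ScanResult", "AnalyticCylinder",
           "simulate_scan", "add_outliers"]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole structured-light camera; +z of ``pose`` is the viewing axis."""

    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    reference_fov: tuple = (800.0, 605.8)  # mm at the reference standoff
    reference_standoff: float = 1500.0
    working_range: tuple = (900.0, 2900.0)
    grid: tuple = (150, 200)  # (rows, cols)
    max_incidence_deg: float = 80.0

    def __post_init__(self) -> None:
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid dimensions must be positive")
        if not (0 < self.working_range[0] < self.working_range[1]):
            raise ValueError("working range must be an increasing positive pair")

    @property
    def forward(self) -> np.ndarray:
        return self.pose.rotation[:, 2]

    def ray_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """World-frame ray origins and unit directions, one per grid sample."""
        rows, cols = self.grid
        tan_x = (self.reference_fov[0] / 2.0) / self.reference_standoff
        tan_y = (self.reference_fov[1] / 2.0) / self.reference_standoff
        xs = np.linspace(-tan_x, tan_x, cols)
        ys = np.linspace(-tan_y, tan_y, rows)
        gx, gy = np.meshgrid(xs, ys)
        dirs_cam = np.column_stack([gx.ravel(), gy.ravel(), np.ones(gx.size)])
        dirs_cam /= np.linalg.norm(dirs_cam, axis=1, keepdims=True)
        dirs = self.pose.apply_vectors(dirs_cam)
        origins = np.broadcast_to(self.pose.translation, dirs.shape).copy()
        return origins, dirs


@dataclass(frozen=True)
class NoiseConfig:
    """Depth-noise model; the hardware's noise figure is not published, so
    the magnitude is a configurable simulation choice (default 0.1 mm)."""

    depth_sigma: float = 0.1  # mm, Gaussian along the viewing ray
    outlier_fraction: float = 0.0
    outlier_box: float = 400.0  # mm edge length, centred on the scan
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_sigma < 0:
            raise ValueError("depth_sigma must be non-negative")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1]")


@dataclass
class ScanResult:
    cloud: PointCloud
    noise: NoiseConfig
    camera: CameraModel
    empty: bool = False  # warning flag: nothing in the frustum


@dataclass(frozen=True)
class AnalyticCylinder:
    """Exact cylinder scan target (machined instruments are true quadrics,
    so sampling a faceted mesh would inject spurious facet-sag error)."""

    center: np.ndarray
    direction: np.ndarray
    radius: float
    length: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        d = d / np.linalg.norm(d)
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("cylinder radius and length must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "direction", d)

    def first_hits(self, origins: np.ndarray, dirs: np.ndarray):
        """Smallest positive ray parameter on the lateral surface, with
        outward normals; misses get t = inf."""
        d_ax = self.direction
        w = origins - self.center
        d_perp = dirs - np.outer(dirs @ d_ax, d_ax)
        w_perp = w - np.outer(w @ d_ax, d_ax)
        a = np.einsum("ij,ij->i", d_perp, d_perp)
        b = 2.0 * np.einsum("ij,ij->i", d_perp, w_perp)
        c = np.einsum("ij,ij->i", w_perp, w_perp) - self.radius ** 2
        disc = b * b - 4.0 * a * c
        t = np.full(len(origins), np.inf)
        ok = (disc >= 0.0) & (a > 1e-15)
        sq = np.sqrt(np.maximum(disc, 0.0))
        for root_sign in (-1.0, 1.0):  # near root first, far as fallback
            tr = np.where(ok, (-b + root_sign * sq) / np.where(ok, 2.0 * a, 1.0),
                          np.inf)
            tr_safe = np.where(np.isfinite(tr), tr, 0.0)
            axial = (origins + tr_safe[:, None] * dirs - self.center) @ d_ax
            valid = ok & np.isfinite(tr) & (tr > 1e-9) \
                & (np.abs(axial) <= self.length / 2.0)
            t = np.where(valid & (tr < t), tr, t)
        t_safe = np.where(np.isfinite(t), t, 0.0)
        pts = origins + t_safe[:, None] * dirs
        rel = pts - self.center
        radial = rel - np.outer(rel @ d_ax, d_ax)
        norm = np.linalg.norm(radial, axis=1)
        normals = radial / np.where(norm[:, None] > 0, norm[:, None], 1.0)
        return t, normals


def _pinhole_first_hits(origin: np.ndarray, dirs: np.ndarray, grid: tuple,
                        tri: np.ndarray, tile: int = 24):
    """First-hit casting for a shared-origin ray grid with cone culling.

    The grid is split into tiles; for each tile only triangles whose
    vertices fall inside the tile's bounding cone (with an angular margin
    larger than any triangle's angular size) are tested, which keeps the
    ray x triangle product small.
    """
    rows, cols = grid
    n = len(dirs)
    t_out = np.full(n, np.inf)
    idx_out = np.full(n, -1, dtype=int)
    verts = tri.reshape(-1, 3)
    rel = verts - origin
    dist = np.linalg.norm(rel, axis=1)
    if np.any(dist < 1e-9):  # origin touches geometry; fall back
        t, i, h = first_hits(origin[None, :].repeat(n, 0), dirs, tri)
        return t, i, h
    unit = rel / dist[:, None]
    # conservative angular margin: largest triangle edge at the closest range
    edges = np.linalg.norm(np.roll(tri, -1, axis=1) - tri, axis=2).max()
    margin = np.arctan2(edges, max(dist.min(), 1e-6))
    idx_grid = np.arange(n).reshape(rows, cols)
    for r0 in range(0, rows, tile):
        for c0 in range(0, cols, tile):
            sel = idx_grid[r0:r0 + tile, c0:c0 + tile].ravel()
            d = dirs[sel]
            m = d.mean(axis=0)
            m /= np.linalg.norm(m)
            cos_tile = float((d @ m).min())
            theta = np.arccos(np.clip(cos_tile, -1.0, 1.0)) + margin
            keep = (unit @ m) >= np.cos(min(theta, np.pi))
            face_keep = np.unique(np.nonzero(keep)[0] // 3)
            if len(face_keep) == 0:
                continue
            sub = tri[face_keep]
            t, i, h = first_hits(np.broadcast_to(origin, d.shape), d, sub)
            t_out[sel] = t
            idx_out[sel] = np.where(h, face_keep[np.where(i >= 0, i, 0)], -1)
    return t_out, idx_out, idx_out >= 0


def simulate_scan(meshes, camera: CameraModel,
                  noise: Optional[NoiseConfig] = None) -> ScanResult:
    """Scan named meshes: first-hit visibility, incidence cutoff, depth noise.

    ``meshes`` is a sequence of ``(name, trimesh.Trimesh)`` pairs (or a
    dict).  Each returned point carries the name of the mesh it was seen
    on.  Deterministic given ``noise.seed``.
    """
    noise = noise or NoiseConfig(depth_sigma=0.0)
    if isinstance(meshes, dict):
        meshes = list(meshes.items())
    if not meshes:
        raise ValueError("no meshes to scan")
    mesh_items, quad_items = [], []
    for name, obj in meshes:
        (quad_items if isinstance(obj, AnalyticCylinder) else mesh_items).append(
            (str(name), obj))

    origins, dirs = camera.ray_grid()
    n_rays = len(dirs)
    t = np.full(n_rays, np.inf)
    hit_normal = np.zeros((n_rays, 3))
    hit_owner = np.full(n_rays, -1, dtype=int)
    names = []

    if mesh_items:
        tris, face_owner, face_normals = [], [], []
        for name, mesh in mesh_items:
            mi = len(names)
            names.append(name)
            tris.append(np.asarray(mesh.triangles, dtype=float))
            face_owner.append(np.full(len(mesh.faces), mi, dtype=int))
            face_normals.append(np.asarray(mesh.face_normals, dtype=float))
        tri = np.vstack(tris)
        owner = np.concatenate(face_owner)
        normals = np.vstack(face_normals)
        tm, tri_idx, hit = _pinhole_first_hits(camera.pose.translation, dirs,
                                               camera.grid, tri)
        better = hit & (tm < t)
        t[better] = tm[better]
        hit_normal[better] = normals[tri_idx[better]]
        hit_owner[better] = owner[tri_idx[better]]

    for name, cyl in quad_items:
        mi = len(names)
        names.append(name)
        tc, nc = cyl.first_hits(origins, dirs)
        better = np.isfinite(tc) & (tc < t)
        t[better] = tc[better]
        hit_normal[better] = nc[better]
        hit_owner[better] = mi

    # working range and grazing-incidence cutoffs
    lo, hi = camera.working_range
    keep = (hit_owner >= 0) & (t >= lo) & (t <= hi)
    cos_cut = np.cos(np.radians(camera.max_incidence_deg))
    cos_inc = -np.einsum("ij,ij->i", dirs, hit_normal)
    keep &= cos_inc >= cos_cut

    if not np.any(keep):
        empty_cloud = PointCloud(np.zeros((0, 3)), labels=np.asarray([], dtype=object))
        return ScanResult(cloud=empty_cloud, noise=noise, camera=camera, empty=True)

    rng = np.random.default_rng(np.random.SeedSequence((abs(noise.seed), 0)))
    depth = t[keep]
    if noise.depth_sigma > 0:
        depth = depth + rng.normal(0.0, noise.depth_sigma, size=depth.shape)
    points = origins[keep] + depth[:, None] * dirs[keep]
    labels = np.asarray([names[i] for i in hit_owner[keep]], dtype=object)
    return ScanResult(cloud=PointCloud(points, labels=labels),
                      noise=noise, camera=camera, empty=False)


def add_outliers(scan: ScanResult) -> ScanResult:
    """Append ``floor(fraction * N)`` uniform box outliers labelled 'outlier'."""
    frac = scan.noise.outlier_fraction
    n = len(scan.cloud)
    n_out = int(np.floor(frac * n))
    if n_out == 0:
        return scan
    rng = np.random.default_rng(np.random.SeedSequence((abs(scan.noise.seed), 1)))
    center = scan.cloud.points.mean(axis=0)
    half = scan.noise.outlier_box / 2.0
    extra = rng.uniform(center - half, center + half, size=(n_out, 3))
    points = np.vstack([scan.cloud.points, extra])
    labels = scan.cloud.labels if scan.cloud.labels is not None \
        else np.asarray(["scan"] * n, dtype=object)
    labels = np.concatenate([labels, np.asarray(["outlier"] * n_out, dtype=object)])
    return ScanResult(cloud=PointCloud(points, labels=labels),
                      noise=scan.noise, camera=scan.camera, empty=scan.empty)
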