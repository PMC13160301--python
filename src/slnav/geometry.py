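"""Rigid-body math, point-cloud containers and triangle-mesh queries.

All coordinates are in millimetres, in a right-handed frame.  Two frames
are used throughout the toolkit: ``image`` (the frame of the preoperative
meshes) and ``world`` (the camera frame of the simulated structured-light
scanner); a :class:`RigidTransform` maps between them.  Angles returned to
callers are in degrees; radians are used internally.

Ray--triangle intersection and point--triangle distance are implemented
here as vectorised NumPy kernels (Möller--Trumbore and plane-projection /
edge-clamping respectively) and back every visibility, entry/exit and
registration-accuracy computation in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "PointCloud",
    "Ray",
    "compose",
    "angle_between_lines",
    "ray_mesh_intersections",
    "point_mesh_distances",
    "interior_signed_distance",
    "points_in_mesh",
]

_ORTHO_TOL = 1e-9


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (N, 3) coordinates, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid map (rotation + translation, mm).

    The rotation block must be orthonormal with determinant +1 (tolerance
    1e-9) and the bottom row exactly ``[0, 0, 0, 1]``; anything else is
    rejected at construction.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"rigid transform must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("rigid transform contains non-finite entries")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("bottom row must be exactly [0, 0, 0, 1]")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block must have determinant +1 (no reflection)")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), translation)

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Axis-angle construction; the rotation vector magnitude is degrees."""
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls.from_rotation_translation(rot.as_matrix(), translation)

    @classmethod
    def random(cls, rng: np.random.Generator, max_angle_deg: float = 180.0,
               max_translation: float = 100.0) -> "RigidTransform":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-max_angle_deg, max_angle_deg)
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls.from_rotvec_deg(axis * angle, t)

    # -- accessors -------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra ---------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def invert(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return pts @ self.rotation.T + self.translation

    def apply_vectors(self, vectors) -> np.ndarray:
        return _as_points(vectors) @ self.rotation.T

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec())))

    # -- serialisation ---------------------------------------------------
    def to_list(self) -> list:
        """Row-major 16-float list (JSON interchange form)."""
        return [float(v) for v in self.matrix.ravel()]

    @classmethod
    def from_list(cls, values: Sequence[float]) -> "RigidTransform":
        vals = np.asarray(values, dtype=float)
        if vals.size != 16:
            raise ValueError("rigid transform JSON form must hold 16 floats")
        return cls(vals.reshape(4, 4))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform applying ``b`` first, then ``a``."""
    return a @ b


@dataclass
class PointCloud:
    """N x 3 point set in mm with optional per-point labels and unit normals."""

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (len(self.points),):
                raise ValueError("labels must be one string per point")
        if self.normals is not None:
            self.normals = _as_points(self.normals)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points in shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length within 1e-6")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, t: RigidTransform) -> "PointCloud":
        """Rigidly moved copy; labels carried over, normals rotated only."""
        normals = None if self.normals is None else t.apply_vectors(self.normals)
        labels = None if self.labels is None else self.labels.copy()
        return PointCloud(t.apply(self.points), labels=labels, normals=normals)

    def select(self, mask) -> "PointCloud":
        mask = np.asarray(mask)
        return PointCloud(
            self.points[mask],
            labels=None if self.labels is None else self.labels[mask],
            normals=None if self.normals is None else self.normals[mask],
        )


@dataclass(frozen=True)
class Ray:
    """Half-line with unit direction (|d| = 1 within 1e-9)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length within 1e-9")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


def angle_between_lines(u, v) -> float:
    """Undirected angle between two line directions, degrees in [0, 90].

    Direction sign is arbitrary for a line (a wire can be parametrised from
    either end), so the dot product is folded by its absolute value.
    """
    u = np.asarray(u, dtype=float).reshape(3)
    v = np.asarray(v, dtype=float).reshape(3)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero vector has no direction")
    c = np.clip(abs(float(u @ v)) / (nu * nv), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# ---------------------------------------------------------------------------
# Ray casting (Möller–Trumbore, vectorised)
# ---------------------------------------------------------------------------

_EPS_PARALLEL = 1e-12
_EPS_T = 1e-9


def _triangles_of(mesh) -> np.ndarray:
    tri = np.asarray(mesh.triangles, dtype=float) if hasattr(mesh, "triangles") \
        else np.asarray(mesh, dtype=float)
    if tri.ndim != 3 or tri.shape[1:] != (3, 3):
        raise ValueError("mesh must provide (F, 3, 3) triangles")
    if len(tri) == 0:
        raise ValueError("mesh has no triangles")
    return tri


def ray_mesh_intersections(ray: Ray, mesh) -> list[tuple[np.ndarray, float]]:
    """All intersections of a ray with a triangle mesh.

    Returns ``[(hit_point, t), ...]`` sorted by increasing ray parameter
    ``t`` (>= 0).  Duplicate hits on shared edges are merged.  Empty list
    when the ray misses.
    """
    tri = _triangles_of(mesh)
    t, u, v, valid = _moller_trumbore(ray.origin[None, :], ray.direction[None, :], tri)
    ts = np.sort(t[0][valid[0]])
    out: list[tuple[np.ndarray, float]] = []
    for tv in ts:
        if out and abs(tv - out[-1][1]) < 1e-9:
            continue  # shared-edge duplicate
        out.append((ray.origin + tv * ray.direction, float(tv)))
    return out


def _moller_trumbore(origins: np.ndarray, dirs: np.ndarray, tri: np.ndarray):
    """Batched ray x triangle intersection.

    origins, dirs: (R, 3); tri: (F, 3, 3).  Returns (t, u, v, valid) each of
    shape (R, F).  Memory is O(R * F); callers chunk over rays.
    """
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0  # (F, 3)
    e2 = v2 - v0
    # pvec: (R, F, 3)
    pvec = np.cross(dirs[:, None, :], e2[None, :, :])
    det = np.einsum("fk,rfk->rf", e1, pvec)
    near_parallel = np.abs(det) < _EPS_PARALLEL
    det_safe = np.where(near_parallel, 1.0, det)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rfk,rfk->rf", tvec, pvec) / det_safe
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rk,rfk->rf", dirs, qvec) / det_safe
    t = np.einsum("fk,rfk->rf", e2, qvec) / det_safe
    valid = (
        ~near_parallel
        & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12)
        & (t >= _EPS_T)
    )
    return t, u, v, valid


def first_hits(origins, dirs, tri, chunk: int = 512):
    """First intersection per ray against a triangle soup.

    Returns ``(t, tri_index, hit_mask)`` arrays of length R.  Rays that miss
    get ``t = inf`` and ``tri_index = -1``.
    """
    origins = _as_points(origins)
    dirs = _as_points(dirs)
    tri = _triangles_of(tri)
    n = len(origins)
    t_out = np.full(n, np.inf)
    idx_out = np.full(n, -1, dtype=int)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        t, _, _, valid = _moller_trumbore(origins[sl], dirs[sl], tri)
        t = np.where(valid, t, np.inf)
        best = np.argmin(t, axis=1)
        rows = np.arange(t.shape[0])
        tbest = t[rows, best]
        hit = np.isfinite(tbest)
        t_out[sl] = tbest
        idx_out[sl] = np.where(hit, best, -1)
    return t_out, idx_out, idx_out >= 0


# ---------------------------------------------------------------------------
# Point–triangle distance (exact, vectorised)
# ---------------------------------------------------------------------------

def _point_segment_sq(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Squared distance and foot point from points (R,F,3) to segments a->b (F,3)."""
    ab = b - a  # (F, 3)
    ap = points - a[None, :, :]
    denom = np.einsum("fk,fk->f", ab, ab)
    denom = np.where(denom == 0.0, 1.0, denom)
    s = np.clip(np.einsum("rfk,fk->rf", ap, ab) / denom, 0.0, 1.0)
    foot = a[None, :, :] + s[..., None] * ab[None, :, :]
    d2 = np.einsum("rfk,rfk->rf", points - foot, points - foot)
    return d2, foot


def _point_triangle_sq(points: np.ndarray, tri: np.ndarray):
    """Squared distance and closest point, points (R,3) x triangles (F,3,3).

    Projects onto the triangle plane; interior projections are exact feet,
    otherwise the minimum over the three edge segments is taken.
    """
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    n = np.cross(e1, e2)
    nn = np.einsum("fk,fk->f", n, n)
    nn = np.where(nn == 0.0, 1.0, nn)
    p = points[:, None, :]  # (R, 1, 3)
    w = p - v0[None, :, :]
    dist_plane = np.einsum("rfk,fk->rf", w, n) / np.sqrt(nn)
    proj = p - dist_plane[..., None] * (n / np.sqrt(nn)[:, None])[None, :, :]
    # barycentric test of the projection
    d00 = np.einsum("fk,fk->f", e1, e1)
    d01 = np.einsum("fk,fk->f", e1, e2)
    d11 = np.einsum("fk,fk->f", e2, e2)
    wp = proj - v0[None, :, :]
    d20 = np.einsum("rfk,fk->rf", wp, e1)
    d21 = np.einsum("rfk,fk->rf", wp, e2)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    bv = (d11 * d20 - d01 * d21) / denom
    bw = (d00 * d21 - d01 * d20) / denom
    inside = (bv >= 0.0) & (bw >= 0.0) & (bv + bw <= 1.0)

    d2_in = dist_plane ** 2
    d2a, fa = _point_segment_sq(p, v0, v1)
    d2b, fb = _point_segment_sq(p, v1, v2)
    d2c, fc = _point_segment_sq(p, v2, v0)
    d2_edge = np.minimum(np.minimum(d2a, d2b), d2c)
    pick_b = (d2b <= d2a) & (d2b <= d2c)
    pick_c = (d2c < d2a) & (d2c < d2b) & ~pick_b
    foot_edge = np.where(pick_b[..., None], fb, np.where(pick_c[..., None], fc, fa))

    d2 = np.where(inside, d2_in, d2_edge)
    foot = np.where(inside[..., None], proj, foot_edge)
    return d2, foot


def _point_triangle_sq_pairwise(points: np.ndarray, tri: np.ndarray):
    """Squared distance / closest point of point i against triangle i only.

    points: (N, 3); tri: (N, 3, 3).  Same mathematics as
    :func:`_point_triangle_sq` without the all-pairs broadcast.
    """
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    n = np.cross(e1, e2)
    nn = np.einsum("nk,nk->n", n, n)
    nn = np.where(nn == 0.0, 1.0, nn)
    unit_n = n / np.sqrt(nn)[:, None]
    w = points - v0
    dist_plane = np.einsum("nk,nk->n", w, unit_n)
    proj = points - dist_plane[:, None] * unit_n
    d00 = np.einsum("nk,nk->n", e1, e1)
    d01 = np.einsum("nk,nk->n", e1, e2)
    d11 = np.einsum("nk,nk->n", e2, e2)
    wp = proj - v0
    d20 = np.einsum("nk,nk->n", wp, e1)
    d21 = np.einsum("nk,nk->n", wp, e2)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    bv = (d11 * d20 - d01 * d21) / denom
    bw = (d00 * d21 - d01 * d20) / denom
    inside = (bv >= 0.0) & (bw >= 0.0) & (bv + bw <= 1.0)

    def seg(a, b):
        ab = b - a
        ap = points - a
        dd = np.einsum("nk,nk->n", ab, ab)
        dd = np.where(dd == 0.0, 1.0, dd)
        s = np.clip(np.einsum("nk,nk->n", ap, ab) / dd, 0.0, 1.0)
        foot = a + s[:, None] * ab
        return np.einsum("nk,nk->n", points - foot, points - foot), foot

    d2a, fa = seg(v0, v1)
    d2b, fb = seg(v1, v2)
    d2c, fc = seg(v2, v0)
    d2_edge = np.minimum(np.minimum(d2a, d2b), d2c)
    pick_b = (d2b <= d2a) & (d2b <= d2c)
    pick_c = (d2c < d2a) & (d2c < d2b) & ~pick_b
    foot_edge = np.where(pick_b[:, None], fb, np.where(pick_c[:, None], fc, fa))
    d2 = np.where(inside, dist_plane ** 2, d2_edge)
    foot = np.where(inside[:, None], proj, foot_edge)
    return d2, foot


def point_mesh_distances(points, mesh, chunk: int = 2048):
    """Unsigned distance from each point to the nearest triangle of a mesh.

    Exact (exhaustive over triangles, vectorised and chunked).  Returns
    ``(distances, closest_points, triangle_index)``.
    """
    pts = _as_points(points)
    tri = _triangles_of(mesh)
    n = len(pts)
    dists = np.empty(n)
    closest = np.empty((n, 3))
    tidx = np.empty(n, dtype=int)
    # chunk so that R_chunk * F stays bounded
    rows = max(1, min(chunk, int(4e6 / max(len(tri), 1))))
    for start in range(0, n, rows):
        sl = slice(start, min(start + rows, n))
        d2, foot = _point_triangle_sq(pts[sl], tri)
        best = np.argmin(d2, axis=1)
        rr = np.arange(d2.shape[0])
        dists[sl] = np.sqrt(d2[rr, best])
        closest[sl] = foot[rr, best]
        tidx[sl] = best
    return dists, closest, tidx


_PARITY_DIR = np.array([0.2938736, 0.5432112, 0.7890121])
_PARITY_DIR = _PARITY_DIR / np.linalg.norm(_PARITY_DIR)


def points_in_mesh(points, mesh) -> np.ndarray:
    """Crossing-parity containment test for a watertight mesh."""
    pts = _as_points(points)
    tri = _triangles_of(mesh)
    inside = np.zeros(len(pts), dtype=bool)
    dirs = np.broadcast_to(_PARITY_DIR, pts.shape)
    for start in range(0, len(pts), 512):
        sl = slice(start, min(start + 512, len(pts)))
        t, _, _, valid = _moller_trumbore(pts[sl], dirs[sl], tri)
        inside[sl] = (valid.sum(axis=1) % 2) == 1
    return inside


def interior_signed_distance(points, mesh) -> np.ndarray:
    """Distance to the mesh surface, positive inside, negative outside."""
    d, _, _ = point_mesh_distances(points, mesh)
    sign = np.where(points_in_mesh(points, mesh), 1.0, -1.0)
    return sign * d
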