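"""Channel planning, drill-sleeve cylinder tracking, and guidance.

A planned trajectory is a :class:`Channel`: a cylinder of given radius and
length along an axis (the preoperative design uses 1 mm x 300 mm channels;
the intraoperative navigation channel derived from the tracked sleeve is
1 mm radius x 800 mm).  The drill sleeve is tracked by fitting a cylinder
of known radius (12.5 mm) to a partial structured-light scan of its
surface: RANSAC over two-point-plus-normal axis hypotheses, followed by
nonlinear least-squares refinement of the 4-DOF axis with the radius held
fixed.  Knowing the radius is what makes fits on narrow visible arcs
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform, angle_between_lines

__all__ = [
    "Channel",
    "NavigationalMap",
    "CylinderFitParams",
    "CylinderFitResult",
    "add_channel",
    "fit_cylinder",
    "channel_from_fit",
    "guidance_offset",
    "simulate_alignment",
]


@dataclass(frozen=True)
class Channel:
    """Cylindrical trajectory: entry-end axis point, unit direction, mm."""

    origin: np.ndarray
    direction: np.ndarray
    radius: float = 1.0
    length: float = 300.0
    label: str = ""
    frame: str = "image"

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("channel direction must be nonzero")
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("channel radius and length must be positive")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    @property
    def tip(self) -> np.ndarray:
        return self.origin + self.length * self.direction

    def transformed(self, t: RigidTransform, frame: Optional[str] = None) -> "Channel":
        return replace(self, origin=t.apply(self.origin)[0],
                       direction=t.apply_vectors(self.direction)[0],
                       frame=self.frame if frame is None else frame)

    def to_dict(self) -> dict:
        return {
            "origin": [float(v) for v in self.origin],
            "direction": [float(v) for v in self.direction],
            "radius": float(self.radius),
            "length": float(self.length),
            "label": self.label,
            "frame": self.frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Channel":
        return cls(origin=d["origin"], direction=d["direction"], radius=d["radius"],
                   length=d["length"], label=d.get("label", ""),
                   frame=d.get("frame", "image"))


@dataclass
class NavigationalMap:
    """Preoperative bundle moved as one rigid body: skin + bones + channels."""

    skin: object  # trimesh.Trimesh
    bones: list
    channels: list
    frame: str = "image"

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch.frame != self.frame:
                raise ValueError(
                    f"channel '{ch.label}' frame {ch.frame!r} does not match "
                    f"map frame {self.frame!r}")


def add_channel(nav_map: NavigationalMap, pose: RigidTransform,
                radius: float = 1.0, length: float = 300.0,
                label: str = "") -> NavigationalMap:
    """Append a planned channel whose axis is the z-axis of ``pose``.

    The default dimensions are the preoperative design cylinder: radius
    1 mm, height 300 mm.  Cloning an existing channel at a new pose is the
    same call with the new pose.
    """
    if nav_map.frame != "image":
        raise ValueError("channels are planned on the image-frame map")
    channel = Channel(origin=pose.translation, direction=pose.rotation[:, 2],
                      radius=radius, length=length, label=label, frame=nav_map.frame)
    return NavigationalMap(skin=nav_map.skin, bones=list(nav_map.bones),
                           channels=list(nav_map.channels) + [channel],
                           frame=nav_map.frame)


# ---------------------------------------------------------------------------
# Cylinder fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderFitParams:
    seed: int = 0
    n_iterations: int = 200
    inlier_threshold: float = 0.3  # mm
    min_points: int = 50
    min_arc_deg: float = 90.0
    normals_k: int = 12
    fixed_radius: bool = True


@dataclass
class CylinderFitResult:
    success: bool
    axis_point: Optional[np.ndarray] = None
    axis_direction: Optional[np.ndarray] = None
    radius: float = 12.5
    inlier_rms: float = np.nan
    inlier_count: int = 0
    arc_coverage_deg: float = 0.0
    reason: str = ""


def _estimate_normals(points: np.ndarray, k: int) -> np.ndarray:
    """Unoriented surface normals from local PCA over k nearest neighbours."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k, len(points)))
    neigh = points[idx]  # (N, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, :, 0]  # smallest-eigenvalue direction


def _radial_residuals(points: np.ndarray, axis_point: np.ndarray,
                      direction: np.ndarray, radius: float) -> np.ndarray:
    rel = points - axis_point
    along = rel @ direction
    radial = rel - np.outer(along, direction)
    return np.linalg.norm(radial, axis=1) - radius


def _arc_coverage(points: np.ndarray, axis_point: np.ndarray,
                  direction: np.ndarray, bin_deg: float = 5.0) -> float:
    rel = points - axis_point
    rel = rel - np.outer(rel @ direction, direction)
    # orthonormal basis of the cross-sectional plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    ang = np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0
    bins = np.unique((ang // bin_deg).astype(int))
    return float(len(bins) * bin_deg)


def fit_cylinder(cloud: PointCloud, fixed_radius: float = 12.5,
                 params: Optional[CylinderFitParams] = None) -> CylinderFitResult:
    """Fit a known-radius cylinder to a partial surface scan.

    RANSAC: two sampled points with estimated normals give an axis
    hypothesis (direction = cross of the normals; axis point = surface
    point pushed one radius inward, both normal signs tried).  The best
    hypothesis by inlier count is refined with least squares on the radial
    residuals over the inliers, radius held at ``fixed_radius`` (or freed
    when ``params.fixed_radius`` is False).  Insufficient points or angular
    coverage below ``min_arc_deg`` yields ``success=False``, not an
    exception — occlusions are an expected operating condition.
    """
    params = params or CylinderFitParams()
    pts = cloud.points
    if len(pts) < params.min_points:
        return CylinderFitResult(False, radius=fixed_radius,
                                 reason=f"only {len(pts)} points "
                                        f"(need {params.min_points})")
    normals = cloud.normals if cloud.normals is not None \
        else _estimate_normals(pts, params.normals_k)

    rng = np.random.default_rng(params.seed)
    best = None  # (count, axis_point, direction)
    for _ in range(params.n_iterations):
        i, j = rng.choice(len(pts), size=2, replace=False)
        d = np.cross(normals[i], normals[j])
        nd = np.linalg.norm(d)
        if nd < 1e-6:
            continue
        d = d / nd
        for sign in (1.0, -1.0):
            a = pts[i] + sign * fixed_radius * normals[i]
            res = _radial_residuals(pts, a, d, fixed_radius)
            count = int(np.sum(np.abs(res) < params.inlier_threshold))
            if best is None or count > best[0]:
                best = (count, a, d)
    if best is None or best[0] < params.min_points:
        return CylinderFitResult(False, radius=fixed_radius,
                                 reason="no consensus axis hypothesis")

    _, axis_point, direction = best
    for _ in range(2):  # refine, re-select inliers, refine again
        res = _radial_residuals(pts, axis_point, direction, fixed_radius)
        inlier = np.abs(res) < params.inlier_threshold
        if inlier.sum() < params.min_points:
            return CylinderFitResult(False, radius=fixed_radius,
                                     reason="consensus set too small")
        axis_point, direction, radius = _refine_axis(
            pts[inlier], axis_point, direction, fixed_radius, params.fixed_radius)

    res = _radial_residuals(pts, axis_point, direction, radius)
    inlier = np.abs(res) < params.inlier_threshold
    coverage = _arc_coverage(pts[inlier], axis_point, direction)
    if coverage < params.min_arc_deg:
        return CylinderFitResult(False, radius=radius, arc_coverage_deg=coverage,
                                 inlier_count=int(inlier.sum()),
                                 reason=f"arc coverage {coverage:.0f} deg below "
                                        f"{params.min_arc_deg:.0f} deg")
    rms = float(np.sqrt(np.mean(res[inlier] ** 2)))
    # canonical axis point: projection of the inlier centroid onto the axis
    centroid = pts[inlier].mean(axis=0)
    axis_point = axis_point + ((centroid - axis_point) @ direction) * direction
    return CylinderFitResult(True, axis_point=axis_point, axis_direction=direction,
                             radius=float(radius), inlier_rms=rms,
                             inlier_count=int(inlier.sum()),
                             arc_coverage_deg=coverage)


def _refine_axis(points: np.ndarray, axis_point: np.ndarray, direction: np.ndarray,
                 radius: float, fixed_radius: bool):
    """Least-squares refinement of the cylinder axis on radial residuals."""
    centroid = points.mean(axis=0)
    # gauge: axis point constrained to the plane through the centroid
    # orthogonal to the current direction; direction in spherical angles.
    theta0 = np.arccos(np.clip(direction[2], -1.0, 1.0))
    phi0 = np.arctan2(direction[1], direction[0])
    a0 = axis_point + ((centroid - axis_point) @ direction) * direction

    def unpack(x):
        theta, phi = x[0], x[1]
        d = np.array([np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        a = centroid + x[2] * e1 + x[3] * e2
        r = x[4] if len(x) > 4 else radius
        return a, d, r

    def residuals(x):
        a, d, r = unpack(x)
        return _radial_residuals(points, a, d, r)

    off = a0 - centroid
    x0 = [theta0, phi0, 0.0, 0.0]
    # express current offset in the initial basis
    a_init, d_init, _ = unpack(np.array([theta0, phi0, 0.0, 0.0]))
    ref = np.array([1.0, 0.0, 0.0]) if abs(d_init[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d_init, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d_init, e1)
    x0[2], x0[3] = float(off @ e1), float(off @ e2)
    if not fixed_radius:
        x0.append(radius)
    sol = least_squares(residuals, np.asarray(x0), method="lm", xtol=1e-14, ftol=1e-14)
    a, d, r = unpack(sol.x)
    return a, d, float(r)


def channel_from_fit(fit: CylinderFitResult, diameter: float = 2.0,
                     length: float = 800.0,
                     camera_forward=None) -> Channel:
    """Navigation channel coaxial with the fitted sleeve axis.

    Defaults follow the intraoperative settings: 2 mm diameter, 800 mm
    length.  The direction is oriented tip-ward (away from the camera,
    i.e. positive dot product with the camera's forward axis) when a
    camera forward direction is supplied.
    """
    if not fit.success:
        raise ValueError(f"cannot build a channel from a failed fit: {fit.reason}")
    d = np.asarray(fit.axis_direction, dtype=float)
    if camera_forward is not None:
        fwd = np.asarray(camera_forward, dtype=float)
        if float(d @ fwd) < 0:
            d = -d
    origin = np.asarray(fit.axis_point, dtype=float) - (length / 2.0) * d
    return Channel(origin=origin, direction=d, radius=diameter / 2.0,
                   length=length, label="navigation", frame="world")


# ---------------------------------------------------------------------------
# Guidance
# ---------------------------------------------------------------------------

def guidance_offset(planned: Channel, current: Channel) -> tuple[float, float]:
    """(entry translation mm, angle deg) needed to bring ``current`` onto plan.

    Entry translation is the perpendicular distance from the planned entry
    point to the current axis line; the angle is the undirected angle
    between the two axis directions.
    """
    if planned.frame != current.frame:
        raise ValueError(
            f"channels are in different frames: {planned.frame!r} vs {current.frame!r}")
    rel = planned.origin - current.origin
    along = float(rel @ current.direction)
    perp = rel - along * current.direction
    return float(np.linalg.norm(perp)), angle_between_lines(planned.direction,
                                                            current.direction)


def simulate_alignment(planned: Channel, start: Channel,
                       tolerance_mm: float = 1e-6, tolerance_deg: float = 1e-6,
                       gain: float = 0.7, max_iterations: int = 200):
    """In-silico stand-in for the manual gimbal/rod adjustment.

    Each iteration applies a fraction ``gain`` of the exact rotational and
    translational correction, emulating incremental manual adjustment, and
    stops once both guidance offsets are within tolerance.  Returns the
    aligned channel and the iteration trace of (translation, angle) pairs.
    """
    if tolerance_mm <= 0 or tolerance_deg <= 0:
        raise ValueError("tolerances must be positive")
    current = start
    trace = []
    for _ in range(max_iterations):
        t_off, a_off = guidance_offset(planned, current)
        if t_off <= tolerance_mm and a_off <= tolerance_deg:
            break
        trace.append((t_off, a_off))
        # rotate current direction toward the planned direction
        d_cur, d_pl = current.direction, planned.direction
        if float(d_cur @ d_pl) < 0:
            d_pl = -d_pl
        axis = np.cross(d_cur, d_pl)
        sin_a = np.linalg.norm(axis)
        if sin_a > 1e-15:
            angle = np.arcsin(np.clip(sin_a, -1.0, 1.0)) * gain
            rot = RigidTransform.from_rotvec_deg(axis / sin_a * np.degrees(angle))
            d_new = rot.apply_vectors(d_cur)[0]
        else:
            d_new = d_pl
        # translate so the planned entry approaches the current axis
        rel = planned.origin - current.origin
        perp = rel - (rel @ d_new) * d_new
        origin_new = current.origin + gain * perp
        current = replace(current, origin=origin_new, direction=d_new)
    return current, trace
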