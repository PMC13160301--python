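"""Seeded synthetic phantom: vertebrae, pedicle corridors, skin, drill sleeve.

The phantom stands in for a rigid multi-vertebra specimen wrapped in a
soft-tissue layer.  Geometry is deliberately parametric rather than
anatomical: each vertebra is an extruded cross-section (elliptical body
plus a rectangular posterior element) and each pedicle corridor is a
straight circular cylinder fully interior to its bone, so containment,
entry/exit points and breach depths all have closed forms that tests can
check analytically.

Default dimensions emulate a large (bovine-scale) cervical specimen: body
half-axes 18 x 14 x 11 mm, corridor radius 3 mm, and a 20 mm soft-tissue
offset between bone and skin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import trimesh
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

from .geometry import RigidTransform
from .tracking import Channel

__all__ = [
    "PhantomSpec",
    "Corridor",
    "PhantomScene",
    "make_vertebra",
    "make_scene",
    "make_drill_sleeve",
]

WIRE_RADIUS = 1.0  # Kirschner wire, 2.0 mm diameter
SLEEVE_RADIUS = 12.5  # drill sleeve, 25 mm outer diameter
SLEEVE_LENGTH = 200.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic specimen.  All lengths in mm."""

    seed: int = 0
    n_vertebrae: int = 7
    body_half_axes: tuple = (18.0, 14.0, 11.0)  # lateral, antero-posterior, half-height
    posterior_width: float = 26.0
    posterior_depth: float = 12.0  # extent of the posterior element beyond the body
    pedicle_corridor_radius: float = 3.0
    pedicle_length: float = 25.0
    cortical_margin: float = 1.5
    corridor_convergence_deg: float = 12.0
    corridor_lateral_offset: float = 5.0
    corridor_center_y: float = 4.0
    skin_offset: float = 20.0  # soft-tissue layer thickness
    inter_vertebra_spacing: float = 4.0
    size_jitter: float = 0.08  # per-vertebra relative size variation
    position_jitter: float = 2.0  # per-vertebra lateral placement variation
    cross_section_segments: int = 12  # quarter-ellipse segments
    skin_sphere_subdivisions: int = 2

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("need at least one vertebra")
        if self.pedicle_corridor_radius <= WIRE_RADIUS:
            raise ValueError(
                f"corridor radius must exceed the {WIRE_RADIUS} mm wire radius")
        if min(self.body_half_axes) <= 0 or self.skin_offset <= 0:
            raise ValueError("all phantom dimensions must be positive")
        if self.pedicle_corridor_radius >= min(self.body_half_axes):
            raise ValueError("corridor radius must be smaller than the vertebral body")


@dataclass(frozen=True)
class Corridor:
    """Straight cylindrical pedicle corridor, fully interior to its bone."""

    vertebra: int
    side: str  # "L" | "R"
    point: np.ndarray  # axis midpoint, mm
    direction: np.ndarray  # unit, posterior -> anterior (insertion direction)
    radius: float
    length: float

    @property
    def label(self) -> str:
        return f"V{self.vertebra + 1}{self.side}"

    def translated(self, offset) -> "Corridor":
        return replace(self, point=self.point + np.asarray(offset, dtype=float))

    def transformed(self, t: RigidTransform) -> "Corridor":
        return replace(self, point=t.apply(self.point)[0],
                       direction=t.apply_vectors(self.direction)[0])


@dataclass
class PhantomScene:
    spec: PhantomSpec
    skin: trimesh.Trimesh
    bones: list
    corridors: list
    truth_trajectories: list
    frame: str = "image"

    def export(self, directory) -> None:
        """Write STL components and a JSON manifest of corridors/channels."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.skin.export(directory / "skin.stl")
        for i, bone in enumerate(self.bones):
            bone.export(directory / f"bone_{i:02d}.stl")
        manifest = {
            "frame": self.frame,
            "n_vertebrae": self.spec.n_vertebrae,
            "seed": self.spec.seed,
            "corridors": [
                {"vertebra": c.vertebra, "side": c.side,
                 "point": list(map(float, c.point)),
                 "direction": list(map(float, c.direction)),
                 "radius": c.radius, "length": c.length}
                for c in self.corridors
            ],
            "channels": [ch.to_dict() for ch in self.truth_trajectories],
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

def _cross_section(spec: PhantomSpec, scale: float) -> Polygon:
    ax, ay, _ = spec.body_half_axes
    ellipse = affinity.scale(
        Point(0, 0).buffer(1.0, quad_segs=spec.cross_section_segments),
        ax * scale, ay * scale)
    tab = box(-spec.posterior_width * scale / 2.0, 0.0,
              spec.posterior_width * scale / 2.0,
              (ay + spec.posterior_depth) * scale)
    poly = unary_union([ellipse, tab])
    if poly.geom_type != "Polygon":
        raise ValueError("vertebra cross-section is not a single polygon")
    return poly


def _extrude_star_polygon(poly: Polygon, half_height: float) -> trimesh.Trimesh:
    """Extrude a polygon star-shaped about the origin into a watertight solid.

    Triangulates caps as fans from the centroid of visibility (the origin),
    which is valid for the body-plus-tab cross-sections built here.
    """
    ring = np.asarray(poly.exterior.coords[:-1], dtype=float)
    # enforce counter-clockwise orientation
    area = np.sum(ring[:, 0] * np.roll(ring[:, 1], -1) - np.roll(ring[:, 0], -1) * ring[:, 1])
    if area < 0:
        ring = ring[::-1]
    n = len(ring)
    bot = np.column_stack([ring, np.full(n, -half_height)])
    top = np.column_stack([ring, np.full(n, half_height)])
    center_bot = np.array([[0.0, 0.0, -half_height]])
    center_top = np.array([[0.0, 0.0, half_height]])
    vertices = np.vstack([bot, top, center_bot, center_top])
    cb, ct = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([cb, j, i])            # bottom cap, normal -z
        faces.append([ct, n + i, n + j])    # top cap, normal +z
        faces.append([i, j, n + j])         # wall
        faces.append([i, n + j, n + i])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    if not mesh.is_watertight:
        raise ValueError("extruded vertebra is not watertight")
    return mesh


def _vertebra_scale(spec: PhantomSpec, index: int) -> float:
    rng = np.random.default_rng(np.random.SeedSequence((abs(spec.seed), index, 0)))
    return 1.0 + spec.size_jitter * rng.uniform(-1.0, 1.0)


def make_vertebra(spec: PhantomSpec, index: int):
    """Build one vertebra mesh and its two pedicle corridors (local frame).

    Deterministic given ``(spec.seed, index)``.  The corridors are validated
    to lie strictly inside the bone with at least ``cortical_margin`` of
    cortex around them; violation raises ``ValueError``.
    """
    if index < 0 or index >= spec.n_vertebrae:
        raise ValueError(f"vertebra index {index} out of range")
    s = _vertebra_scale(spec, index)
    poly = _cross_section(spec, s)
    half_height = spec.body_half_axes[2] * s
    mesh = _extrude_star_polygon(poly, half_height)

    theta = np.radians(spec.corridor_convergence_deg)
    r = spec.pedicle_corridor_radius
    corridors = []
    for side, sign in (("L", -1.0), ("R", 1.0)):
        center = np.array([sign * spec.corridor_lateral_offset * s,
                           spec.corridor_center_y * s, 0.0])
        direction = np.array([-sign * np.sin(theta), -np.cos(theta), 0.0])
        direction /= np.linalg.norm(direction)
        corridor = Corridor(index, side, center, direction, r, spec.pedicle_length * s)
        corridors.append(corridor)
        _validate_corridor(spec, poly, half_height, center, direction, r,
                           corridor.length)
    return mesh, corridors


def _validate_corridor(spec, poly, half_height, center, direction, radius,
                       length) -> None:
    clearance = radius + spec.cortical_margin
    half = length / 2.0
    a = center - half * direction
    b = center + half * direction
    seg = LineString([a[:2], b[:2]])
    core = poly.buffer(-clearance)
    if core.is_empty or not core.covers(seg):
        raise ValueError("pedicle corridor breaches the cortical margin")
    if clearance > half_height:
        raise ValueError("pedicle corridor breaches the endplates")


def make_scene(spec: PhantomSpec) -> PhantomScene:
    """Assemble the full phantom: stacked bones, corridors, skin, trajectories.

    Vertebrae are stacked along +z with the stated spacing; per-vertebra
    size and lateral placement vary with the seed.  The skin is a convex
    offset hull at ``skin_offset`` from the bone compound.  Ground-truth
    trajectories are 1 mm x 300 mm channels coaxial with the corridors.
    """
    if spec.inter_vertebra_spacing <= 0:
        raise ValueError("inter_vertebra_spacing must be positive (bones overlap)")
    bones, corridors, channels = [], [], []
    z = 0.0
    prev_half = None
    for i in range(spec.n_vertebrae):
        mesh, local_corridors = make_vertebra(spec, i)
        s = _vertebra_scale(spec, i)
        half_height = spec.body_half_axes[2] * s
        if prev_half is None:
            z = 0.0
        else:
            z += prev_half + spec.inter_vertebra_spacing + half_height
        prev_half = half_height
        rng = np.random.default_rng(np.random.SeedSequence((abs(spec.seed), i, 1)))
        dx, dy = rng.uniform(-spec.position_jitter, spec.position_jitter, size=2)
        offset = np.array([dx, dy, z])
        mesh = mesh.copy()
        mesh.apply_translation(offset)
        bones.append(mesh)
        for c in local_corridors:
            c = c.translated(offset)
            corridors.append(c)
            channels.append(Channel(
                origin=c.point - 150.0 * c.direction,
                direction=c.direction,
                radius=WIRE_RADIUS,
                length=300.0,
                label=c.label,
                frame="image",
            ))
    skin = _offset_hull(bones, spec.skin_offset, spec.skin_sphere_subdivisions)
    return PhantomScene(spec=spec, skin=skin, bones=bones,
                        corridors=corridors, truth_trajectories=channels)


def _offset_hull(bones, offset: float, subdivisions: int,
                 tessellation_subdivisions: int = 4) -> trimesh.Trimesh:
    """Smooth convex skin: bones' hull dilated outward by ``offset``.

    The dilation is a Minkowski sum with a discretised sphere; the
    resulting hull is then re-tessellated by projecting a fine icosphere
    from the centroid onto the hull surface.  Raw hull triangulations mix
    slivers with very large facets, which makes both scan sampling and
    nearest-triangle queries unreliable; the projected tessellation has
    uniformly well-shaped triangles while keeping every vertex on the
    hull.
    """
    from .geometry import first_hits

    all_vertices = np.vstack([b.vertices for b in bones])
    base = trimesh.convex.convex_hull(all_vertices)
    dirs = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0).vertices
    cloud = (base.vertices[:, None, :] + offset * dirs[None, :, :]).reshape(-1, 3)
    hull = trimesh.convex.convex_hull(cloud)

    ico = trimesh.creation.icosphere(subdivisions=tessellation_subdivisions,
                                     radius=1.0)
    center = hull.vertices.mean(axis=0)
    origins = np.broadcast_to(center, ico.vertices.shape)
    t, _, hit = first_hits(origins, ico.vertices,
                           np.asarray(hull.triangles, dtype=float))
    if not np.all(hit):
        raise ValueError("skin hull projection failed (non-star-shaped hull?)")
    skin = trimesh.Trimesh(vertices=center + t[:, None] * ico.vertices,
                           faces=ico.faces, process=False)
    if not skin.is_watertight:
        raise ValueError("re-tessellated skin is not watertight")
    return skin


def make_drill_sleeve(pose: RigidTransform) -> trimesh.Trimesh:
    """Drill-sleeve outer surface: 25 mm diameter x 200 mm cylinder.

    The cylinder axis runs along the z-axis of ``pose``, centred on the
    pose origin.
    """
    sleeve = trimesh.creation.cylinder(radius=SLEEVE_RADIUS, height=SLEEVE_LENGTH,
                                       sections=64)
    sleeve.apply_transform(pose.matrix)
    return sleeve
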