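"""File I/O: STL meshes, PLY/CSV point clouds, JSON rigid transforms.

STL (binary and ASCII) is the canonical mesh interchange format; PLY
(ASCII, double precision, optional per-point label) is canonical for point
clouds because it preserves provenance labels; CSV ``x,y,z[,label]`` is
accepted for small fixtures.  Rigid transforms travel as JSON row-major
16-float lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .geometry import PointCloud, RigidTransform

__all__ = [
    "MeshIOError",
    "CloudIOError",
    "read_mesh",
    "write_mesh",
    "read_cloud",
    "write_cloud",
    "read_transform",
    "write_transform",
]


class MeshIOError(ValueError):
    pass


class CloudIOError(ValueError):
    pass


def read_mesh(path) -> trimesh.Trimesh:
    """Load a triangle mesh (STL/PLY/OFF...); raises :class:`MeshIOError`."""
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"{path}: no such file")
    try:
        mesh = trimesh.load(path, force="mesh", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise MeshIOError(f"{path}: failed to parse mesh ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshIOError(f"{path}: file contains no triangle geometry")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, ascii_stl: bool = False) -> None:
    """Export a mesh; STL is binary by default, ASCII on request."""
    path = Path(path)
    if ascii_stl and path.suffix.lower() == ".stl":
        mesh.export(path, file_type="stl_ascii")
    else:
        mesh.export(path)


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

def write_cloud(cloud: PointCloud, path) -> None:
    """Write a cloud as ASCII PLY (double precision) or CSV by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_cloud_csv(cloud, path)
    else:
        _write_cloud_ply(cloud, path)


def read_cloud(path) -> PointCloud:
    path = Path(path)
    if not path.exists():
        raise CloudIOError(f"{path}: no such file")
    if path.suffix.lower() == ".csv":
        return _read_cloud_csv(path)
    return _read_cloud_ply(path)


def _write_cloud_csv(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        cols = "x,y,z" + (",label" if cloud.labels is not None else "")
        fh.write(cols + "\n")
        for i, p in enumerate(cloud.points):
            row = f"{p[0]:.9f},{p[1]:.9f},{p[2]:.9f}"
            if cloud.labels is not None:
                row += f",{cloud.labels[i]}"
            fh.write(row + "\n")


def _read_cloud_csv(path: Path) -> PointCloud:
    pts, labels = [], []
    has_labels = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if lineno == 1 and fields[0].lower() in ("x", "# x", "#x"):
                continue
            try:
                xyz = [float(v) for v in fields[:3]]
            except ValueError as exc:
                raise CloudIOError(f"{path}:{lineno}: bad coordinate row ({exc})") from exc
            if len(fields) < 3:
                raise CloudIOError(f"{path}:{lineno}: expected at least x,y,z")
            pts.append(xyz)
            if len(fields) > 3:
                has_labels = True
                labels.append(fields[3])
            else:
                labels.append("")
    points = np.asarray(pts, dtype=float).reshape(-1, 3)
    return PointCloud(points, labels=np.asarray(labels, dtype=object) if has_labels else None)


def _write_cloud_ply(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    has_normals = cloud.normals is not None
    has_labels = cloud.labels is not None
    label_names: list[str] = []
    label_idx = None
    if has_labels:
        label_names = sorted(set(str(v) for v in cloud.labels))
        lut = {name: i for i, name in enumerate(label_names)}
        label_idx = [lut[str(v)] for v in cloud.labels]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        for i, name in enumerate(label_names):
            fh.write(f"comment label {i} {name}\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if has_normals:
            fh.write("property double nx\nproperty double ny\nproperty double nz\n")
        if has_labels:
            fh.write("property int label\n")
        fh.write("end_header\n")
        for i in range(n):
            row = " ".join(f"{v:.9f}" for v in cloud.points[i])
            if has_normals:
                row += " " + " ".join(f"{v:.9f}" for v in cloud.normals[i])
            if has_labels:
                row += f" {label_idx[i]}"
            fh.write(row + "\n")


def _read_cloud_ply(path: Path) -> PointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudIOError(f"{path}:1: not a PLY file")
    n = None
    props: list[str] = []
    label_names: dict[int, str] = {}
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise CloudIOError(f"{path}:{i}: only ASCII PLY is supported")
        elif tok[0] == "comment" and len(tok) >= 4 and tok[1] == "label":
            label_names[int(tok[2])] = " ".join(tok[3:])
        elif tok[0] == "element":
            if tok[1] != "vertex":
                raise CloudIOError(f"{path}:{i}: unsupported element '{tok[1]}'")
            n = int(tok[2])
        elif tok[0] == "property":
            props.append(tok[2])
        elif tok[0] == "end_header":
            body_start = i
            break
    if n is None or body_start is None:
        raise CloudIOError(f"{path}: truncated PLY header")
    for required in ("x", "y", "z"):
        if required not in props:
            raise CloudIOError(f"{path}: PLY header lacks property '{required}'")
    rows = []
    for lineno, line in enumerate(lines[body_start:body_start + n], start=body_start + 1):
        vals = line.split()
        if len(vals) != len(props):
            raise CloudIOError(
                f"{path}:{lineno}: expected {len(props)} values, got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise CloudIOError(f"{path}:{lineno}: bad value ({exc})") from exc
    if len(rows) != n:
        raise CloudIOError(f"{path}: header promises {n} vertices, found {len(rows)}")
    data = np.asarray(rows, dtype=float).reshape(-1, len(props))
    col = {name: j for j, name in enumerate(props)}
    points = data[:, [col["x"], col["y"], col["z"]]] if n else np.zeros((0, 3))
    normals = None
    if all(k in col for k in ("nx", "ny", "nz")) and n:
        normals = data[:, [col["nx"], col["ny"], col["nz"]]]
    labels = None
    if "label" in col and n:
        labels = np.asarray(
            [label_names.get(int(v), str(int(v))) for v in data[:, col["label"]]],
            dtype=object)
    return PointCloud(points, labels=labels, normals=normals)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def write_transform(t: RigidTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": t.to_list()}, fh, indent=1)


def read_transform(path) -> RigidTransform:
    with open(path) as fh:
        data = json.load(fh)
    return RigidTransform.from_list(data["matrix"])
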