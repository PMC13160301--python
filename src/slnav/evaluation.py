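"""Puncture-accuracy analytics.

Entry and exit points are the intersections of a trajectory axis with the
bone surface (dorsal entry, anterior exit).  Per-wire deviations compare
the planned channel with the achieved wire: Euclidean offsets at entry and
exit, the undirected angle between the axes, signed per-axis coordinate
differences (preoperative minus postoperative), and the Neo breach grade
of the wire against its pedicle corridor (grade 0: no perforation;
1: breach < 2 mm; 2: 2--4 mm; 3: > 4 mm).  Summary statistics report
mean +/- sample SD and median (Q1, Q3); paired location differences use a
paired t test when the differences pass Shapiro-Wilk normality and the
Wilcoxon signed-rank test otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .geometry import Ray, angle_between_lines, ray_mesh_intersections
from .phantom import Corridor
from .tracking import Channel

__all__ = [
    "TrajectoryEndpoints",
    "DeviationRecord",
    "SummaryRow",
    "TrajectoryMissError",
    "entry_exit_points",
    "trajectory_deviation",
    "neo_grade",
    "breach_depth",
    "summarize",
    "paired_location_test",
]


class TrajectoryMissError(ValueError):
    """Raised when a trajectory axis does not intersect the bone."""


@dataclass(frozen=True)
class TrajectoryEndpoints:
    entry: np.ndarray
    exit: np.ndarray
    direction: np.ndarray  # unit, entry -> exit

    def __post_init__(self) -> None:
        e = np.asarray(self.entry, dtype=float).reshape(3)
        x = np.asarray(self.exit, dtype=float).reshape(3)
        if np.allclose(e, x):
            raise ValueError("entry and exit points coincide")
        d = np.asarray(self.direction, dtype=float).reshape(3)
        d = d / np.linalg.norm(d)
        if float(d @ (x - e)) <= 0:
            raise ValueError("direction is inconsistent with exit - entry")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "exit", x)
        object.__setattr__(self, "direction", d)


@dataclass
class DeviationRecord:
    entry_offset: float
    exit_offset: float
    angle_offset: float
    entry_dxyz: np.ndarray  # planned - achieved
    exit_dxyz: np.ndarray
    neo_grade: Optional[int] = None
    label: str = ""


@dataclass(frozen=True)
class SummaryRow:
    metric: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


def entry_exit_points(channel: Channel, bone) -> TrajectoryEndpoints:
    """First and last axis-mesh intersections within the channel length.

    Entry is the first crossing along the insertion direction; exit the
    last within the channel's length (anterior cortex penetration).  A
    miss raises :class:`TrajectoryMissError` reporting the nearest
    approach of the axis to the bone.
    """
    ray = Ray(channel.origin, channel.direction)
    hits = [(p, t) for p, t in ray_mesh_intersections(ray, bone)
            if t <= channel.length]
    if len(hits) < 2:
        verts = np.asarray(bone.vertices, dtype=float)
        rel = verts - channel.origin
        along = np.clip(rel @ channel.direction, 0.0, channel.length)
        nearest = float(np.min(np.linalg.norm(
            rel - along[:, None] * channel.direction, axis=1)))
        raise TrajectoryMissError(
            f"channel '{channel.label}' does not traverse the bone "
            f"(nearest axis-to-surface approach {nearest:.3f} mm)")
    entry, exit_ = hits[0][0], hits[-1][0]
    return TrajectoryEndpoints(entry=entry, exit=exit_,
                               direction=channel.direction)


def trajectory_deviation(planned: TrajectoryEndpoints,
                         achieved: TrajectoryEndpoints,
                         label: str = "") -> DeviationRecord:
    """Entry/exit offsets (mm), undirected axis angle (deg), signed
    per-axis differences (planned minus achieved)."""
    return DeviationRecord(
        entry_offset=float(np.linalg.norm(planned.entry - achieved.entry)),
        exit_offset=float(np.linalg.norm(planned.exit - achieved.exit)),
        angle_offset=angle_between_lines(planned.direction, achieved.direction),
        entry_dxyz=planned.entry - achieved.entry,
        exit_dxyz=planned.exit - achieved.exit,
        label=label,
    )


def breach_depth(wire: Channel, corridor: Corridor, n_samples: int = 200) -> float:
    """Maximal cortical breach of the wire surface beyond the corridor wall.

    Samples the wire axis over the span it shares with the corridor;
    at each sample the breach is (distance to the corridor axis + wire
    radius - corridor radius), clamped at zero.  Zero axial overlap is an
    error: the wire never entered the pedicle.
    """
    half = corridor.length / 2.0
    # wire axis parameter range whose projection falls inside the corridor span
    d_w, d_c = wire.direction, np.asarray(corridor.direction, dtype=float)
    rel = wire.origin - corridor.point
    denom = float(d_w @ d_c)
    if abs(denom) < 1e-12:
        raise ValueError("wire runs perpendicular to the corridor; no overlap")
    lo = (-half - float(rel @ d_c)) / denom
    hi = (half - float(rel @ d_c)) / denom
    lo, hi = min(lo, hi), max(lo, hi)
    lo = max(lo, 0.0)
    hi = min(hi, wire.length)
    if hi <= lo:
        raise ValueError("wire and corridor spans do not overlap")
    ts = np.linspace(lo, hi, n_samples)
    pts = wire.origin + ts[:, None] * d_w
    rel_pts = pts - corridor.point
    axial = rel_pts @ d_c
    radial = np.linalg.norm(rel_pts - axial[:, None] * d_c, axis=1)
    breach = np.maximum(radial + wire.radius - corridor.radius, 0.0)
    return float(breach.max())


def neo_grade(wire: Channel, corridor: Corridor) -> int:
    """Breach grade: 0 if contained, 1 if < 2 mm, 2 if 2--4 mm, 3 if >= 4 mm."""
    depth = breach_depth(wire, corridor)
    if depth == 0.0:
        return 0
    if depth < 2.0:
        return 1
    if depth < 4.0:
        return 2
    return 3


def summarize(values, metric: str = "") -> SummaryRow:
    """Mean, sample SD (n-1), median and quartiles of a metric vector."""
    vals = np.asarray(values, dtype=float).ravel()
    if len(vals) < 2:
        raise ValueError("need at least two values for a sample SD")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return SummaryRow(metric=metric, n=len(vals), mean=float(vals.mean()),
                      sd=float(vals.std(ddof=1)), median=float(med),
                      q1=float(q1), q3=float(q3))


def paired_location_test(pre, post, alpha: float = 0.05):
    """Paired location test with a normality-driven branch.

    Shapiro-Wilk on the paired differences decides the branch: paired t
    test for normal differences, Wilcoxon signed-rank otherwise.  Returns
    ``(test_name, statistic, p_value)``; identical samples give the
    degenerate report ``("degenerate", 0.0, None)``.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    if len(pre) < 3:
        raise ValueError("need at least 3 pairs")
    diff = pre - post
    if np.allclose(diff, 0.0):
        return ("degenerate", 0.0, None)
    sw_p = stats.shapiro(diff).pvalue
    if sw_p >= alpha:
        res = stats.ttest_rel(pre, post)
        return ("paired-t", float(res.statistic), float(res.pvalue))
    res = stats.wilcoxon(pre, post)
    return ("wilcoxon", float(res.statistic), float(res.pvalue))
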