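"""Entry/exit points, deviation metrics, Neo grading, summary statistics."""

import numpy as np
import pytest
import trimesh

from slnav.evaluation import (TrajectoryEndpoints, TrajectoryMissError,
                              breach_depth, entry_exit_points, neo_grade,
                              paired_location_test, summarize,
                              trajectory_deviation)
from slnav.phantom import Corridor
from slnav.tracking import Channel


def _wire(origin, direction, radius=1.0, length=300.0):
    return Channel(origin=origin, direction=direction, radius=radius,
                   length=length, frame="image")


def _corridor(point, direction, radius=3.0, length=25.0):
    direction = np.asarray(direction, dtype=float)
    return Corridor(0, "L", np.asarray(point, dtype=float),
                    direction / np.linalg.norm(direction), radius, length)


class TestEntryExitPoints:
    def test_sphere_chord_length(self):
        r = 15.0
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=r)
        ch = _wire([0.0, 0.0, -100.0], [0.0, 0.0, 1.0])
        ep = entry_exit_points(ch, sphere)
        assert np.linalg.norm(ep.exit - ep.entry) == pytest.approx(2 * r, abs=2e-2)
        assert np.allclose(ep.direction, [0, 0, 1])

    def test_corridor_channel_crosses_vertebra(self, tiny_scene):
        """Planned trajectories traverse their bone: entry dorsal of the
        corridor span, exit ventral of it."""
        for corridor, channel in zip(tiny_scene.corridors,
                                     tiny_scene.truth_trajectories):
            bone = tiny_scene.bones[corridor.vertebra]
            ep = entry_exit_points(channel, bone)
            along_entry = (ep.entry - corridor.point) @ corridor.direction
            along_exit = (ep.exit - corridor.point) @ corridor.direction
            assert along_entry < -corridor.length / 2.0
            assert along_exit > corridor.length / 2.0

    def test_miss_raises_with_distance(self):
        cube = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
        ch = _wire([50.0, 0.0, -100.0], [0.0, 0.0, 1.0])
        with pytest.raises(TrajectoryMissError, match="mm"):
            entry_exit_points(ch, cube)


class TestTrajectoryDeviation:
    def _endpoints(self, entry, exit_):
        entry = np.asarray(entry, dtype=float)
        exit_ = np.asarray(exit_, dtype=float)
        return TrajectoryEndpoints(entry, exit_, exit_ - entry)

    def test_self_deviation_is_zero(self):
        ep = self._endpoints([0, 0, 0], [0, 0, 30.0])
        dev = trajectory_deviation(ep, ep)
        assert dev.entry_offset == 0.0
        assert dev.exit_offset == 0.0
        assert dev.angle_offset == 0.0
        assert np.allclose(dev.entry_dxyz, 0.0)

    def test_pure_translation(self):
        planned = self._endpoints([0, 0, 0], [0, 0, 30.0])
        achieved = self._endpoints([1.0, 0, 0], [1.0, 0, 30.0])
        dev = trajectory_deviation(planned, achieved)
        assert dev.entry_offset == pytest.approx(1.0)
        assert dev.exit_offset == pytest.approx(1.0)
        assert dev.angle_offset == pytest.approx(0.0, abs=1e-9)
        assert dev.entry_dxyz[0] == pytest.approx(-1.0)

    def test_one_degree_rotation_chord(self):
        """Rotating about the entry by 1 degree moves the exit by the chord
        2 L sin(0.5 deg)."""
        L = 30.0
        planned = self._endpoints([0, 0, 0], [0, 0, L])
        c, s = np.cos(np.radians(1.0)), np.sin(np.radians(1.0))
        achieved = self._endpoints([0, 0, 0], [L * s, 0.0, L * c])
        dev = trajectory_deviation(planned, achieved)
        assert dev.entry_offset == pytest.approx(0.0, abs=1e-12)
        assert dev.angle_offset == pytest.approx(1.0, abs=1e-9)
        assert dev.exit_offset == pytest.approx(
            2 * L * np.sin(np.radians(0.5)), abs=1e-6)


class TestNeoGrade:
    def test_coaxial_wire_is_grade_zero(self):
        corr = _corridor([0, 0, 0], [0, 0, 1])
        wire = _wire([0, 0, -150.0], [0, 0, 1])
        assert neo_grade(wire, corr) == 0

    @pytest.mark.parametrize("offset,expected_breach,expected_grade", [
        (1.5, 0.0, 0),   # 1.5 + 1 < 3: contained
        (3.0, 1.0, 1),   # 3.0 + 1 - 3 = 1 mm breach
        (4.5, 2.5, 2),
        (6.5, 4.5, 3),
    ])
    def test_lateral_offset_breach_closed_form(self, offset, expected_breach,
                                               expected_grade):
        corr = _corridor([0, 0, 0], [0, 0, 1])
        wire = _wire([offset, 0, -150.0], [0, 0, 1])
        assert breach_depth(wire, corr) == pytest.approx(expected_breach,
                                                         abs=1e-9)
        assert neo_grade(wire, corr) == expected_grade

    @staticmethod
    def dense_surface_breach(wire, corr, n_axial=201, n_angle=6000):
        """Brute-force breach: max excess of wire-surface samples beyond the
        corridor wall, over dense axial x azimuthal rings."""
        ref = np.array([1.0, 0.0, 0.0]) if abs(wire.direction[0]) < 0.9 \
            else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(wire.direction, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(wire.direction, e1)
        ang = np.linspace(0.0, 2 * np.pi, n_angle, endpoint=False)
        ring = wire.radius * (np.cos(ang)[:, None] * e1
                              + np.sin(ang)[:, None] * e2)
        best = 0.0
        for t in np.linspace(0.0, wire.length, n_axial):
            surf = wire.origin + t * wire.direction + ring
            rel = surf - corr.point
            axial = rel @ corr.direction
            inside = np.abs(axial) <= corr.length / 2.0
            if not np.any(inside):
                continue
            radial = np.linalg.norm(
                rel[inside] - np.outer(axial[inside], corr.direction), axis=1)
            best = max(best, float((radial - corr.radius).max()))
        return best

    def test_breach_matches_dense_surface_sampling_parallel(self):
        """For a parallel-offset wire the axis closed form must agree with
        exhaustive surface sampling to 1e-6 mm."""
        corr = _corridor([1.0, -2.0, 3.0], [0.2, 0.1, 0.97])
        wire = _wire(corr.point - 150.0 * corr.direction
                     + np.array([2.4, -0.8, 0.0])
                     - ((np.array([2.4, -0.8, 0.0]) @ corr.direction)
                        * corr.direction),
                     corr.direction)
        analytic = breach_depth(wire, corr)
        sampled = self.dense_surface_breach(wire, corr)
        assert analytic > 0.0
        assert sampled == pytest.approx(analytic, abs=1e-6)

    def test_breach_bounds_sampling_for_skew_axes(self):
        """With skew axes the closed form is a tight upper bound on surface
        sampling (the limiting ring straddles the span boundary)."""
        corr = _corridor([1.0, -2.0, 3.0], [0.2, 0.1, 0.97])
        d = np.array([0.23, 0.08, 0.96])
        d /= np.linalg.norm(d)
        wire = _wire(corr.point - 150.0 * d + np.array([2.4, -0.8, 0.0]), d)
        analytic = breach_depth(wire, corr, n_samples=2001)
        sampled = self.dense_surface_breach(wire, corr, n_axial=2001)
        assert sampled <= analytic + 1e-9
        assert sampled == pytest.approx(analytic, abs=0.05)

    def test_no_overlap_rejected(self):
        corr = _corridor([0, 0, 0], [0, 0, 1])
        wire = _wire([0, 0, 100.0], [0, 0, 1], length=20.0)  # starts past span
        with pytest.raises(ValueError):
            neo_grade(wire, corr)


class TestSummarize:
    def test_constant_vector(self):
        row = summarize([2.0, 2.0, 2.0, 2.0], "c")
        assert row.sd == 0.0
        assert row.mean == 2.0
        assert row.q1 == row.median == row.q3 == 2.0

    def test_quartile_ordering(self, rng):
        row = summarize(rng.normal(size=200), "x")
        assert row.q1 <= row.median <= row.q3
        assert row.sd >= 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestPairedLocationTest:
    def test_identical_samples_degenerate(self):
        name, stat, p = paired_location_test([1, 2, 3.0], [1, 2, 3.0])
        assert name == "degenerate"
        assert stat == 0.0
        assert p is None

    def test_paired_t_matches_closed_form(self):
        diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pre = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        post = pre - diffs
        name, stat, p = paired_location_test(pre, post)
        assert name == "paired-t"
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert stat == pytest.approx(expected, abs=1e-9)

    def test_heavy_tailed_selects_rank_branch(self, rng):
        base = rng.normal(size=40)
        heavy = base + np.where(rng.uniform(size=40) < 0.15,
                                rng.standard_cauchy(size=40) * 50, 0.0)
        name, _, _ = paired_location_test(base + heavy, base)
        assert name == "wilcoxon"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_location_test([1, 2, 3.0], [1, 2.0])
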