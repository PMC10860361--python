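"""Geometric kernel: sphere fitting, axes, rigid rotation, ray casting."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from subtalarsim import (
    DegenerateInputError,
    LandmarkSet,
    RotationAxis,
    SurfaceMesh,
    estimate_subtalar_axis,
    estimate_talocrural_axis,
    fit_sphere,
    intersect_ray_mesh,
    make_vertical_axis,
    rotate_about_axis,
)
finite_coord = st.floats(-100, 100, allow_nan=False)
vec3 = st.tuples(finite_coord, finite_coord, finite_coord)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------


class TestFitSphere:
    def test_axis_aligned_six_points_exact(self):
        c = np.array([1.0, 2.0, 3.0])
        pts = c + 5.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        s = fit_sphere(pts)
        assert np.allclose(s.center, c, atol=1e-12)
        assert s.radius == pytest.approx(5.0, abs=1e-12)
        assert s.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_sphere_from_random_surface_points(self, rng):
        # oracle: points constructed on a known sphere must return it
        center = np.array([3.0, -2.0, 5.0])
        radius = 10.0
        d = rng.normal(size=(8, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        s = fit_sphere(center + radius * d)
        assert np.allclose(s.center, center, atol=1e-9)
        assert s.radius == pytest.approx(radius, abs=1e-9)

    def test_agrees_with_exact_four_point_solve(self, rng):
        # independent oracle: the circumsphere of 4 points from the linear
        # system 2(p_i - p_0) . c = |p_i|^2 - |p_0|^2
        center = np.array([-4.0, 7.0, 1.5])
        radius = 6.0
        d = rng.normal(size=(4, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        pts = center + radius * d
        a = 2.0 * (pts[1:] - pts[0])
        b = np.einsum("ij,ij->i", pts[1:], pts[1:]) - pts[0] @ pts[0]
        c_oracle = np.linalg.solve(a, b)
        s = fit_sphere(pts)
        assert np.allclose(s.center, c_oracle, atol=1e-8)

    @pytest.mark.parametrize(
        "pts",
        [
            np.zeros((3, 3)),  # too few
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float),  # coplanar
        ],
    )
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(DegenerateInputError):
            fit_sphere(pts)


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------


class TestAxes:
    def test_subtalar_axis_from_constructed_landmarks(self, rng):
        c1, r1 = np.zeros(3), 13.0
        c2, r2 = np.array([30.0, 20.0, 25.0]), 9.0
        def on_sphere(c, r, n):
            d = rng.normal(size=(n, 3))
            d /= np.linalg.norm(d, axis=1)[:, None]
            return c + r * d
        lm = LandmarkSet(
            groups={
                LandmarkSet.CALCANEAL: on_sphere(c1, r1, 8),
                LandmarkSet.NAVICULAR: on_sphere(c2, r2, 8),
            }
        )
        ax = estimate_subtalar_axis(lm)
        assert np.allclose(ax.point, c1, atol=1e-8)
        expected_dir = c2 / np.linalg.norm(c2)
        assert np.arccos(np.clip(ax.direction @ expected_dir, -1, 1)) < 1e-8
        assert ax.meta["calcaneal_sphere"].radius == pytest.approx(r1, abs=1e-8)

    def test_noiseless_specimen_recovers_true_axis(self, noiseless_specimen):
        sp = noiseless_specimen
        ax = estimate_subtalar_axis(sp.landmarks)
        true = sp.true_subtalar_axis
        ang = np.arccos(np.clip(abs(ax.direction @ true.direction), -1, 1))
        assert ang < 1e-6
        assert np.linalg.norm(ax.point - true.point) < 1e-6

    def test_coincident_sphere_centers_raise(self, rng):
        d = rng.normal(size=(8, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        pts = 10.0 * d  # both groups on the same sphere
        lm = LandmarkSet(groups={LandmarkSet.CALCANEAL: pts, LandmarkSet.NAVICULAR: pts})
        with pytest.raises(DegenerateInputError):
            estimate_subtalar_axis(lm)

    def test_talocrural_axis_through_trochlear_points(self):
        ax = estimate_talocrural_axis((-20.0, 0.0, 10.0), (20.0, 0.0, 10.0))
        assert np.allclose(ax.point, [-20, 0, 10])
        assert np.allclose(ax.direction, [1, 0, 0])
        with pytest.raises(DegenerateInputError):
            estimate_talocrural_axis((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))

    def test_vertical_axis_at_talocrural_midpoint(self):
        tc = estimate_talocrural_axis((-20.0, 0.0, 10.0), (20.0, 0.0, 10.0))
        v = make_vertical_axis(tc)
        assert np.allclose(v.point, [0, 0, 10])
        assert v.direction @ np.array([0, 0, 1.0]) == pytest.approx(1.0, abs=1e-15)

    def test_vertical_axis_mirror_invariant(self, noiseless_specimen):
        # a mirrored-then-canonicalised left twin shares the vertical axis
        sp = noiseless_specimen
        left = sp.canonical()  # right stays right
        tc_l = sp.true_talocrural_axis.mirrored().mirrored()  # round trip
        v = make_vertical_axis(sp.true_talocrural_axis)
        v2 = make_vertical_axis(tc_l)
        assert np.allclose(v.point, v2.point, atol=1e-9)
        assert np.allclose(v.direction, v2.direction, atol=1e-12)
        assert left.side == "right"


# ---------------------------------------------------------------------------
# rigid rotation
# ---------------------------------------------------------------------------


class TestRotation:
    def test_quarter_turn_about_z(self):
        axis = RotationAxis(np.zeros(3), [0, 0, 1])
        assert np.allclose(rotate_about_axis([1, 0, 0], axis, 90.0), [0, 1, 0], atol=1e-12)

    def test_half_turn_about_offset_axis_matches_matrix_oracle(self):
        axis = RotationAxis([1.0, 1.0, 0.0], [0, 0, 1])
        p = np.array([2.0, 1.0, 0.0])
        got = rotate_about_axis(p, axis, 180.0)
        # oracle: explicit 3x3 rotation matrix applied about the axis point
        th = np.pi
        r = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        expected = r @ (p - axis.point) + axis.point
        assert np.allclose(got, expected, atol=1e-12)
        assert np.allclose(got, [0, 1, 0], atol=1e-12)

    @given(p=vec3, angle=st.floats(-360, 360, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_zero_and_inverse_composition(self, p, angle):
        axis = RotationAxis([1.0, -2.0, 0.5], [0.3, -0.5, 0.81])
        p = np.asarray(p)
        assert np.allclose(rotate_about_axis(p, axis, 0.0), p, atol=0)
        back = rotate_about_axis(rotate_about_axis(p, axis, angle), axis, -angle)
        assert np.allclose(back, p, atol=1e-9)

    @given(p=vec3, q=vec3, angle=st.floats(-180, 180, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_rigid_isometry(self, p, q, angle):
        axis = RotationAxis([0.0, 5.0, -3.0], [1.0, 1.0, 1.0])
        d0 = np.linalg.norm(np.asarray(p) - np.asarray(q))
        d1 = np.linalg.norm(
            rotate_about_axis(p, axis, angle) - rotate_about_axis(q, axis, angle)
        )
        assert d1 == pytest.approx(d0, abs=1e-9)

    @given(t=st.floats(-50, 50, allow_nan=False), angle=st.floats(-180, 180))
    @settings(max_examples=50, deadline=None)
    def test_axis_points_are_fixed(self, t, angle):
        axis = RotationAxis([1.0, 2.0, 3.0], [0.1, 0.7, -0.3])
        p = axis.point + t * axis.direction
        assert np.allclose(rotate_about_axis(p, axis, angle), p, atol=1e-12)

    @given(
        p=vec3,
        angle=st.floats(0.1, 180.0, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_chord_displacement_law(self, p, angle):
        # |R_a(p) - p| = 2 d sin(|a|/2), d = perpendicular distance to axis
        axis = RotationAxis([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        p = np.asarray(p)
        d = axis.perpendicular_distance(p)
        moved = np.linalg.norm(rotate_about_axis(p, axis, angle) - p)
        assert moved == pytest.approx(2.0 * d * np.sin(np.deg2rad(angle) / 2.0), abs=1e-9)

    def test_chord_displacement_increases_with_angle(self):
        axis = RotationAxis(np.zeros(3), [0, 0, 1])
        p = np.array([10.0, 0.0, 5.0])
        moved = [
            np.linalg.norm(rotate_about_axis(p, axis, a) - p) for a in (3, 6, 9, 90, 180)
        ]
        assert all(m1 < m2 for m1, m2 in zip(moved, moved[1:]))


# ---------------------------------------------------------------------------
# ray-mesh intersection
# ---------------------------------------------------------------------------


def _moller_trumbore_scalar(origin, direction, tri):
    """Independent scalar oracle for a single ray-triangle test."""
    v0, v1, v2 = tri
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = e1 @ h
    if abs(a) < 1e-12:
        return None
    f = 1.0 / a
    s = origin - v0
    u = f * (s @ h)
    if u < -1e-12 or u > 1 + 1e-12:
        return None
    q = np.cross(s, e1)
    v = f * (direction @ q)
    if v < -1e-12 or u + v > 1 + 1e-12:
        return None
    t = f * (e2 @ q)
    return t if t > 1e-9 else None


class TestRayMesh:
    def test_sphere_hit_distances(self):
        sphere = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        mesh = SurfaceMesh.from_trimesh(sphere)
        mesh.vertices = mesh.vertices + np.array([5.0, 0, 0])
        hits = intersect_ray_mesh([0, 0, 0], [1, 0, 0], mesh)
        assert len(hits) == 2
        # discretisation of the unit icosphere is accurate to ~1e-4
        assert hits[0].distance == pytest.approx(4.0, abs=5e-3)
        assert hits[1].distance == pytest.approx(6.0, abs=5e-3)

    def test_ray_pointing_away_misses(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        mesh = SurfaceMesh.from_trimesh(sphere)
        mesh.vertices = mesh.vertices + np.array([5.0, 0, 0])
        assert intersect_ray_mesh([0, 0, 0], [-1, 0, 0], mesh) == []

    def test_origin_on_surface_not_reported(self, noiseless_specimen):
        mesh = noiseless_specimen.talus
        origin = mesh.vertices[mesh.faces[0]].mean(axis=0)  # on face 0
        hits = intersect_ray_mesh(origin, [0.2, 0.3, 0.93], mesh)
        assert all(h.distance > 1e-9 for h in hits)

    def test_matches_scalar_brute_force_oracle(self, noiseless_specimen, rng):
        mesh = noiseless_specimen.calcaneus
        tris = mesh.vertices[mesh.faces]
        for _ in range(10):
            origin = rng.uniform(-60, 60, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            expected = sorted(
                t
                for t in (_moller_trumbore_scalar(origin, direction, tri) for tri in tris)
                if t is not None
            )
            # merge duplicates on shared edges as the implementation does
            merged = []
            for t in expected:
                if not merged or abs(t - merged[-1]) >= 1e-7:
                    merged.append(t)
            got = [h.distance for h in intersect_ray_mesh(origin, direction, mesh)]
            assert np.allclose(got, merged, atol=1e-9)
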