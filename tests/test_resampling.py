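"""Boundary discretization, normals and the ray-conditioning chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import rayshell as rs
from rayshell.errors import BoundaryError, ParameterError, SamplingError

from conftest import circle_boundary, square_boundary


def regular_polygon(cx, cy, radius, n):
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])


class TestClosedBoundary:
    def test_too_few_points_rejected(self):
        with pytest.raises(BoundaryError):
            rs.ClosedBoundary(regular_polygon(0, 0, 1, 5))

    def test_self_intersecting_rejected(self):
        pts = regular_polygon(0, 0, 10, 8)
        pts[[1, 5]] = pts[[5, 1]]  # swap two vertices to force a crossing
        with pytest.raises(BoundaryError):
            rs.ClosedBoundary(pts)

    def test_cw_input_canonicalized_to_ccw(self):
        pts = regular_polygon(0, 0, 10, 12)
        b = rs.ClosedBoundary(pts[::-1])
        x, y = b.points[:, 0], b.points[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0


class TestResampleClosedPolyline:
    def test_square_resampled_to_corners_and_midpoints(self):
        # side-2 square, perimeter 8: targets at unit arc length are the
        # 4 corners plus the 4 edge midpoints, spacing exactly 1
        pts = np.array(
            [
                [0, 0], [0.5, 0], [2, 0], [2, 0.5],
                [2, 2], [1.5, 2], [0, 2], [0, 1.5],
            ],
            dtype=float,
        )
        out = rs.resample_closed_polyline(rs.ClosedBoundary(pts), 8)
        expected = np.array(
            [
                [0, 0], [1, 0], [2, 0], [2, 1],
                [2, 2], [1, 2], [0, 2], [0, 1],
            ],
            dtype=float,
        )
        np.testing.assert_allclose(out.points, expected, atol=1e-12)
        seg = np.linalg.norm(np.diff(np.vstack([out.points, out.points[:1]]), axis=0), axis=1)
        np.testing.assert_allclose(seg, 1.0, atol=1e-12)

    def test_uniform_input_is_exact_identity(self):
        b = circle_boundary(50, 50, 20, n=64)
        out = rs.resample_closed_polyline(b, 64)
        assert np.array_equal(out.points, b.points)

    def test_dense_circle_resampling_stays_on_circle(self):
        b = rs.ClosedBoundary(regular_polygon(100, 100, 60, 360))
        out = rs.resample_closed_polyline(b, 720)
        radii = np.hypot(out.points[:, 0] - 100, out.points[:, 1] - 100)
        # chord-vs-arc error of a 360-gon of radius 60 is below 0.01 px
        assert np.all(np.abs(radii - 60) < 0.01)

    def test_too_few_target_points_rejected(self):
        b = circle_boundary(0, 0, 10)
        with pytest.raises(ParameterError):
            rs.resample_closed_polyline(b, 4)


class TestExteriorNormals:
    def test_regular_polygon_normals_are_radial(self):
        center = np.array([30.0, 40.0])
        b = rs.ClosedBoundary(regular_polygon(*center, 15, 36))
        normals = rs.exterior_normals(b)
        radial = b.points - center
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        np.testing.assert_allclose(normals, radial, atol=1e-12)

    def test_square_corner_normal_is_diagonal(self):
        b = square_boundary(0, 0, 1)
        normals = rs.exterior_normals(b)
        idx = np.argwhere((b.points == [1.0, 0.0]).all(axis=1))[0, 0]
        np.testing.assert_allclose(normals[idx], [1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_orientation_canonicalization_gives_identical_normals(self):
        pts = regular_polygon(10, 10, 5, 16)
        n_fwd = rs.exterior_normals(rs.ClosedBoundary(pts))
        n_rev = rs.exterior_normals(rs.ClosedBoundary(pts[::-1]))
        # reversed input is canonicalized back to the original CCW order
        np.testing.assert_allclose(n_fwd, n_rev, atol=1e-12)

    def test_coincident_neighbors_raise(self):
        pts = regular_polygon(10, 10, 5, 16)
        pts[3] = pts[1]  # makes chord 2: from pts[1] to pts[3] zero
        with pytest.raises(BoundaryError):
            rs.exterior_normals(rs.ClosedBoundary(pts, validate=False))

    def test_convex_polygon_normals_point_outward(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = rng.integers(8, 30)
            theta = np.sort(rng.uniform(0, 2 * np.pi, n))
            pts = np.column_stack([50 + 20 * np.cos(theta), 50 + 12 * np.sin(theta)])
            try:
                b = rs.ClosedBoundary(pts)
            except BoundaryError:
                continue  # near-duplicate angles can degenerate; skip the draw
            normals = rs.exterior_normals(b)
            centroid = b.points.mean(axis=0)
            assert np.all(np.sum(normals * (b.points - centroid), axis=1) > 0)


class TestSampleRaySignals:
    def test_constant_image_gives_constant_signal(self):
        img = rs.ImageSlice(np.full((64, 64), 3.5))
        b = circle_boundary(31.5, 31.5, 15)
        rays = rs.sample_ray_signals(img, b, rs.exterior_normals(b), M=8)
        np.testing.assert_allclose(rays.raw_signal, 3.5)

    def test_step_image_profile_monotone_across_edge(self):
        img = np.zeros((100, 100))
        img[:, :50] = 10.0
        b = circle_boundary(40, 50, 10, n=64)  # rightmost element at x=50
        rays = rs.sample_ray_signals(rs.ImageSlice(img), b, rs.exterior_normals(b), M=8)
        i = np.argmax(b.points[:, 0])  # the horizontal ray crossing the step
        profile = rays.raw_signal[i]
        assert np.all(np.diff(profile) <= 1e-12)
        assert profile[0] == 10.0 and profile[-1] == 0.0

    def test_ray_inside_uniform_disc_is_constant(self):
        ys, xs = np.mgrid[0:128, 0:128]
        img = np.where(np.hypot(xs - 63.5, ys - 63.5) <= 50, 80.0, 0.0)
        b = circle_boundary(63.5, 63.5, 20)
        rays = rs.sample_ray_signals(rs.ImageSlice(img), b, rs.exterior_normals(b), M=10)
        np.testing.assert_allclose(rays.raw_signal, 80.0)

    def test_out_of_bounds_ray_names_element(self):
        img = rs.ImageSlice(np.zeros((64, 64)))
        b = circle_boundary(31.5, 31.5, 25)
        with pytest.raises(SamplingError, match="element"):
            rs.sample_ray_signals(img, b, rs.exterior_normals(b), M=10)

    def test_constant_image_valid_gradient_is_zero(self):
        img = rs.ImageSlice(np.full((64, 64), 9.0))
        b = circle_boundary(31.5, 31.5, 15)
        rays = rs.build_ray_field(img, b, M=8)
        assert np.all(rays.grad == 0)


class TestClampProfile:
    def test_hand_example(self):
        clamped, L1, L2 = rs.clamp_profile([10.0, 9.0, 5.0, 1.0, 0.0])
        assert L2 == 9.5 and L1 == 0.5
        np.testing.assert_allclose(clamped, [9.5, 9.0, 5.0, 1.0, 0.5])

    def test_profile_within_bounds_unchanged(self):
        v = np.array([7.0, 7.0, 5.0, 3.0, 3.0])
        clamped, L1, L2 = rs.clamp_profile(v)
        np.testing.assert_array_equal(clamped, v)

    def test_constant_profile(self):
        clamped, L1, L2 = rs.clamp_profile(np.full(7, 4.0))
        assert L1 == L2 == 4.0
        np.testing.assert_array_equal(clamped, np.full(7, 4.0))

    @given(
        hnp.arrays(
            np.float64,
            st.integers(2, 8).map(lambda M: 2 * M + 1),
            elements=st.floats(0, 1e6, allow_nan=False),
        )
    )
    def test_reclipping_with_same_bounds_is_noop(self, v):
        clamped, L1, L2 = rs.clamp_profile(v)
        lo, hi = min(L1, L2), max(L1, L2)
        assert np.all(clamped >= lo - 1e-12) and np.all(clamped <= hi + 1e-12)
        np.testing.assert_array_equal(np.clip(clamped, lo, hi), clamped)


class TestSmoothProfile:
    def test_constant_invariant(self):
        v = np.full(11, 2.5)
        np.testing.assert_array_equal(rs.smooth_profile(v, 10), v)

    def test_single_pass_with_edge_replication(self):
        np.testing.assert_allclose(rs.smooth_profile([0.0, 3.0, 0.0], 1), [1.0, 1.0, 1.0])

    def test_linear_ramp_interior_unchanged(self):
        v = np.arange(9.0)
        out = rs.smooth_profile(v, 1)
        np.testing.assert_allclose(out[1:-1], v[1:-1])

    @given(
        hnp.arrays(
            np.float64,
            st.integers(3, 25),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        ),
        st.integers(1, 12),
    )
    def test_contraction_in_range(self, v, passes):
        out = rs.smooth_profile(v, passes)
        assert out.max() <= v.max() + 1e-9
        assert out.min() >= v.min() - 1e-9


class TestValidGradient:
    def test_hand_example(self):
        g = rs.valid_gradient([8.0, 8.0, 8.0, 2.0, 2.0])
        np.testing.assert_array_equal(g, [0.0, 0.0, 6.0, 0.0])

    def test_increasing_profile_gives_zero(self):
        assert np.all(rs.valid_gradient(np.arange(9.0)) == 0)

    @given(
        hnp.arrays(
            np.float64,
            st.integers(5, 25),
            elements=st.floats(0, 1e6, allow_nan=False),
        )
    )
    def test_nonnegative_and_conserves_descent(self, v):
        g = rs.valid_gradient(v)
        assert np.all(g >= 0)
        neg_var = sum(max(0.0, v[i] - v[i + 1]) for i in range(len(v) - 1))
        assert np.isclose(g.sum(), neg_var, rtol=1e-12, atol=1e-9)


class TestRayFieldConditioning:
    def test_conditioned_signal_within_per_ray_bounds(self, standard_phantom_data):
        _, stack, truths = standard_phantom_data
        b = rs.resample_closed_polyline(truths[0], 180)
        rays = rs.build_ray_field(stack[0], b, M=20)
        lo = np.minimum(rays.L1, rays.L2)[:, None]
        hi = np.maximum(rays.L1, rays.L2)[:, None]
        assert np.all(rays.conditioned_signal >= lo - 1e-9)
        assert np.all(rays.conditioned_signal <= hi + 1e-9)
        # interior brighter than exterior on this phantom
        assert np.all(rays.L2 >= rays.L1)
        assert np.all(rays.grad >= 0)
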