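"""Shape membership, patterns, grid repetition and set combinators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimsynth import ComponentSpec, grid_points, grid_vertices, shape_membership
from stimsynth.primers import (
    Annulus,
    BezierRegion,
    Disc,
    Polygon,
    Rectangle,
    campbell_robson,
    eval_pattern,
    layout_hexagonal,
    layout_random,
    layout_rectangular,
    membership_and,
    membership_difference,
    membership_not,
    membership_or,
    sine_grating,
    square_grating,
)


class TestShapeMembership:
    def test_disc_center_is_inside(self):
        assert shape_membership(Disc((0, 0), 5.0), 0.0, 0.0) == 1.0

    def test_annulus_hole_is_outside(self):
        ann = Annulus((0, 0), inner_radius=4.0, outer_radius=8.0)
        assert shape_membership(ann, 1.0, 0.0) == 0.0
        assert shape_membership(ann, 6.0, 0.0) == 1.0

    def test_soft_edge_half_on_contour(self):
        # smoothstep of signed distance: the zero-distance contour maps to 0.5
        m = shape_membership(Disc((0, 0), 10.0), 10.0, 0.0, edge_width=2.0)
        assert m == pytest.approx(0.5, abs=1e-12)

    def test_soft_edge_ramp_monotone_across_boundary(self):
        d = Disc((0, 0), 10.0)
        xs = np.linspace(8.5, 11.5, 31)
        m = shape_membership(d, xs, np.zeros_like(xs), edge_width=2.0)
        assert np.all(np.diff(m) <= 0)
        assert m[0] == 1.0 and m[-1] == 0.0

    def test_hard_edge_is_limit_of_soft(self):
        d = Disc((0, 0), 10.0)
        for x in (3.0, 9.0, 11.0, 20.0):
            hard = shape_membership(d, x, 0.0, edge_width=0.0)
            soft = shape_membership(d, x, 0.0, edge_width=1e-6)
            assert hard == pytest.approx(soft, abs=1e-9)

    def test_rotated_rectangle(self):
        r = Rectangle((0, 0), width=10.0, height=2.0, angle=np.pi / 2)
        assert shape_membership(r, 0.0, 4.0) == 1.0  # long axis now vertical
        assert shape_membership(r, 4.0, 0.0) == 0.0

    def test_polygon_square(self):
        sq = Polygon([(0, 0), (4, 0), (4, 4), (0, 4)])
        assert shape_membership(sq, 2.0, 2.0) == 1.0
        assert shape_membership(sq, 5.0, 2.0) == 0.0

    def test_self_intersecting_polygon_even_odd(self):
        # pentagram: the central pentagon is wound twice -> outside by even-odd
        angles = [np.pi / 2 + 2 * np.pi * (2 * k) / 5 for k in range(5)]
        star = Polygon([(np.cos(a), np.sin(a)) for a in angles])
        assert shape_membership(star, 0.0, 0.0) == 0.0
        # a point inside one spike is inside
        tip = (np.cos(angles[0]), np.sin(angles[0]))
        near_tip = (0.8 * tip[0], 0.8 * tip[1])
        assert shape_membership(star, *near_tip) == 1.0

    def test_bezier_region_flattens_to_polygon(self):
        reg = BezierRegion()
        assert shape_membership(reg, 0.0, 0.0) == 1.0
        assert shape_membership(reg, 30.0, 0.0) == 0.0
        assert len(reg.to_polygon().vertices) >= 8

    def test_negative_edge_width_rejected(self):
        with pytest.raises(ValueError):
            shape_membership(Disc((0, 0), 5.0), 0, 0, edge_width=-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.floats(-30, 30),
        y=st.floats(-30, 30),
        edge=st.floats(0, 5),
        radius=st.floats(0.5, 20),
    )
    def test_membership_bounded(self, x, y, edge, radius):
        m = shape_membership(Disc((0, 0), radius), x, y, edge_width=edge)
        assert 0.0 <= m <= 1.0


class TestSetOperations:
    def test_de_morgan_identities_exact(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        assert np.array_equal(membership_not(membership_or(a, b)),
                              membership_and(membership_not(a), membership_not(b)))
        assert np.array_equal(membership_not(membership_and(a, b)),
                              membership_or(membership_not(a), membership_not(b)))

    def test_difference_is_intersection_with_complement(self, rng):
        a = rng.random((8, 8))
        b = rng.random((8, 8))
        assert np.array_equal(membership_difference(a, b),
                              membership_and(a, membership_not(b)))


class TestPatterns:
    def test_sine_on_zero_phase_line_is_mean(self):
        assert sine_grating(0.0, 0.0, 0.1, 0.0, 0.0, mean=0.4, amplitude=0.3) \
            == pytest.approx(0.4)

    def test_square_tie_goes_high(self):
        assert square_grating(0.0, 0.0, 0.1, 0.0, 0.0, mean=0.4, amplitude=0.3) \
            == pytest.approx(0.7)

    def test_grating_mean_over_integer_periods(self):
        # one full period sampled at pixel centers: spatial mean ~ `mean`
        n = 200
        x = (np.arange(n) + 0.5) * (1.0 / n)  # one period of f=1
        v = sine_grating(x, np.zeros_like(x), 1.0, 0.0, 0.0, mean=0.5, amplitude=0.5)
        assert abs(v.mean() - 0.5) < 1e-3
        vsq = square_grating(x, np.zeros_like(x), 1.0, 0.0, 0.0, mean=0.5, amplitude=0.5)
        assert abs(vsq.mean() - 0.5) < 1e-2

    def test_campbell_robson_zero_contrast_edge(self):
        x = np.linspace(0, 100, 7)
        v = campbell_robson(x, np.full_like(x, 100.0), 100.0, 100.0,
                            contrast_start=1.0, contrast_end=0.0)
        assert np.allclose(v, 0.5)

    def test_campbell_robson_frequency_increases_along_x(self):
        # zero crossings of the carrier get denser towards high-frequency side
        x = np.linspace(0, 100, 2001)
        v = campbell_robson(x, np.zeros_like(x), 100.0, 100.0,
                            freq_start=0.01, freq_end=0.3, contrast_start=1.0,
                            contrast_end=1.0)
        crossings = np.nonzero(np.diff(np.sign(v - 0.5)))[0]
        first_half = (crossings < 1000).sum()
        second_half = (crossings >= 1000).sum()
        assert second_half > 2 * first_half

    def test_eval_pattern_dispatch_and_unknown(self):
        assert eval_pattern("sine_grating", 0.0, 0.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            eval_pattern("plaid", 0.0, 0.0)

    def test_amplitude_bound_enforced(self):
        with pytest.raises(ValueError):
            ComponentSpec("primer", "sine_grating",
                          {"mean": 0.9, "amplitude": 0.5}).build()


class TestGridPoints:
    def _disc(self, **kw):
        return ComponentSpec("primer", "disc", {"radius": 2.0, **kw})

    def test_rectangular_3x4_has_12_vertices(self):
        spec = grid_points(self._disc(), "rectangular", rows=3, cols=4, spacing_x=10.0)
        assert len(spec.params["vertices"]) == 12

    def test_singleton_equals_translated_base(self, geom, ctx):
        spec = grid_points(self._disc(), "explicit", vertices=[(10.0, 20.0)])
        X, Y = geom.pixel_centers()
        rgb, alpha = spec.build().evaluate(X, Y, 0.0, ctx)
        base = ComponentSpec("primer", "disc",
                             {"radius": 2.0, "center": (10.0, 20.0)}).build()
        rgb_b, alpha_b = base.evaluate(X, Y, 0.0, ctx)
        assert np.array_equal(rgb, rgb_b)
        assert np.array_equal(alpha, alpha_b)

    def test_hexagonal_lattice_geometry(self):
        s = 10.0
        verts = layout_hexagonal(rows=2, cols=3, spacing=s)
        # row 0: y = 0, x = 0, 10, 20; row 1 offset by s/2, pitch s*sqrt(3)/2
        expected = [(0, 0), (10, 0), (20, 0),
                    (5, s * np.sqrt(3) / 2), (15, s * np.sqrt(3) / 2),
                    (25, s * np.sqrt(3) / 2)]
        assert np.allclose(verts, expected)

    def test_random_layout_reproducible_and_bounded(self):
        v1 = layout_random(n=20, width=50, height=40, seed=9)
        v2 = layout_random(n=20, width=50, height=40, seed=9)
        assert v1 == v2
        assert all(0 <= x < 50 and 0 <= y < 40 for x, y in v1)

    def test_labels_retrievable_and_unique(self):
        spec = grid_points(self._disc(), "explicit",
                           vertices=[(0, 0), (5, 5)], labels=["a", "b"])
        assert grid_vertices(spec)["b"] == (5.0, 5.0)
        assert spec.build().vertex("a") == (0.0, 0.0)
        with pytest.raises(ValueError):
            grid_points(self._disc(), "explicit",
                        vertices=[(0, 0), (5, 5)], labels=["a", "a"])

    def test_overlapping_copies_combine_by_maximum(self, geom, ctx):
        spec = grid_points(self._disc(radius=5.0), "explicit",
                           vertices=[(16.0, 16.0), (18.0, 16.0)])
        X, Y = geom.pixel_centers()
        _, alpha = spec.build().evaluate(X, Y, 0.0, ctx)
        assert alpha.max() == 1.0

    def test_rectangular_count_matches_layout(self):
        assert len(layout_rectangular(rows=2, cols=5, spacing_x=1.0)) == 10
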