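"""Descriptor formulas, their invariances, and the raster oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedshape.geometry import (Contour, GeometryError, compute_descriptors,
                                convex_hull, fitted_ellipse_axes,
                                polygon_area, polygon_perimeter)

from conftest import circle, ellipse, polar_contour, spiky_ellipse


class TestContour:
    def test_orientation_enforced(self):
        cw = Contour([(0, 0), (0, 1), (1, 1), (1, 0)])  # clockwise input
        assert polygon_area(cw) == pytest.approx(1.0)

    @pytest.mark.parametrize("points", [
        [(0, 0), (1, 0)],                                # too few
        [(0, 0), (1, 0), (1, 0), (0, 1)],                # duplicate
        [(0, 0), (1, 1), (1, 0), (0, 1)],                # bow-tie
        [(0, 0), (1, 0), (2, 0)],                        # collinear
    ])
    def test_invalid_contours_rejected(self, points):
        with pytest.raises(GeometryError):
            Contour(points)

    def test_explicit_closing_vertex_dropped(self):
        c = Contour([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert len(c) == 4


class TestAreaPerimeter:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0)
        assert polygon_perimeter(unit_square) == pytest.approx(4.0)

    def test_right_triangle(self):
        tri = Contour([(0, 0), (3, 0), (0, 4)])
        assert polygon_area(tri) == pytest.approx(6.0)
        assert polygon_perimeter(tri) == pytest.approx(12.0)

    def test_256gon_circle(self):
        c = circle(n=256)
        assert polygon_area(c) == pytest.approx(np.pi, abs=1e-3)
        assert polygon_perimeter(c) == pytest.approx(2 * np.pi, abs=2e-3)


class TestAxesAndHull:
    def test_ellipse_axes(self, fine_ellipse):
        L, W = fitted_ellipse_axes(fine_ellipse)
        assert L == pytest.approx(4.0, rel=0.01)
        assert W == pytest.approx(2.0, rel=0.01)

    def test_circle_axes_equal(self, fine_circle):
        L, W = fitted_ellipse_axes(fine_circle)
        assert L == pytest.approx(2.0, rel=0.01)
        assert W == pytest.approx(2.0, rel=0.01)

    def test_square_axes_match_pixel_moment_oracle(self, unit_square):
        # brute-force: uniform grid of interior points, covariance eigvals
        n = 1000
        xs = (np.arange(n) + 0.5) / n
        var = np.var(xs)  # independent axes for the axis-aligned square
        expected = 4.0 * np.sqrt(var)
        L, W = fitted_ellipse_axes(unit_square)
        assert L == pytest.approx(expected, rel=1e-3)
        assert W == pytest.approx(expected, rel=1e-3)

    def test_hull_of_convex_is_identity(self, fine_ellipse):
        hull = convex_hull(fine_ellipse)
        assert polygon_area(hull) == pytest.approx(
            polygon_area(fine_ellipse), rel=1e-6)

    def test_hull_of_star_is_spike_quadrilateral(self):
        # 4 spikes at radius 1, valleys at 0.3
        pts = []
        for i in range(8):
            ang = i * np.pi / 4
            r = 1.0 if i % 2 == 0 else 0.3
            pts.append((r * np.cos(ang), r * np.sin(ang)))
        hull = convex_hull(Contour(pts))
        assert len(hull) == 4
        assert polygon_area(hull) == pytest.approx(2.0)  # square, diag 2

    def test_l_shape_hull_area(self):
        L = Contour([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
        assert polygon_area(L) == pytest.approx(3.0)
        assert polygon_area(convex_hull(L)) == pytest.approx(3.5)


class TestDescriptors:
    def test_circle_maximizes_indices(self, fine_circle):
        d = compute_descriptors(fine_circle)
        for value in (d.C, d.R, d.AR, d.S):
            assert value == pytest.approx(1.0, abs=0.01)

    def test_unit_square_closed_forms(self, unit_square):
        d = compute_descriptors(unit_square)
        assert d.C == pytest.approx(np.pi / 4, abs=1e-9)
        assert d.S == pytest.approx(1.0, abs=1e-9)

    def test_ellipse_closed_forms(self, fine_ellipse):
        d = compute_descriptors(fine_ellipse)
        assert d.AR == pytest.approx(2.0, rel=0.01)
        assert d.R == pytest.approx(0.5, rel=0.01)

    @settings(max_examples=25, deadline=None)
    @given(angle=st.floats(-np.pi, np.pi),
           tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, angle, tx, ty):
        base = spiky_ellipse(n=720)
        d0 = compute_descriptors(base)
        d1 = compute_descriptors(
            base.transformed(rotation=angle, translation=(tx, ty)))
        for name, v0 in d0.as_dict().items():
            assert getattr(d1, name) == pytest.approx(v0, rel=1e-6), name

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100))
    def test_scaling_behavior(self, scale):
        base = spiky_ellipse(n=720)
        d0, d1 = (compute_descriptors(base),
                  compute_descriptors(base.transformed(scale=scale)))
        assert d1.A == pytest.approx(d0.A * scale**2, rel=1e-9)
        for name in ("P", "L", "W"):
            assert getattr(d1, name) == pytest.approx(
                getattr(d0, name) * scale, rel=1e-9)
        for name in ("AR", "C", "R", "S"):
            assert getattr(d1, name) == pytest.approx(
                getattr(d0, name), rel=1e-6)

    def test_roughness_law(self):
        """Radial spikes lengthen P and depress C and S but barely move R."""
        prev = compute_descriptors(ellipse(n=2880))
        for amplitude in np.linspace(0.005, 0.05, 10):
            d = compute_descriptors(spiky_ellipse(amplitude=amplitude))
            assert d.P > prev.P
            assert d.C < prev.C
            assert d.S < prev.S
            assert abs(d.R - prev.R) < 0.02
            prev = d

    def test_isoperimetric_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            c = polar_contour(
                lambda t: 1 + 0.3 * np.sin(rng.integers(2, 7) * t
                                           + rng.uniform(0, np.pi)), n=720)
            assert compute_descriptors(c).C <= 1.0 + 1e-9

    def test_raster_oracle_equivalence(self):
        """Polygon descriptors agree ~1% with pixel counting at 2000 px."""
        from seedshape.silhouette_io import rasterize_contour
        from skimage.morphology import convex_hull_image

        c = spiky_ellipse(a=1.6, b=1.0, amplitude=0.08, k=16)
        d = compute_descriptors(c)
        mask = rasterize_contour(c, pixel_size=3.6 / 2000)
        px = mask.pixel_size
        area_px = mask.grid.sum() * px**2
        assert area_px == pytest.approx(d.A, rel=0.01)
        # moment axes from raw pixel coordinates
        rr, cc = np.nonzero(mask.grid)
        cov = np.cov(np.vstack([cc, rr]) * px)
        lam = np.linalg.eigvalsh(cov)
        assert 4 * np.sqrt(lam[1]) == pytest.approx(d.L, rel=0.01)
        assert 4 * np.sqrt(lam[0]) == pytest.approx(d.W, rel=0.01)
        hull_px = convex_hull_image(mask.grid).sum() * px**2
        assert area_px / hull_px == pytest.approx(d.S, rel=0.01)
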