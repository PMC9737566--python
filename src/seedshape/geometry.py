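"""Planar silhouette geometry and the seed shape-descriptor system.

A seed silhouette is represented as a :class:`Contour`, a simple closed
polygon in millimetres, oriented counterclockwise.  From a contour the
eight classical particle-analysis descriptors are computed:

====================  ==========================================
area ``A``            interior area, mm^2
perimeter ``P``       outline length, mm
major axis ``L``      major axis of the moment-equivalent ellipse, mm
minor axis ``W``      minor axis of the same ellipse, mm
aspect ratio ``AR``   ``L / W`` (>= 1)
circularity ``C``     ``4*pi*A / P**2`` (1 for a circle)
roundness ``R``       ``4*A / (pi*L**2)`` (insensitive to roughness)
solidity ``S``        ``A / area(convex hull)`` (1 iff convex)
====================  ==========================================

``L`` and ``W`` follow the moment-equivalent-ellipse convention used by
mainstream image-measurement software: the ellipse with the same area and
the same normalized second central moments as the polygon interior.  This
makes ``R = b/a`` exact for ellipses and keeps the descriptors independent
of any rasterization.

Outline roughness (surface projections) lengthens ``P`` and therefore
depresses ``C`` and ``S`` while leaving ``R`` essentially unchanged;
elongation depresses ``R``.  That complementarity is what makes the
descriptor set informative for seed-coat ornamentation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from shapely.geometry import LinearRing, Polygon

__all__ = [
    "Contour",
    "ShapeDescriptors",
    "GeometryError",
    "polygon_area",
    "polygon_perimeter",
    "fitted_ellipse_axes",
    "convex_hull",
    "compute_descriptors",
]

#: areas below this (mm^2) are treated as degenerate
_AREA_EPS = 1e-9

#: solidity above which a figure is reported convex within tolerance
CONVEX_SOLIDITY_TOL = 0.995


class GeometryError(ValueError):
    """Raised for degenerate or invalid contours."""


class Contour:
    """A simple closed polygon in mm, counterclockwise, implicitly closed.

    Parameters
    ----------
    points : array-like of shape (n, 2)
        Vertex coordinates ``(x, y)`` in mm.  The closing edge from the
        last vertex back to the first is implicit; do not repeat the first
        vertex.  Clockwise input is reversed to counterclockwise.

    Raises
    ------
    GeometryError
        For fewer than 3 distinct vertices, consecutive duplicate points,
        a self-intersecting outline, or (near-)zero enclosed area.
    """

    __slots__ = ("points",)

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError(f"expected (n, 2) coordinates, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("non-finite coordinates in contour")
        # drop an explicitly repeated closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise GeometryError("a contour needs at least 3 vertices")
        seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        scale = max(1.0, float(np.abs(pts).max()))
        if np.any(seg < 1e-12 * scale):
            raise GeometryError("consecutive duplicate vertices")
        signed = _signed_area(pts)
        if abs(signed) < _AREA_EPS:
            raise GeometryError("degenerate contour: enclosed area ~ 0")
        if signed < 0:
            pts = pts[::-1]
        if not LinearRing(pts).is_simple:
            raise GeometryError("self-intersecting contour")
        self.points = pts
        self.points.setflags(write=False)

    def __len__(self) -> int:
        return len(self.points)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Contour({len(self)} vertices, A={polygon_area(self):.4g} mm^2)"

    def transformed(self, *, rotation: float = 0.0, scale: float = 1.0,
                    translation=(0.0, 0.0)) -> "Contour":
        """Similarity transform: rotate (radians, ccw), scale, translate."""
        if scale <= 0:
            raise GeometryError("scale must be positive")
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        return Contour(self.points @ rot.T * scale + np.asarray(translation, float))

    def centroid(self) -> np.ndarray:
        """Area centroid ``(x, y)`` of the polygon interior."""
        p, q = self.points, np.roll(self.points, -1, axis=0)
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        a = cross.sum() / 2.0
        cx = ((p[:, 0] + q[:, 0]) * cross).sum() / (6 * a)
        cy = ((p[:, 1] + q[:, 1]) * cross).sum() / (6 * a)
        return np.array([cx, cy])

    def shapely(self) -> Polygon:
        """The contour as a shapely polygon."""
        return Polygon(self.points)


@dataclass(frozen=True)
class ShapeDescriptors:
    """The measured descriptor tuple for one silhouette (units in class docs)."""

    A: float
    P: float
    L: float
    W: float
    AR: float
    C: float
    R: float
    S: float

    def __post_init__(self):
        for name in ("A", "P", "L", "W"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.AR < 1 - 1e-9:
            raise GeometryError("aspect ratio below 1")

    @property
    def is_convex(self) -> bool:
        """Convex within the rasterization tolerance ``S >= 0.995``."""
        return self.S >= CONVEX_SOLIDITY_TOL

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _signed_area(pts: np.ndarray) -> float:
    q = np.roll(pts, -1, axis=0)
    return float((pts[:, 0] * q[:, 1] - q[:, 0] * pts[:, 1]).sum() / 2.0)


def polygon_area(c: Contour) -> float:
    """Enclosed area in mm^2 (shoelace formula; positive by construction)."""
    return _signed_area(c.points)


def polygon_perimeter(c: Contour) -> float:
    """Outline length in mm, including the implicit closing segment."""
    d = np.diff(np.vstack([c.points, c.points[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _central_second_moments(c: Contour) -> tuple[float, float, float]:
    """Normalized central second moments (var_x, var_y, cov_xy) of the interior.

    Exact Green's-theorem integrals over the polygon interior, divided by
    the area, i.e. the covariance of a uniform density on the interior.
    """
    p, q = c.points, np.roll(c.points, -1, axis=0)
    x0, y0, x1, y1 = p[:, 0], p[:, 1], q[:, 0], q[:, 1]
    cross = x0 * y1 - x1 * y0
    a = cross.sum() / 2.0
    cx = ((x0 + x1) * cross).sum() / (6 * a)
    cy = ((y0 + y1) * cross).sum() / (6 * a)
    # raw second moments about the origin
    ixx = (cross * (y0 * y0 + y0 * y1 + y1 * y1)).sum() / 12.0   # ∫ y^2 dA
    iyy = (cross * (x0 * x0 + x0 * x1 + x1 * x1)).sum() / 12.0   # ∫ x^2 dA
    ixy = (cross * (x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0)).sum() / 24.0
    var_x = iyy / a - cx * cx
    var_y = ixx / a - cy * cy
    cov = ixy / a - cx * cy
    return var_x, var_y, cov


def principal_axis_angle(c: Contour) -> float:
    """Orientation (radians in (-pi/2, pi/2]) of the interior's principal axis."""
    var_x, var_y, cov = _central_second_moments(c)
    return 0.5 * np.arctan2(2 * cov, var_x - var_y)


def fitted_ellipse_axes(c: Contour) -> tuple[float, float]:
    """Major and minor axes (L, W) of the moment-equivalent ellipse, mm.

    For an ellipse with semi-axes ``(a, b)`` the normalized second central
    moments are ``a^2/4`` and ``b^2/4`` along the principal directions, so
    the equivalent full axes are ``4*sqrt(lambda)`` for each eigenvalue of
    the interior covariance matrix.
    """
    var_x, var_y, cov = _central_second_moments(c)
    cov_mat = np.array([[var_x, cov], [cov, var_y]])
    lam = np.linalg.eigvalsh(cov_mat)
    if lam[0] <= 0:
        raise GeometryError("degenerate contour: vanishing second moment")
    w, l = 4.0 * np.sqrt(lam)
    return float(l), float(w)


def convex_hull(c: Contour) -> Contour:
    """Convex hull of the contour, as a Contour (collinear points removed)."""
    hull = c.shapely().convex_hull
    if hull.geom_type != "Polygon":  # pragma: no cover - guarded by Contour
        raise GeometryError("hull is not a polygon")
    return Contour(np.asarray(hull.exterior.coords)[:-1])


def compute_descriptors(c: Contour) -> ShapeDescriptors:
    """All eight shape descriptors of a silhouette contour.

    ``A`` and ``P`` come from the polygon itself, ``L``/``W`` from the
    moment-equivalent ellipse, ``C = 4*pi*A/P**2``, ``R = 4*A/(pi*L**2)``,
    ``AR = L/W`` and ``S = A / area(convex_hull)``.
    """
    a = polygon_area(c)
    p = polygon_perimeter(c)
    l, w = fitted_ellipse_axes(c)
    hull_a = polygon_area(convex_hull(c))
    return ShapeDescriptors(
        A=a,
        P=p,
        L=l,
        W=w,
        AR=l / w,
        C=4.0 * np.pi * a / p**2,
        R=4.0 * a / (np.pi * l**2),
        S=a / hull_a,
    )
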