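"""Cardioid-derived geometric seed models and the J similarity index.

Lateral views of seeds in this group of plants are classically described
as reniform; quantitatively they are well captured by a family of curves
derived from the cardioid.  Here the lateral base curve is the limaçon

    r(theta) = 1 - e * cos(theta)

with the hilum (the attachment scar, the "opening" of the outline) at
``theta = 0``; a notch of relative depth ``h`` and angular width ``w_h``
is carved at the hilum with a raised-cosine profile.  Dorsal views are
modelled as an ellipse of given axis ratio with optional symmetric
raised-cosine concavities of depth ``d`` at the top and bottom
(``theta = +/- pi/2``), the "channeled back" morphology.

The J index is the percentage similarity between a silhouette and a model
figure.  It is defined here as intersection-over-union of the two filled
shapes after normalization (centroid, principal axis, unit area), times
100.  Note that some earlier work defines J as shared area over total
area; absolute J values are therefore not comparable across definitions.
IoU is used because it is symmetric and bounded in [0, 100].

Fitting a silhouette to the family — "which model adjusts best" — is a
derivative-free coordinate search minimizing ``100 - J``, wrapped in the
Model/Results idiom: build a :class:`SeedModelFamily` from a contour,
call :meth:`~SeedModelFamily.fit`, inspect the returned
:class:`SeedModelFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
from shapely.geometry import Polygon

from .geometry import Contour, polygon_area, principal_axis_angle

__all__ = ["SeedModel", "render_model", "j_index", "normalize_contour",
           "SeedModelFamily", "SeedModelFitResults"]


@dataclass(frozen=True)
class SeedModel:
    """Parameters of one model figure.

    Lateral family: eccentricity ``e`` in [0, 1], hilum-notch depth ``h``
    in [0, 1] and angular width ``w_h`` (radians, in (0, pi]).  Dorsal
    family: ``axis_ratio`` >= 1 and top/bottom concavity depth ``d`` in
    [0, 1] of angular width ``w_d``.  ``h = 0`` / ``d = 0`` (with modest
    ``e``) give convex figures.
    """

    family: str = "lateral"
    e: float = 0.0
    h: float = 0.0
    w_h: float = 1.0
    axis_ratio: float = 1.0
    d: float = 0.0
    w_d: float = np.pi / 2
    resolution: int = 360

    def __post_init__(self):
        if self.family not in ("lateral", "dorsal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.resolution < 32:
            raise ValueError("resolution must be >= 32 vertices")
        for name, lo, hi in (("e", 0, 1), ("h", 0, 1), ("d", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0 < self.w_h <= np.pi:
            raise ValueError("w_h must be in (0, pi]")
        if not 0 < self.w_d <= np.pi:
            raise ValueError("w_d must be in (0, pi]")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _raised_cosine(theta: np.ndarray, center: float, width: float) -> np.ndarray:
    """C1 bump: 1 at ``center``, 0 outside ``center +/- width/2``."""
    delta = np.angle(np.exp(1j * (theta - center)))
    out = np.zeros_like(theta)
    inside = np.abs(delta) <= width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * delta[inside] / width))
    return out


def render_model(m: SeedModel) -> Contour:
    """Render the model figure as a polygon contour (unit-scale, mm-free)."""
    theta = np.linspace(0.0, 2 * np.pi, m.resolution, endpoint=False)
    if m.family == "lateral":
        r = 1.0 - m.e * np.cos(theta)
        r = r * (1.0 - m.h * _raised_cosine(theta, 0.0, m.w_h))
    else:
        a, b = 1.0, 1.0 / m.axis_ratio
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        dent = (_raised_cosine(theta, np.pi / 2, m.w_d)
                + _raised_cosine(theta, -np.pi / 2, m.w_d))
        r = r * (1.0 - m.d * dent)
    return Contour(np.c_[r * np.cos(theta), r * np.sin(theta)])


def normalize_contour(c: Contour) -> Contour:
    """Center on the centroid, rotate the principal axis to x, scale to unit area."""
    centered = Contour(c.points - c.centroid())
    rotated = centered.transformed(rotation=-principal_axis_angle(centered))
    return rotated.transformed(scale=1.0 / np.sqrt(polygon_area(rotated)))


def _iou(p: Polygon, q: Polygon) -> float:
    inter = p.intersection(q).area
    union = p.union(q).area
    return inter / union if union > 0 else 0.0


def j_index(s: Contour, m: Contour, align: bool = True) -> float:
    """Percentage similarity (0-100) between two silhouettes.

    With ``align`` (default) both shapes are normalized to centroid /
    principal axis / unit area first, and the residual 180-degree
    ambiguity of the principal axis is resolved by keeping whichever of
    the two orientations of the second shape overlaps more.  J is
    symmetric in its arguments and invariant to similarity transforms of
    either input when aligned.  Disjoint shapes give 0, identical ones 100.
    """
    if align:
        s, m = normalize_contour(s), normalize_contour(m)
        ps = Polygon(s.points).buffer(0)
        pm = Polygon(m.points).buffer(0)
        best = max(_iou(ps, pm),
                   _iou(ps, Polygon(-m.points).buffer(0)))
        return float(np.clip(100.0 * best, 0.0, 100.0))
    return float(np.clip(
        100.0 * _iou(Polygon(s.points).buffer(0), Polygon(m.points).buffer(0)),
        0.0, 100.0))


# ---------------------------------------------------------------------------
# model fitting


#: search space per family: (param, lower, upper)
_SEARCH_SPACE = {
    "lateral": [("e", 0.0, 0.9), ("h", 0.0, 0.8), ("w_h", 0.2, np.pi)],
    "dorsal": [("axis_ratio", 1.0, 3.5), ("d", 0.0, 0.6), ("w_d", 0.2, np.pi)],
}


class SeedModelFamily:
    """Continuous model family to be fitted to one silhouette contour.

    Parameters
    ----------
    contour : Contour
        The silhouette to explain.
    family : {'lateral', 'dorsal'}
        Which parametric family to search.
    resolution : int
        Vertices used when rendering candidate figures.
    """

    def __init__(self, contour: Contour, family: str = "lateral",
                 resolution: int = 256):
        self.contour = contour
        self.family = family
        self.resolution = resolution
        self._target = normalize_contour(contour)
        if family not in _SEARCH_SPACE:
            raise ValueError(f"unknown family {family!r}")

    def _objective(self, values) -> float:
        params = {name: v for (name, _, _), v in zip(_SEARCH_SPACE[self.family], values)}
        model = SeedModel(family=self.family, resolution=self.resolution, **params)
        return 100.0 - j_index(self._target, render_model(model))

    def fit(self, n_restarts: int = 3, seed: int = 0,
            n_sweeps: int = 6) -> "SeedModelFitResults":
        """Coordinate search for the best-adjusting model figure.

        Cyclic 1-D golden-ish refinement over each parameter with a
        shrinking bracket, restarted from ``n_restarts`` random points
        (plus the space midpoint); the best of all restarts wins.
        """
        rng = np.random.default_rng(seed)
        space = _SEARCH_SPACE[self.family]
        lo = np.array([s[1] for s in space])
        hi = np.array([s[2] for s in space])
        starts = [0.5 * (lo + hi)]
        starts += [lo + rng.random(len(space)) * (hi - lo) for _ in range(n_restarts)]
        best_x, best_f, n_eval = None, np.inf, 0
        for x0 in starts:
            x = x0.copy()
            f = self._objective(x)
            n_eval += 1
            step = 0.25 * (hi - lo)
            for _ in range(n_sweeps):
                for i in range(len(x)):
                    for cand in (x[i] - step[i], x[i] + step[i]):
                        cand = float(np.clip(cand, lo[i], hi[i]))
                        trial = x.copy()
                        trial[i] = cand
                        ft = self._objective(trial)
                        n_eval += 1
                        if ft < f:
                            x, f = trial, ft
                step *= 0.5
            if f < best_f:
                best_x, best_f = x, f
        params = {name: float(v) for (name, _, _), v in zip(space, best_x)}
        model = SeedModel(family=self.family, resolution=self.resolution, **params)
        return SeedModelFitResults(self, model, 100.0 - best_f, n_eval)


class SeedModelFitResults:
    """Best-fitting model figure for one silhouette, with its J index."""

    def __init__(self, family: SeedModelFamily, model: SeedModel,
                 j: float, n_eval: int):
        self.model_family = family
        self.model = model
        self.params = {k: v for k, v in model.to_dict().items()
                       if k in [s[0] for s in _SEARCH_SPACE[family.family]]}
        self.j = j
        self.n_eval = n_eval

    def render(self) -> Contour:
        return render_model(self.model)

    def summary(self) -> str:
        lines = [
            "Seed model fit",
            "=" * 40,
            f"family:        {self.model.family}",
            f"J index:       {self.j:.2f} %",
            f"evaluations:   {self.n_eval}",
        ]
        for k, v in self.params.items():
            lines.append(f"{k + ':':14s}{v:.4f}")
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return f"<SeedModelFitResults J={self.j:.2f} {self.params}>"
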