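"""Per-species average silhouettes from stacks of aligned individual masks.

The consensus shape of ~20 seeds of one species is built by (1) rigidly
aligning every individual silhouette — centroid to the canvas centre,
principal axis horizontal, the 180-degree ambiguity resolved by pointing
the heavier half (larger third moment along the axis) toward +x, with an
optional hilum rule for lateral views that instead puts the deepest
radial concavity on the -x side — (2) optionally rescaling each seed to
a common reference area, (3) averaging the aligned binary rasters into a
per-pixel inclusion fraction ("stack"), and (4) thresholding the stack at
an inclusion fraction (default 0.5, ties counted as foreground).

Averaging acts as a shape low-pass: uncorrelated ornamentation (random
spike phases) cancels, so average outlines are smoother than their
inputs and their descriptors less dispersed — which is exactly why
average silhouettes are useful for between-group comparison.

Alignment rotates the *contour* and re-rasterizes it, rather than
rotating the raster grid, to avoid interpolation artifacts in binary
images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Contour, polygon_area, principal_axis_angle
from .silhouette_io import (BinaryMask, ExtractionError, fill_polygon,
                            mask_to_contour, write_contour_csv, write_mask)

__all__ = ["AverageSilhouette", "align_mask", "align_contour", "average_silhouette"]


@dataclass
class AverageSilhouette:
    """Consensus silhouette of one species (one view)."""

    mask: BinaryMask
    contour: Contour
    stack: np.ndarray
    n_inputs: int
    params: dict = field(default_factory=dict)

    def save(self, basepath) -> None:
        """Write PNG mask + contour CSV + JSON sidecar with the parameters."""
        base = Path(basepath)
        write_mask(base.with_suffix(".png"), self.mask)
        write_contour_csv(base.with_suffix(".csv"), self.contour)
        meta = dict(self.params, n_inputs=self.n_inputs)
        base.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def _hilum_angle(points: np.ndarray) -> float:
    """Angle of the deepest radial concavity (global minimum of r(theta))."""
    centered = points - points.mean(axis=0)
    r = np.hypot(centered[:, 0], centered[:, 1])
    i = int(np.argmin(r))
    return float(np.arctan2(centered[i, 1], centered[i, 0]))


def align_contour(contour: Contour, reference_area: float | None = None,
                  hilum_to_minus_x: bool = False) -> Contour:
    """Normalize pose: centroid at origin, principal axis along x.

    The 180-degree ambiguity is resolved by the third-moment rule, or —
    for lateral seed views — by rotating the deepest concavity (the hilum
    notch) to the -x half-plane.  With ``reference_area`` set the contour
    is also rescaled to that area (mm^2).
    """
    c = Contour(contour.points - contour.centroid())
    c = c.transformed(rotation=-principal_axis_angle(c))
    if hilum_to_minus_x:
        if np.cos(_hilum_angle(c.points)) > 0:
            c = c.transformed(rotation=np.pi)
    else:
        x = c.points[:, 0] - c.centroid()[0]
        if np.sum(x**3) < 0:  # vertex-based skew proxy, deterministic
            c = c.transformed(rotation=np.pi)
    if reference_area is not None:
        c = c.transformed(scale=np.sqrt(reference_area / polygon_area(c)))
    return c


def _rasterize_centered(contour: Contour, pixel_size: float,
                        canvas: tuple[int, int]) -> np.ndarray:
    """Rasterize a centroid-at-origin contour with the centroid at the
    exact canvas centre (so a 180-degree grid rotation is pose-preserving)."""
    n_rows, n_cols = canvas
    pts = contour.points / pixel_size
    rows = (n_rows - 1) / 2.0 - pts[:, 1]
    cols = (n_cols - 1) / 2.0 + pts[:, 0]
    if rows.min() < 1 or cols.min() < 1 or rows.max() > n_rows - 2 \
            or cols.max() > n_cols - 2:
        raise ExtractionError(
            f"canvas {canvas} too small for aligned mask "
            f"(needs rows {rows.min():.0f}..{rows.max():.0f}, "
            f"cols {cols.min():.0f}..{cols.max():.0f})"
        )
    return fill_polygon(rows, cols, canvas)


def align_mask(m: BinaryMask, canvas: tuple[int, int] | None = None,
               normalize_scale: bool = False,
               reference_area: float | None = None,
               hilum_to_minus_x: bool = False) -> BinaryMask:
    """Aligned re-rasterization of one silhouette mask.

    ``reference_area`` (mm^2) is the target area when ``normalize_scale``
    is on; it defaults to the mask's own area (pure pose alignment).
    """
    contour = mask_to_contour(m)
    if normalize_scale and reference_area is None:
        reference_area = polygon_area(contour)
    aligned = align_contour(
        contour,
        reference_area=reference_area if normalize_scale else None,
        hilum_to_minus_x=hilum_to_minus_x,
    )
    if canvas is None:
        span = np.abs(aligned.points / m.pixel_size).max()
        n = 2 * int(np.ceil(span)) + 9
        canvas = (n, n)
    grid = _rasterize_centered(aligned, m.pixel_size, canvas)
    return BinaryMask(grid=grid, pixel_size=m.pixel_size)


def average_silhouette(masks: list[BinaryMask], threshold: float = 0.5,
                       normalize_scale: bool = True,
                       hilum_to_minus_x: bool = False,
                       canvas: tuple[int, int] | None = None,
                       ) -> AverageSilhouette:
    """Stack-average aligned silhouettes and threshold the inclusion fraction.

    Requires >= 2 masks.  Without scale normalization all masks must share
    one pixel size; with it (the default) each seed is rescaled to the
    mean input area first, removing size variation so the consensus is a
    pure shape.  Pixels whose inclusion fraction is >= ``threshold``
    (ties included) are foreground; the contour traces the largest
    component.  The result is permutation-invariant bit-exactly because
    the stack is an integer count divided by n.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to average")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    pixel_sizes = {round(m.pixel_size, 12) for m in masks}
    if not normalize_scale and len(pixel_sizes) > 1:
        raise ValueError(
            "masks have mismatched pixel sizes; enable normalize_scale"
        )
    pixel_size = masks[0].pixel_size
    contours = [mask_to_contour(m) for m in masks]
    reference_area = float(np.mean([polygon_area(c) for c in contours])) \
        if normalize_scale else None
    aligned = [
        align_contour(c, reference_area=reference_area,
                      hilum_to_minus_x=hilum_to_minus_x)
        for c in contours
    ]
    if canvas is None:
        span = max(np.abs(a.points / pixel_size).max() for a in aligned)
        n = 2 * int(np.ceil(span)) + 9
        canvas = (n, n)
    count = np.zeros(canvas, dtype=np.int64)
    for a in aligned:
        count += _rasterize_centered(a, pixel_size, canvas)
    stack = count / len(masks)
    grid = stack >= threshold
    if not grid.any():
        raise ExtractionError("average is empty at this threshold")
    mask = BinaryMask(grid=grid, pixel_size=pixel_size)
    contour = mask_to_contour(mask)
    return AverageSilhouette(
        mask=mask, contour=contour, stack=stack, n_inputs=len(masks),
        params={
            "threshold": threshold,
            "normalize_scale": normalize_scale,
            "hilum_to_minus_x": hilum_to_minus_x,
            "canvas": list(canvas),
            "pixel_size_mm": pixel_size,
        },
    )
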