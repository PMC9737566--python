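"""Quick-look plots for silhouettes, consensus stacks and model fits."""

from __future__ import annotations

import numpy as np

from .averaging import AverageSilhouette
from .geometry import Contour

__all__ = ["plot_contour", "plot_average", "plot_model_fit"]


def plot_contour(contour: Contour, ax=None, **kwargs):
    """Draw a closed silhouette outline (mm axes, equal aspect)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = np.vstack([contour.points, contour.points[:1]])
    ax.plot(pts[:, 0], pts[:, 1], **kwargs)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax


def plot_average(avg: AverageSilhouette, ax=None, cmap="gray_r"):
    """Inclusion-fraction stack with the consensus outline on top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    px = avg.mask.pixel_size
    n_rows, n_cols = avg.stack.shape
    ax.imshow(avg.stack, cmap=cmap, vmin=0, vmax=1,
              extent=(0, n_cols * px, 0, n_rows * px), origin="upper")
    plot_contour(avg.contour, ax=ax, color="crimson", linewidth=1.2)
    ax.set_title(f"consensus of {avg.n_inputs} silhouettes")
    return ax


def plot_model_fit(results, ax=None):
    """Overlay a fitted model figure on its normalized silhouette."""
    from .models import normalize_contour, render_model

    ax = plot_contour(normalize_contour(results.model_family.contour),
                      ax=ax, color="black", label="silhouette")
    plot_contour(normalize_contour(render_model(results.model)), ax=ax,
                 color="crimson", linestyle="--",
                 label=f"model (J = {results.j:.1f}%)")
    ax.legend(loc="lower right", fontsize="small")
    return ax
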