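"""Shared fixtures: analytic contours and a small synthetic study."""

import numpy as np
import pytest

from seedshape.geometry import Contour


def polar_contour(radius_fn, n=720, scale=1.0, center=(0.0, 0.0)):
    """Polygon from a polar radius function (counterclockwise)."""
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = radius_fn(theta) * scale
    return Contour(np.c_[r * np.cos(theta) + center[0],
                         r * np.sin(theta) + center[1]])


def circle(r=1.0, n=720, center=(0.0, 0.0)):
    return polar_contour(lambda t: np.full_like(t, r), n=n, center=center)


def ellipse(a=2.0, b=1.0, n=720, center=(0.0, 0.0)):
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return Contour(np.c_[a * np.cos(theta) + center[0],
                         b * np.sin(theta) + center[1]])


def spiky_ellipse(a=2.0, b=1.0, amplitude=0.05, k=24, phase=0.0, n=2880):
    """Ellipse with multiplicative triangular radial spikes."""
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    u = (k * (theta + phase) / (2 * np.pi)) % 1.0
    g = np.clip(1 - np.abs(u - 0.5) / 0.25, 0, None)
    r = 1.0 + amplitude * g
    return Contour(np.c_[a * r * np.cos(theta), b * r * np.sin(theta)])


@pytest.fixture
def unit_square():
    return Contour([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def fine_circle():
    return circle(n=2048)


@pytest.fixture
def fine_ellipse():
    return ellipse(n=2048)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """Tiny 4-group study (2 species x 6 seeds per group) on disk."""
    from seedshape.synthetic_seeds import generate_study

    out = tmp_path_factory.mktemp("study")
    manifest = generate_study(out, species_per_group=2, n_seeds=6, seed=11,
                              resolution_px=256)
    return out, manifest


@pytest.fixture(scope="session")
def small_report(small_study):
    from seedshape.pipeline import StudyConfig, run_study

    out, _ = small_study
    return run_study(out / "manifest.csv", StudyConfig())
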