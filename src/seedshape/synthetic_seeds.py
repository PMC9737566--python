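"""Synthetic seed populations with the outline structure of the four groups.

Real seed-coat ornamentation falls into four silhouette classes: *smooth*
(no superficial projections), *rugose* (rounded tubercles), *echinate*
(acute spines) and *papillose* (long, broad prolongations, mostly flat at
the tip).  The generator emulates exactly that vocabulary: each species
has a base outline from the cardioid-derived model family (lateral view
with a hilum notch; dorsal ellipse with optional top/bottom concavities)
on which a multiplicative radial ornament is superimposed,

    r(theta) -> r(theta) * (1 + a * g(theta; k, phase)),

with ``g`` a periodic non-negative profile whose shape encodes the group:
raised-cosine bumps (rugose), narrow triangular spikes (echinate), tall
smoothed trapezoids with flat tops (papillose), and ``a = 0`` for smooth.
Amplitude ranges per group follow the verbal morphology: rugose 0.02-0.06,
echinate 0.05-0.12, papillose 0.15-0.30 of the local radius.

Within a species, seeds vary by random ornament phase, jittered amplitude
and log-normal size scatter (default CV 10%); across species of a group,
base size varies with a larger CV (default 45%) so that study-level area
and perimeter dispersions dominate, as they do in real seed collections.
Everything is deterministic given the integer seed.

Seeds are rendered to binary masks (default 512 px across the long axis)
and measured through the same extraction path as real photographs, so a
synthetic study exercises the entire pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Contour, polygon_area
from .models import SeedModel
from .records import SeedRecord
from .silhouette_io import (MANIFEST_COLUMNS, mask_to_contour,
                            rasterize_contour, write_manifest, write_mask)

__all__ = ["Ornament", "SpeciesSpec", "default_species_spec",
           "clean_outline", "generate_species", "generate_study",
           "GROUP_DEFAULTS"]

_THETA = np.linspace(0.0, 2 * np.pi, 1024, endpoint=False)


@dataclass(frozen=True)
class Ornament:
    """Periodic radial ornament: amplitude, count and tip shape."""

    amplitude: float = 0.0
    count: int = 12
    tip: str = "none"  # none | rounded | spike | papilla

    def profile(self, theta: np.ndarray, phase: float) -> np.ndarray:
        """Non-negative ornament profile g(theta) in [0, 1]."""
        if self.tip == "none" or self.amplitude == 0:
            return np.zeros_like(theta)
        u = (self.count * (theta + phase) / (2 * np.pi)) % 1.0
        if self.tip == "rounded":  # adjacent smooth tubercles
            return 0.5 * (1 + np.cos(2 * np.pi * (u - 0.5)))
        if self.tip == "spike":  # acute triangular spines with gaps
            width = 0.5
            return np.clip(1 - np.abs(u - 0.5) / (width / 2), 0, None)
        if self.tip == "papilla":  # broad, steep-sided, flat-topped
            width, ramp = 0.72, 0.12
            return np.clip((width / 2 - np.abs(u - 0.5)) / ramp, 0, 1)
        raise ValueError(f"unknown tip shape {self.tip!r}")


#: per-group defaults: base models, ornament, the range the species-level
#: ornament amplitude is drawn from, and group-mean lateral area (mm^2).
#: Magnitudes mirror real seed collections: smooth and rugose seeds carry
#: an open (concave) hilum region, echinate seeds are more closed around
#: the hilum and mostly convex dorsally, papillose seeds carry the
#: longest, broadest projections.
GROUP_DEFAULTS: dict[str, dict] = {
    "smooth": dict(
        lateral=SeedModel(family="lateral", e=0.5, h=0.45, w_h=1.6),
        dorsal=SeedModel(family="dorsal", axis_ratio=1.85, d=0.15, w_d=1.4),
        ornament=Ornament(0.0, 12, "none"),
        amplitude_range=(0.0, 0.0),
        size_mean_mm2=1.31,
    ),
    "rugose": dict(
        lateral=SeedModel(family="lateral", e=0.5, h=0.40, w_h=1.5),
        dorsal=SeedModel(family="dorsal", axis_ratio=1.85, d=0.12, w_d=1.4),
        ornament=Ornament(0.04, 12, "rounded"),
        amplitude_range=(0.02, 0.06),
        size_mean_mm2=1.19,
    ),
    "echinate": dict(
        lateral=SeedModel(family="lateral", e=0.45, h=0.18, w_h=1.0),
        dorsal=SeedModel(family="dorsal", axis_ratio=1.70, d=0.03, w_d=1.2),
        ornament=Ornament(0.085, 24, "spike"),
        amplitude_range=(0.05, 0.12),
        size_mean_mm2=0.89,
    ),
    "papillose": dict(
        lateral=SeedModel(family="lateral", e=0.45, h=0.20, w_h=1.0),
        dorsal=SeedModel(family="dorsal", axis_ratio=1.80, d=0.05, w_d=1.2),
        ornament=Ornament(0.22, 9, "papilla"),
        amplitude_range=(0.15, 0.30),
        size_mean_mm2=1.22,
    ),
}


@dataclass(frozen=True)
class SpeciesSpec:
    """Recipe for one synthetic species (both views)."""

    species: str
    group: str
    lateral: SeedModel
    dorsal: SeedModel
    ornament: Ornament
    n_seeds: int = 20
    size_mean_mm2: float = 1.0     # mean lateral silhouette area
    size_cv: float = 0.10          # within-species log-normal size CV
    dorsal_area_ratio: float = 0.72
    amplitude_jitter: float = 0.20  # relative log-SD of per-seed amplitude
    elongation_jitter: float = 0.05  # log-SD of per-seed axis-ratio factor
    notch_jitter: float = 0.10     # log-SD of per-seed notch/dent depth
    lateral_y_scale: float = 0.80  # anisotropic squeeze giving AR ~ 1.25
    resolution_px: int = 512       # pixels across the longest axis
    seed: int = 0

    def __post_init__(self):
        if self.group not in GROUP_DEFAULTS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.group == "smooth" and self.ornament.amplitude != 0:
            raise ValueError("smooth seeds have no superficial projections")

    def to_dict(self) -> dict:
        return asdict(self)


def default_species_spec(group: str, species: str | None = None,
                         size_mean_mm2: float | None = None,
                         seed: int = 0, **overrides) -> SpeciesSpec:
    """A SpeciesSpec with the group's default morphology."""
    if group not in GROUP_DEFAULTS:
        raise ValueError(f"unknown group {group!r}")
    base = GROUP_DEFAULTS[group]
    return SpeciesSpec(
        species=species or f"{group}_sp",
        group=group,
        lateral=base["lateral"],
        dorsal=base["dorsal"],
        ornament=base["ornament"],
        size_mean_mm2=size_mean_mm2 or base["size_mean_mm2"],
        seed=seed,
        **overrides,
    )


def _base_outline(spec: SpeciesSpec, view: str,
                  amplitude: float = 0.0, phase: float = 0.0,
                  elongation_factor: float = 1.0,
                  depth_factor: float = 1.0) -> Contour:
    """Ornamented polar outline at unit scale (not yet sized or rasterized).

    ``elongation_factor`` and ``depth_factor`` carry the per-seed
    within-species jitter of the axis ratio and of the hilum-notch /
    dorsal-dent depth.
    """
    model = spec.lateral if view == "lateral" else spec.dorsal
    theta = _THETA
    if model.family == "lateral":
        r = 1.0 - model.e * np.cos(theta)
        notch = np.zeros_like(theta)
        delta = np.angle(np.exp(1j * theta))
        inside = np.abs(delta) <= model.w_h / 2
        notch[inside] = 0.5 * (1 + np.cos(2 * np.pi * delta[inside] / model.w_h))
        depth = min(model.h * depth_factor, 0.95)
        r = r * (1.0 - depth * notch)
    else:
        ratio = max(1.0, model.axis_ratio * elongation_factor)
        a, b = 1.0, 1.0 / ratio
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        dent = np.zeros_like(theta)
        for center in (np.pi / 2, -np.pi / 2):
            delta = np.angle(np.exp(1j * (theta - center)))
            inside = np.abs(delta) <= model.w_d / 2
            dent[inside] += 0.5 * (1 + np.cos(2 * np.pi * delta[inside] / model.w_d))
        r = r * (1.0 - min(model.d * depth_factor, 0.95) * dent)
    if amplitude > 0:
        r = r * (1.0 + amplitude * spec.ornament.profile(theta, phase))
    xy = np.c_[r * np.cos(theta), r * np.sin(theta)]
    if view == "lateral":
        xy[:, 1] *= spec.lateral_y_scale / elongation_factor
    return Contour(xy)


def clean_outline(spec: SpeciesSpec, view: str = "lateral",
                  area_mm2: float | None = None) -> Contour:
    """The species' ornament-free base outline at the mean size."""
    c = _base_outline(spec, view)
    target = area_mm2 if area_mm2 is not None else (
        spec.size_mean_mm2 if view == "lateral"
        else spec.size_mean_mm2 * spec.dorsal_area_ratio)
    return c.transformed(scale=np.sqrt(target / polygon_area(c)))


def _render_record(spec: SpeciesSpec, view: str, index: int,
                   amplitude: float, phase: float, area: float,
                   elongation_factor: float = 1.0,
                   depth_factor: float = 1.0) -> SeedRecord:
    outline = _base_outline(spec, view, amplitude, phase,
                            elongation_factor, depth_factor)
    target = area if view == "lateral" else area * spec.dorsal_area_ratio
    outline = outline.transformed(scale=np.sqrt(target / polygon_area(outline)))
    span = (outline.points.max(axis=0) - outline.points.min(axis=0)).max()
    pixel_size = span / spec.resolution_px
    mask = rasterize_contour(outline, pixel_size, pad_px=6)
    contour = mask_to_contour(mask)
    return SeedRecord(
        seed_id=f"{spec.species}_{index:03d}",
        species=spec.species,
        view=view,
        group=spec.group,
        contour=contour,
        mask=mask,
    )


def generate_species(spec: SpeciesSpec) -> list[SeedRecord]:
    """All seed records (both views) of one species; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log(1 + spec.size_cv**2))
    records: list[SeedRecord] = []
    for i in range(spec.n_seeds):
        phase = rng.uniform(0, 2 * np.pi)
        amplitude = spec.ornament.amplitude * float(
            np.exp(rng.normal(0.0, spec.amplitude_jitter)))
        area = spec.size_mean_mm2 * float(
            np.exp(rng.normal(-sigma**2 / 2, sigma)))
        elongation = float(np.exp(rng.normal(0.0, spec.elongation_jitter)))
        depth = float(np.exp(rng.normal(0.0, spec.notch_jitter)))
        for view in ("lateral", "dorsal"):
            records.append(_render_record(spec, view, i, amplitude, phase,
                                          area, elongation, depth))
    return records


def study_specs(groups=("smooth", "rugose", "echinate", "papillose"),
                species_per_group: int = 4, n_seeds: int = 20, seed: int = 0,
                across_species_size_cv: float = 0.45,
                across_species_elongation_sd: float = 0.05,
                across_species_depth_sd: float = 0.15,
                resolution_px: int = 512) -> list[SpeciesSpec]:
    """Species recipes for a multi-group study.

    Species of one group share the group's base morphology but differ —
    as real congeners do — in mean size (log-normal, default CV 45%, so
    area/perimeter dispersion dominates at study level), elongation
    (log-SD 5% on the axis ratio), hilum-notch / dorsal-dent depth
    (log-SD 15%) and ornament amplitude (uniform in the group's stated
    range).  Every species also gets a private RNG seed.  All draws flow
    from ``seed``.
    """
    if species_per_group < 1:
        raise ValueError("species_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + across_species_size_cv**2))
    specs = []
    for group in groups:
        if group not in GROUP_DEFAULTS:
            raise ValueError(f"unknown group {group!r}")
        base = GROUP_DEFAULTS[group]
        for j in range(species_per_group):
            size = base["size_mean_mm2"] * float(
                np.exp(rng.normal(-sigma**2 / 2, sigma)))
            elong = float(np.exp(rng.normal(0, across_species_elongation_sd)))
            depth = float(np.exp(rng.normal(0, across_species_depth_sd)))
            lo, hi = base["amplitude_range"]
            amplitude = float(rng.uniform(lo, hi))
            lateral = replace(base["lateral"],
                              h=min(base["lateral"].h * depth, 0.95))
            dorsal = replace(base["dorsal"],
                             axis_ratio=max(1.0, base["dorsal"].axis_ratio * elong),
                             d=min(base["dorsal"].d * depth, 0.95))
            ornament = replace(base["ornament"], amplitude=amplitude)
            specs.append(SpeciesSpec(
                species=f"{group}_{j:02d}", group=group,
                lateral=lateral, dorsal=dorsal, ornament=ornament,
                size_mean_mm2=size, n_seeds=n_seeds,
                lateral_y_scale=min(0.8 / elong, 1.0),
                seed=int(rng.integers(2**31)),
                resolution_px=resolution_px,
            ))
    return specs


def generate_study(out_dir, groups=("smooth", "rugose", "echinate", "papillose"),
                   species_per_group: int = 4, n_seeds: int = 20,
                   seed: int = 0, resolution_px: int = 512,
                   specs: list[SpeciesSpec] | None = None) -> pd.DataFrame:
    """Write a full synthetic study: PNG masks + manifest CSV + spec JSON.

    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``); masks land under ``out_dir/masks/`` and the
    exact recipes under ``out_dir/study_spec.json`` for regeneration.
    """
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = study_specs(groups, species_per_group, n_seeds, seed,
                            resolution_px=resolution_px)
    rows = []
    for spec in specs:
        for rec in generate_species(spec):
            rel = f"masks/{rec.seed_id}_{rec.view}.png"
            write_mask(out / rel, rec.mask)
            rows.append({
                "path": rel,
                "seed_id": rec.seed_id,
                "species": rec.species,
                "view": rec.view,
                "group": rec.group,
                "pixels_per_mm": 1.0 / rec.mask.pixel_size,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_manifest(out / "manifest.csv", manifest)
    (out / "study_spec.json").write_text(
        json.dumps([s.to_dict() for s in specs], indent=1))
    return manifest
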