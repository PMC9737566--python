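# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `seedshape`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Contours and descriptors

A silhouette is a simple closed polygon in mm, stored counterclockwise
with an implicit closing edge.  Degenerate inputs (< 3 vertices,
consecutive duplicates, self-intersection, enclosed area < 1e-9 mm²) are
hard construction errors, never silently repaired.

Area and perimeter are the shoelace sum and the edge-length sum.  The
major/minor axes `L`, `W` follow the **moment-equivalent ellipse**
convention of mainstream image-measurement software: the ellipse with the
same area and the same normalized second central moments as the polygon
interior.  The second moments are exact Green's-theorem integrals over
the polygon (not pixel sums), so `R = b/a` holds exactly for ellipse
polygons and all descriptors are rasterization-free for polygon input.
Feret (caliper) diameters are deliberately *not* used; they would couple
`L` to ornament tips and break the roughness-insensitivity of roundness.

Solidity uses the convex hull (GEOS, via shapely).  `S >= 0.995` is
reported as "convex within tolerance": rasterized shapes never reach
`S = 1` exactly.

## 2. Sub-pixel boundary extraction

Silhouettes are segmented by Otsu thresholding (polarity auto-detected by
comparing the border-pixel mean with the global mean; an image more than
half foreground is rejected as a polarity error), keeping the largest
8-connected component and filling holes — a silhouette is a solid figure,
anything else corrupts solidity.

The outline is the 0.5 level set of the binary indicator field smoothed
with a Gaussian of **sigma = 1.5 px**.  Marching squares on the raw
binary yields a pixel staircase that inflates perimeters by ~5–10% and
drags the solidity of convex figures below 0.995 at 512 px; the smoothed
level set restores a genuinely sub-pixel boundary (circle perimeter
accurate to ~0.3%, convex solidity >= 0.998 at 512 px) while ornament at
realistic scales (>= ~10 px) is preserved.  The sigma trades staircase
suppression against blunting of very fine spikes; at the default raster
resolution (512 px across the long axis) this bias is shared by all
groups and cancels from between-group contrasts.  Extraction is
idempotent to better than 1% in every descriptor.

Rasterization of polygons uses an even-odd scanline fill (pixel centre
inside the polygon), which is orders of magnitude faster than generic
point-in-polygon tests for marching-squares-sized vertex counts.

## 3. Average silhouettes

The consensus of n individual silhouettes of one species is built by
rigid alignment, optional size normalization, stack averaging and
thresholding:

1. the contour (not the raster) is translated to its centroid and rotated
   so the principal axis of the interior is horizontal — rotating rasters
   would need interpolation on binary images;
2. the 180° ambiguity is resolved by the third-moment rule (heavier half
   to +x); for lateral views an optional hilum rule instead places the
   deepest radial concavity (the hilum notch, found as the global minimum
   of the radial profile) on the −x side, giving all seeds the
   conventional hilum-left pose;
3. with `normalize_scale` (default on) each seed is rescaled to the mean
   input area, so the consensus is a pure shape; the flag is recorded in
   the JSON sidecar because the original published procedure leaves this
   point open;
4. aligned contours are re-rasterized onto a common canvas, the per-pixel
   inclusion fraction ("stack") is the integer count divided by n — hence
   bit-exact permutation invariance — and pixels with fraction
   **>= 0.5** (ties included) are foreground.

Averaging acts as a shape low-pass: uncorrelated ornament phases cancel,
so consensus outlines are smoother (higher C, shorter normalized
perimeter) than their inputs, most visibly for spiny groups, and the
dispersion of shape descriptors across species collapses relative to the
dispersion across individual seeds.

## 4. Cardioid seed models and the J index

Lateral outlines are modelled as limaçons `r(θ) = 1 − e·cosθ` (hilum at
θ = 0) with a raised-cosine notch of depth `h ∈ [0,1]` and angular width
`w_h` carved at the hilum; the limaçon is convex for `e <= 0.5`, and
`h = 0` figures rasterize to `S >= 0.995`.  Dorsal outlines are ellipses
(axis ratio >= 1) with optional symmetric raised-cosine concavities of
depth `d` at θ = ±π/2 — the "channeled back" morphology.  Historical
catalogues of discrete lateral/dorsal model figures are replaced by this
continuous 3-parameter family; "which model adjusts best" becomes a fit.

**J index** = 100 × area(intersection)/area(union) after both shapes are
normalized to centroid, principal axis and unit area; the residual 180°
ambiguity is resolved by keeping the better-overlapping orientation.
IoU is symmetric and bounded in [0, 100].  *Caution:* some earlier work
defines J as shared-area-over-total-area; absolute J values are not
comparable across definitions, so J values from this package should only
be compared with each other.

Fitting minimizes `100 − J` by cyclic coordinate descent with a halving
bracket (6 sweeps) from the space midpoint plus 3 random restarts; the
objective is smooth and low-dimensional, and planted parameters are
recovered to ~0.05 in the unit-range parameters at J > 99.

## 5. The synthetic seed generator

The generator emulates the four ornamentation groups as multiplicative
radial ornament on the model-family base outline,
`r(θ) → r(θ)·(1 + a·g(θ))` with per-group profile and amplitude range:

| group | profile g | species amplitude a | base morphology |
|---|---|---|---|
| smooth | none (a = 0) | 0 | open hilum notch (h = 0.45) |
| rugose | adjacent raised-cosine bumps, k = 12 | U(0.02, 0.06) | open notch (h = 0.40) |
| echinate | triangular spikes with gaps, k = 24 | U(0.05, 0.12) | closed hilum (h = 0.18), convex dorsal |
| papillose | broad flat-topped trapezoids, k = 9 | U(0.15, 0.30) | h = 0.20, largest projections |

Base lateral outlines get an anisotropic squeeze (`lateral_y_scale =
0.8`) because the pure limaçon cannot exceed AR ≈ 1.1 while real lateral
views sit near AR ≈ 1.25.  Within a species, seeds vary by ornament
phase (uniform), amplitude (log-SD 0.20), size (log-normal, CV 10%),
elongation (log-SD 5% — chosen so individual lateral roundness CV lands
near the ~7% observed in real collections) and notch/dent depth (log-SD
10%).  Across species of a group, mean size varies with CV 45% (real
area/perimeter dispersion is dominated by the across-species component),
elongation with log-SD 5%, depth with log-SD 15%, and the ornament
amplitude is drawn per species from the group's range.  All randomness
flows from a single integer seed per species (study-level seeds derived
from one master seed), so regeneration is bit-identical.

Seeds are rendered at 512 px across the long axis and measured through
the same extraction path as real photographs.

What the generator does **not** emulate: photographic artifacts (shadows,
glare, defocus), multi-seed scenes, testa cell texture inside the
outline, asymmetric or clustered ornament, and any within-group
correlation structure between size and ornament.  A green test on
synthetic data therefore validates the measurement and inference
machinery and the qualitative group structure, not the absolute
descriptor values of any real seed collection.

## 6. Statistics

CV is the sample (n−1) standard deviation over the mean, ×100.
Kruskal–Wallis uses midranks with the standard tie correction and the
chi-square approximation (k−1 df) throughout; all-identical data returns
H = 0, p = 1 rather than an error.  An exact-permutation p-value
(complete enumeration of group assignments) is available for total
n <= 12 and backs the oracle tests.

The Campbell–Skillings step-down search orders groups by mean global
midrank and tests contiguous subsets in a closed fashion, **re-ranking
within each subset** (the subset's own KW test — the defining feature of
the procedure).  The full set is tested at α; a subset of size p < k at
`α_p = 1 − (1−α)^((p−1)/(k−1))`.  Published descriptions vary in the
adjustment, so it is pluggable (`adjust="none"` tests every subset at α);
letter patterns on real data may therefore differ from other software.
Accepted subsets, reduced to maximal ones, are the homogeneous subsets;
they are contiguous in mean-rank order by construction, and letters are
assigned left to right.  Under the global null the family-wise error of
the whole display equals the omnibus rejection rate, ≈ α (the test suite
verifies ~0.05 within [0.035, 0.065] over 2000 null replicates).

Descriptors whose omnibus test accepts are flagged (`results.excluded`)
rather than dropped — reproducing, as behavior, the classical practice
of excluding measurements "for lack of differences".

On average silhouettes only shape descriptors (AR, C, R, S) are compared:
size is randomized by the averaging process and is not a property of a
consensus shape.

## 7. Numerical choices and degenerate inputs

- Convexity tolerance 0.995; contour duplicate tolerance 1e-12 relative.
- Stack threshold ties count as foreground (`>=`), making the
  two-concentric-disks half-inclusion case deterministic.
- Principal-axis alignment is undefined for isotropic shapes (disks);
  the rotation then depends on numerical noise but the consensus of
  isotropic shapes is rotation-invariant anyway.
- Masks must contain exactly one 8-connected component not touching the
  raster border (guard band >= 1 px); violations are errors.
- Empty intersection in the J index gives J = 0, not an error.

## 8. Known limitations

- Absolute perimeters (hence C) depend on the boundary-smoothing sigma;
  comparisons are only meaningful within one sigma setting.
- The hilum-notch detector assumes the notch is the deepest radial
  concavity; heavily ornamented lateral views with concavities deeper
  than the hilum would be flipped inconsistently.
- The exact-permutation KW option is exponential in n and refuses
  n > 12.
- Model fitting is a local search with restarts; pathological
  silhouettes may fit to a local optimum (raise `n_restarts`).
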