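# seedshape

Morphometrics of seed silhouettes — the two-dimensional outlines of seeds
photographed in lateral view (hilum to one side, the classic "reniform" /
cardioid-related profile) and dorsal view.  Seed-coat ornamentation leaves a
clear signature in these outlines: *smooth* seeds have no superficial
projections, *rugose* seeds carry rounded tubercles, *echinate* seeds acute
spines, and *papillose* seeds long, broad, mostly flat-tipped papillae.
`seedshape` turns calibrated seed photographs (or binary masks) into shape
descriptors, per-species consensus silhouettes and letter-annotated group
comparisons, and ships a fully parameterized synthetic seed generator so
every stage can be exercised and validated without any image collection.

Intended users: plant morphologists and taxonomists quantifying seed-shape
variation across species, and anyone needing reproducible outline
morphometrics of small objects segmented from contrasting backgrounds.

## The measurement system

For a silhouette with outline area $A$ and perimeter $P$, the package
computes

- circularity $C = 4\pi A / P^2$ — 1 for a circle, depressed by outline
  roughness;
- roundness $R = 4A / (\pi L^2)$, with $L$ the major axis of the
  moment-equivalent ellipse — penalizes elongation but is insensitive to
  roughness;
- aspect ratio $AR = L/W \ge 1$;
- solidity $S = A / A_{\text{hull}}$ — 1 exactly for convex figures,
  depressed by concavities and projections.

Surface projections lengthen $P$ and therefore depress $C$ and $S$ while
leaving $R$ essentially unchanged; this complementarity is what lets the
descriptor set separate ornamentation classes.  Outlines are measured on
the sub-pixel 0.5-level boundary of the (smoothed) binary silhouette, so
rasterized convex figures measure $S \ge 0.995$ at 512 px.

Overall shape is quantified against a continuous cardioid-derived model
family (lateral: limaçon $r(\theta) = 1 - e\cos\theta$ with a raised-cosine
hilum notch of depth $h$ and width $w_h$; dorsal: ellipse with optional
top/bottom concavities of depth $d$).  The **J index** is the percentage
similarity between a silhouette and a model figure, computed as
intersection-over-union after normalization to centroid, principal axis and
unit area ($J = 100$ for identical shapes).

Between-group differences are assessed with a Kruskal–Wallis omnibus test
followed by Campbell–Skillings stepwise step-down homogeneous subsets
(re-ranked subset tests at level
$\alpha_p = 1-(1-\alpha)^{(p-1)/(k-1)}$), reported as a compact letter
display: groups sharing a letter do not differ at $\alpha = 0.05$.

## Worked example

Measure a polygon directly:

```python
from seedshape import Contour, compute_descriptors

L_shape = Contour([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
print(compute_descriptors(L_shape).as_dict())
```

```
A = 3.0000   P = 8.0000   L = 2.5820  W = 1.7638
AR = 1.4639  C = 0.5890   R = 0.5730  S = 0.8571
```

`A`, `P` are exact (shoelace / edge sums); `S = 3/3.5` because the convex
hull closes the notch of the L; `C` is well below 1 because the re-entrant
outline lengthens the perimeter relative to the enclosed area.

Simulate a four-group study and compare the groups end to end:

```python
from seedshape import generate_study, run_study, StudyConfig

generate_study("demo", species_per_group=2, n_seeds=10, seed=0)
report = run_study("demo/manifest.csv", StudyConfig(), out_dir="demo_out")
print(report.comparisons["lateral"].summary())
```

```
Seed group comparison (Kruskal-Wallis + step-down letters)
============================================================
alpha = 0.05, adjustment = stepdown

                        A              P             AR              C              R              S
echinate    0.963 (9.6) b  4.37 (14.1) b   1.18 (3.7) c  0.66 (22.8) b  0.841 (3.7) a  0.908 (4.1) b
papillose  0.884 (18.9) b   4.58 (9.8) b   1.13 (5.0) b  0.53 (13.2) a  0.853 (4.9) a  0.866 (2.6) a
rugose     0.637 (11.6) a   2.96 (5.5) a   1.08 (3.9) a  0.911 (1.7) c  0.924 (3.9) b  0.974 (0.7) c
smooth      1.32 (12.6) c   4.26 (7.0) b  1.13 (6.0) bc  0.908 (1.8) c  0.877 (6.1) a  0.981 (0.2) d
```

Cells are `mean (CV%) letters`.  Papillose seeds take the unique lowest
letter for circularity and solidity — the heavy flat-tipped papillae
lengthen the outline and open deep concavities between projections —
while echinate seeds sit between papillose and the rugose/smooth pair.
The run directory contains the per-seed descriptor CSV, per-species
average silhouettes (PNG + contour CSV + JSON sidecar), the classic
summary table (mean / SD / CV / extreme species per descriptor) and both
comparison tables (individual silhouettes; average silhouettes, shape
descriptors only).

The same workflow is available from the shell:

```bash
seedshape simulate --out demo --seed 0
seedshape run --manifest demo/manifest.csv --out demo_out
seedshape calibrate 0 0 30 40 5        # two ruler points, 5 mm apart
```

Real photographs enter through `seedshape extract` (Otsu threshold,
polarity auto-detection, largest component, hole filling) with a manual
two-point ruler calibration, and a manifest CSV
(`path,seed_id,species,view,group,pixels_per_mm`) drives the same `run`
verb.  Group labels are metadata you supply — the package never
classifies seeds into ornamentation groups itself.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the package's headline analytic check: it
renders twenty random convex figures (polygons and ellipses) as 512-px
masks, re-extracts their sub-pixel contours, measures solidity through the
standard pipeline, and reports the mean — for convex figures solidity is 1
by definition, so the measured value quantifies the discretization error
of the whole raster-to-descriptor path.

## Layout

- `src/seedshape/geometry.py` — contours, descriptor formulas
- `src/seedshape/silhouette_io.py` — calibration, extraction, file formats
- `src/seedshape/averaging.py` — aligned consensus silhouettes
- `src/seedshape/models.py` — cardioid model family, J index, model fitting
- `src/seedshape/synthetic_seeds.py` — the four-group seed generator
- `src/seedshape/stats.py` — CV, Kruskal–Wallis, step-down letters
- `src/seedshape/pipeline.py`, `cli.py`, `plotting.py` — orchestration
- `docs/methods.md` — models, assumptions, parameter choices, limitations
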