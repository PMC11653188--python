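# Methods

## Input contract

The pipeline consumes 8-bit single-channel TIFF/PNG rasters that an
upstream workflow (typically ImageJ thresholding of Iba-1
photomicrographs) has already binarized; `load_mask` re-thresholds at
`binarize_threshold` (default 127) so 0/255 and 0/1 encodings both work.
Multi-channel images are rejected rather than silently flattened.
Group labels and the lateral (medio-lateral) coordinate of each slice
come from a sidecar CSV (`image_id,group,lateral_mm`), never from
filename parsing. Coordinates are 0-based `(row, col)` with half-open
bounding boxes.

## Segmentation

Cells are 8-connected components by default — microglial processes are
often one pixel wide and diagonal, and 4-connectivity would shatter
them. Components under `min_area` (default 60 px², debris at 40×
magnification) are dropped. Whether border-touching cells should be
excluded is a judgment call (they are truncated, but dropping them
biases against large ramified cells); both behaviors are supported via
`border_policy`, and the default keeps them. Cell ids order components
by bounding-box top-left corner, so repeated runs on the same image give
identical ids.

## The 32 features

Five families, family-prefixed names (`Sk_`, `So_`, `C_`, `F_`, `Sh_`),
4 + 8 + 8 + 9 + 3 = 32 per cell. All lengths in pixels, angles in
degrees.

**Shape descriptors** (applied to soma, whole cell, and convex hull):
area is the foreground pixel count; the perimeter traces the
marching-squares boundary polygon (high connectivity, so 1-px diagonal
processes stay on one contour) simplified by Douglas–Peucker at 1 px
tolerance — raw marching-squares staircases overestimate smooth
boundaries by ~5%, and the simplification brings a rasterized disk's
circularity `4πA/P²` to 0.99 and a 20×10 rectangle's to 0.75 (continuum
value 0.70). Feret diameter is the maximum pairwise distance between
convex-hull vertices of the boundary. Compactness is the equivalent
circular diameter over the Feret diameter (`√(4A/π)/Feret`); no standard
formula exists, this one is dimensionless in (0, 1] and swappable.
Aspect ratio is bounding-box width/height. Orientation and eccentricity
come from the second central moments of the pixel coordinates with a
+1/12 per-axis pixel-extent term, which keeps single pixels and 1-px
lines non-degenerate; orientation is the major-axis angle from the
positive column axis in [0, 180), and eccentricity is the major/minor
axis-length ratio (≥ 1, exactly 1 for symmetric shapes).

**Soma detection.** The cell body is the largest connected component
surviving a morphological opening with a disk of radius 6 px (default;
scale with magnification). The opening erases anything thinner than the
disk — i.e. the processes — and is anti-extensive, so the soma is always
inside the cell. If the whole cell is thinner than the element the soma
falls back to the maximal-inscribed-disk component (distance-transform
peak), which is never empty.

**Skeleton.** Topology-preserving thinning to a 1-px skeleton.
Endpoints are skeleton pixels with exactly one 8-connected neighbor;
junction pixels have ≥ 3 neighbors, with touching junction pixels merged
into one junction; initial points are skeleton pixels outside the soma
that touch it (process roots). Total branch length counts skeleton
pixels outside the soma — soma-internal skeleton is cell-body medial
axis, not process — with diagonal steps weighted 1 by default (`√2` by
flag).

**Fractal dimension** is box-counting on the filled silhouette: occupied
boxes N(s) on top-left-anchored grids of dyadic side s ∈ {2, 4, …,
max(h, w)/2}, least-squares slope of log N vs log s, clipped to [0, 2].
`max` rather than `min` of the canvas sides keeps degenerate thin masks
fittable. A mask too small or too uniform for a two-point fit raises,
and the cell is flagged and excluded (with its reason logged) rather
than given a fabricated value.

**Sholl.** Circles of radius step, 2·step, … (step 10 px) around the
soma centroid, up to the largest circle that still reaches a skeleton
pixel. A crossing is one connected run of skeleton pixels inside a
circle's 1-px annulus — counting runs rather than pixels avoids
double-counting thick or tangential intersections. The third Sholl
feature is the maximum distance from the centroid to the four image
corners (an image-geometry normalizer, deliberately kept even though it
depends on the cell's position in the canvas). Since the total crossing
count must be a scalar feature, crossings are summed over circles.

## Selection, embedding, clustering

RFE drops one feature per iteration by random-forest importance
(100 trees, seeded) until half remain (16 of 32 by default). Selection
is supervised by the group column and refuses single-group tables.

Features are z-scored before UMAP: they mix px, px², degrees and
dimensionless ratios, and unscaled UMAP distances would be dominated by
area terms. The embedding defaults (`n_neighbors=10`, `min_dist=0.1`,
`n_components=2`) follow the hyperparameter choice that best preserved
structure in the motivating study; fixing the seed forces
single-threaded layout and bit-for-bit reproducible coordinates
(parallel layout is faster but non-deterministic).

HDBSCAN (`min_cluster_size=20`, `min_samples=10`) labels low-density
cells −1. Cluster ids are renumbered by descending size (ties broken by
original id) so "cluster 0" is stable across reruns. Noise cells are
excluded from the contingency table, the heatmaps and all spatial
counts.

## Spatial mapping

Painting uses the Okabe–Ito colorblind-safe palette with a reserved gray
for noise; painting is bijective (palette position ↔ cluster id), so
overlays can be read back to labels exactly. A cell belongs to the first
annotated layer polygon covering its centroid (boundary inclusive;
centroid assignment is deterministic and cheap — majority-pixel overlap
would differ only for cells straddling a boundary). Cells outside every
polygon are tallied as `unassigned`, so per-layer counts plus unassigned
always conserve the non-noise total. Lateral bins are half-open
`[0.48 + k·0.24, …)` mm by default, matching a standard 240 μm
slice-sampling series; per-bin per-cluster counts are tallied per image
first, then averaged over the images in the bin.

## Statistics

The chi-square independence statistic, expected counts and p-value come
from the standard contingency machinery (no continuity correction above
2×2; Yates by flag); both Pearson residuals `(O−E)/√E` and
marginal-adjusted residuals `(O−E)/√(E(1−row/N)(1−col/N))` are reported,
because "standardized residual" is used for either convention in
practice. Heatmaps z-score each feature over all cells (constant
features map to 0 with a warning) before averaging within cluster or
group; the per-feature between-level variance quantifies how much
structure the keys explain. The Mann–Whitney U test is exact for ≤ 8
observations per side without ties (the intended use is 4 slices per
condition) and falls back to the normal approximation otherwise;
completely tied inputs return p = 1 with a warning. No multiple-testing
correction is applied across layer × cluster tests by default.

## Synthetic cells

The generator draws a disk-derived elliptical soma (elongation
U(1.0, 1.5), random rotation) plus random-walk processes anchored on the
soma rim: per-step heading noise `tortuosity` (radians), optional one
branch per segment with probability `branch_prob` (recursive,
depth ≤ 3), dilation to `process_width`. Three presets span the
morphology spectrum: amoeboid (soma 12 ± 1.5 px, no processes — the
fully retracted state), reactive (soma 9 ± 1, 3 ± 0.8 processes of
35 ± 8 px, width 3), ramified (soma 7 ± 0.8, 6 ± 1 processes of
80 ± 12 px, width 1, branch probability 0.3). The elliptical soma is
load-bearing: with perfectly circular somata, cells of one archetype are
near-duplicates in feature space, and the embedding fragments them into
sub-modes keyed to the discrete process count; the continuous elongation
variance restores within-class unimodality, as in real cells.

Scenes place cells by rejection sampling (≤ 1,000 tries per cell) with a
minimum centroid separation and a 2-px exclusion margin so neighboring
cells never touch. Everything is driven by one `numpy` Generator seed
and is bitwise reproducible.

What the cartoons do **not** emulate: staining noise, touching/
overlapping cells, segmentation artifacts, rod-like polarized cells,
process thickness variation along a branch, and 3-D structure collapsed
into 2-D. Passing the recovery tests therefore shows the pipeline
separates genuinely distinct morphologies under clean segmentation — not
that it is robust to poor staining or touching cells.

## Problem sizes and numerical choices

Recovery checks run 300 cells (100 per archetype across 8 scenes of
1280² px) for each of 10 seeds; the feature-selection and embedding
cardinality checks use an 800-row simulated feature table; the
type-I-error calibration uses 2,000 simulated 4×4 tables of 400 cells.
Feature extraction costs ~15–20 ms per cell on one core. Degenerate
inputs fail loudly (empty masks, single-group selection, zero
contingency marginals) or are defined explicitly (single-pixel moments,
all-tied rank tests, constant-feature z-scores), never silently patched.

## Known limitations

2-D morphometry only; no process-polarity feature, so rod-like cells are
not separable from their branching level alone; soma detection depends
on one opening radius that must be rescaled for other magnifications;
perimeter (hence circularity) carries ~1–5% rasterization bias for cells
under ~10 px; layer assignment by centroid ignores cells straddling
layer boundaries.
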