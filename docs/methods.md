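# Methods

## The detection problem

Multinucleated germ cells (MNGs) — germ cells whose single cell boundary
encloses two or more nuclei — are a reproducible histopathological endpoint
of fetal phthalate exposure in the rat testis. Counting them by eye in
hematoxylin-stained thin sections is slow and requires expert training, and
even experts disagree on a fraction of calls. This package automates the
count: a convolutional network turns a grayscale section image into a
per-pixel MNG-likelihood map, and a deterministic post-processing chain turns
that map into discrete detections that are scored object-by-object against a
human reference scorer.

All images are single-channel 8-bit grayscale at a working resolution of
1 micron per pixel, so pixel areas are directly areas in square microns.

## Pipeline stages

### Panel sampling and augmentation (`panels`)

Training examples are square panels (default 512 x 512 px; desk scale
128 x 128) cut around each annotated MNG, with the MNG center placed
uniformly at random inside the panel. Random placement serves two purposes:
it decorrelates the target from panel position, and it sweeps in large
amounts of surrounding negative tissue. Each sampled panel is expanded by
the 8 symmetries of the square (identity, three rotations, four
reflections), applied identically to image and mask. Near image edges the
default policy shifts the window back inside the image (`clip_shift`); a
`reflect_pad` policy exists for images smaller than the panel.

For whole-image inference the image is covered with tiles at a configurable
stride (default half a panel); when the stride does not divide the image
size the final row/column of tiles is shifted inward rather than padded.
Overlapping tile predictions are blended by per-pixel arithmetic mean.

### Network (`network`)

The model is the canonical U-Net encoder-decoder: per level, two
same-padded 3 x 3 convolutions with ReLU, then 2 x 2 max pooling, with
filter counts doubling per level; the expanding path uses 2 x 2 transposed
convolutions and skip concatenations; a 1 x 1 convolution with a sigmoid
head produces per-pixel probabilities. Targets are the *filled* MNG areas
(not outlines), so the output is a solid heat blob per cell. Model output
p in [0, 1] is scaled to integer brightness round(255 p).

The implementation is plain numpy with hand-written forward and backward
passes (convolutions as nine shifted matrix products; the backward pass is
verified against central finite differences in the test suite). Training
uses pixel-wise binary cross-entropy and Adam (default learning rate 1e-3
at full scale, 2e-3 at desk scale; both configurable). One checkpoint is
saved per epoch, and each epoch starts from the previous epoch's weights,
so the epoch index is itself a hyperparameter searched later.

Design notes:

* Same-padded convolutions keep output shape equal to input shape (the
  original unpadded U-Net crops); full-panel heatmaps are what the
  post-processing consumes.
* `depth` and `base_filters` are configurable. The canonical geometry is
  depth 4 / 64 filters on 512 px panels; the desk-scale geometry used by
  the tests and the reproduction script is depth 3 / 8 filters on 128 px
  panels, which trains in about a minute per epoch on one CPU core.
* Determinism: parameter initialization and epoch shuffling are seeded;
  identical seeds give identical checkpoints on a given platform.

### Post-processing (`postprocess`)

A heatmap becomes detections in four steps:

1. **Brightness cutoff** — keep pixels with value >= cutoff (0-255).
2. **Connected components** — 8-connected by default (4 available).
3. **Boundary + area** — each component's outer boundary is traced through
   its pixel centers by Moore-neighbor tracing with Jacob's stopping
   criterion, and the Green's-theorem (shoelace) area of that polygon is
   computed. This area is slightly smaller than the pixel count: a solid
   w x h rectangle measures exactly (w-1)(h-1), and single-pixel or
   1-pixel-wide regions measure 0, which makes the area filter an
   aggressive speck remover. Interior holes are ignored (heat blobs are
   effectively solid).
4. **Area cutoff** — keep regions with area >= cutoff.

Both cutoffs are inclusive ("below the cutoff" is removed). Detections
carry the member pixel set, the traced polygon, the area, and the unweighted
mean of member pixel coordinates as centroid.

### Evaluation (`evaluation`)

Scoring is object-level, not pixel-level. A detection and an annotation are
candidate matches when the detection's pixels overlap the annotation's
filled polygon by at least one pixel (threshold configurable) or the
detection centroid falls inside the polygon. True positives are the
maximum-cardinality one-to-one matching over the candidate graph, computed
exactly (Hopcroft-Karp via scipy); because only the matching *size* enters
the counts, the result is deterministic and free of tie-break artifacts,
and one detection straddling two annotations still counts one true positive
plus one false negative. Precision, recall, and F1 follow the standard
definitions; F1 is defined as 0 when tp = 0 with objects present, and an
explicit error is raised when there are no objects at all. FP:FN ratios and
mean/sample-sd aggregation (n-1 denominator) match how the benchmark tables
are summarized.

### Cross-validation and grid search (`crossval`)

Slides are the unit of fold assignment (all testis slices of a slide stay
together, so per-slide conditions such as staining and lighting cannot leak
across splits). Slides are sorted by MNG count, chunked into groups of
`n_folds`, and each group is spread across distinct folds. The assignment
minimizing the variance of per-fold MNG totals is found exactly by
exhaustive search over per-group permutations when the state count is small
(<= 2e5, which covers instances around 10 slides; the first group is pinned
since fold labels are symmetric), and otherwise by a sequential greedy
search, one group at a time. The greedy path is the one exercised at the
28-slide scale of the benchmark and at the 40-scene scale of the synthetic
study.

Each of the `n_folds` fold configurations uses fold h as holdout, fold
(h+1) mod n_folds as test, and the rest for training. The grid search runs
the full predict -> threshold -> trace -> filter -> match chain for every
(epoch, brightness cutoff, area cutoff) combination, pooling confusion
counts across the test fold's images before computing F1 (per-fold pooled
counts, not per-image averages). Ties are broken deterministically: lowest
epoch, then highest brightness, then highest area — the cheapest model and
the most conservative detector. The selected triple is then applied
unchanged to the holdout fold; holdout data never participates in
selection, which the interface enforces (the selection function never sees
holdout scenes).

Default full-scale grids: epochs 1-15, brightness 100-254 step 2, areas
{10, 20, 50, 100, 150, 200, 300, 400, 500, 700, 1000}. The desk-scale study
uses a coarse grid (3 epochs x 4 brightnesses x 4 areas).

## Synthetic histology (`synthetic`)

No real slide images ship with the package, so every stage is exercised on
generated scenes that emulate the features the detector actually uses:

* light background (~205 gray) with Gaussian texture;
* mononucleated cells: one dark nucleus (~60 gray, radius 2.5-4 um) inside
  a mid-gray cytoplasm rim — rendered but *never* annotated;
* MNGs: 2-3 dark nuclei (radius 5-7 um each, large as germ-cell nuclei in
  cross-section are) packed inside one cytoplasm boundary; the annotation
  polygon is the convex hull of the nuclei dilated by the cytoplasm margin
  (3 um), and the center point is the cell center;
* additive Gaussian pixel noise (sd 3).

Object placements are rejection-sampled to avoid overlap, with a bounded
retry count. Identical configurations (including seed) render bit-identical
scenes. An `oracle_heatmap` turns a truth mask into an idealized network
output (optionally blurred and noisy) so post-processing and evaluation can
be tested in isolation from training; with no blur and no noise it is
exactly 255 x mask, and detection on it must recover every annotation with
F1 = 1.0.

What the generator does *not* emulate — and what passing tests therefore do
not show — includes: seminiferous cord architecture and densely packed
germ-cell neighborhoods, partial-volume nuclei from 5 um sectioning,
stain variability between batches, hematoxylin-dense cytoplasmic granules
that mimic nucleus edges, and the genuinely ambiguous cells on which human
scorers disagree. Synthetic results validate the machinery, not clinical
accuracy; on real sections the discrimination problem is much harder, as
the benchmark's human-scorer F1 scores (≈0.76-0.79) indicate.

## The desk-scale study (`workflows`)

The standard small study used by the test suite and the reproduction
script: 40 scenes of 192 x 192 px (one slide each, one MNG plus 15
mononucleated cells), 128 px panels, 2 random placements per MNG expanded
x8 dihedrally, depth-3 / 8-filter U-Net trained 3 epochs (Adam, lr 2e-3,
batch 4), coarse grid over 3 epochs x {100, 160, 200, 240} brightness x
{20, 50, 150, 300} area, five fold configurations. These sizes run the
entire protocol in roughly 7-8 minutes on one CPU core while leaving every
algorithmic path identical to a full-scale run. On these deliberately
high-contrast scenes the holdout F1 is expected near 1.0; the suite
requires mean holdout F1 >= 0.70.

## Numerical choices and degenerate inputs

* Grayscale conversion uses ITU-R BT.601 luma weights, rounded to nearest
  integer; resampling uses an area-averaging box filter before requantizing,
  which preserves uniform-region means to within rounding.
* Rasterization: a pixel is inside a polygon iff its integer-coordinate
  center is inside or on the boundary (even-odd rule, boundary inclusive).
  Coordinates are 0-based (x = column, y = row) everywhere.
* Heatmap stitching rounds half to even (numpy rounding) after averaging.
* `precision_recall_f1` and `fp_fn_ratio` raise typed errors on undefined
  inputs (no objects; fn = 0) rather than returning silent zeros.
* Boundary tracing of a single pixel returns a one-vertex polygon of area 0;
  empty pixel sets are rejected.
* Training determinism is best-effort: bitwise reproducibility holds for a
  fixed numpy build and platform but is not guaranteed across BLAS
  implementations.

## Known limitations

* The numpy network is CPU-bound and meant for desk-scale geometries;
  full-scale (512 px, depth 4, 64 filters, 500 panels per MNG, 15 epochs)
  training is expressible but slow without an accelerator framework.
* The matching rule (pixel overlap or centroid-in-polygon, one-to-one) is a
  reasonable object-level criterion but not the only possible one; both the
  overlap threshold and connectivity are configurable.
* Green's-theorem areas use the outer boundary only; regions with interior
  holes are measured as if filled.
* The synthetic generator's realism limits are listed above; conclusions
  about real-tissue accuracy require real annotated slides.
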