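# Methods

This note documents the models, algorithms and design choices behind
`lunggrade`, a pipeline for grading mouse lung adenocarcinoma (LUAD) in
H&E whole-slide images and relating immunohistochemical (IHC) staining to
the resulting grade maps.

## Pixel taxonomy and coordinate conventions

Every pixel carries one of seven classes: Background, Normal alveoli,
Normal airway, and LUAD Grades 1–4 (mouse grading scale, Grade 1 lowest).
Rasters are row-major with 0-based (row, col) coordinates; physical areas
are pixel counts times the squared resolution (µm/px, reference
0.5022 µm/px from a 20x scan). Transform matrices act on (x, y) = (col,
row) homogeneous coordinates, as in scikit-image.

## Stain normalization (Macenko)

Working space is base-10 optical density, `OD = -log10(I / I0)` with
`I0 = 255` per channel by default (configurable). Tissue pixels are those
with OD norm above the floor β = 0.15; at least 100 are required. The two
stain directions are the α / (100−α) percentile angles (α = 1 by default)
of tissue pixels projected into the top-two right-singular plane of the
OD cloud. Hematoxylin is the column with the larger red-channel OD
component — hematoxylin looks blue because it absorbs red — which gives a
deterministic ordering without user input. Concentrations are recovered
by least squares; normalization rescales each stain's 99th-percentile
concentration to the reference value and re-composites with the reference
stain matrix (the widely used H&E reference vectors; concentrations on
the base-10 scale). A rank-1 OD cloud (grayscale input) has no stain
plane and raises a collinearity error rather than returning a degenerate
basis.

α and β are not fixed by any measurement here; they are the conventional
defaults and are explicit function arguments. A fitted `StainModel` can
be serialized to JSON and supplied as an alternative reference.

## Patch library

Slides are tiled into size×size patches (default 224 px ≈ 112 µm);
right/bottom remainders are reflection-padded on the image, with padded
label pixels set to Background so they never vote or contribute loss.
Each patch's dominant class is its modal non-Background label; ties break
toward the higher grade (rare high-grade patches should not be diluted),
then airway over alveoli. Slides are assigned to train/validation/test
(60/20/20) *before* patch selection by a seeded greedy heuristic on
per-slide annotated area, so no slide ever spans two splits; per-class
selection up to the quota (default 6000) is a seeded draw without
replacement.

Area balancing appends augmented copies of patches whose dominant class
is the most deficient one until every class's pixel area is within the
tolerance (default 5%) of the maximum. Augmentations are a joint
geometric transform of image and labels (nearest-neighbor labels):
translation up to a quarter of the patch (56 px at 224), shear up to 10°,
and rotation of 90/180/270° ± 10°, with reflection fill. Copies are drawn
from the purest quartile of the deficient class's patches — appending
impure copies raises the majority class almost as fast as the deficient
one and can make balance unreachable. If a copy fails to improve the
class's area ratio (sources too impure) or the copy cap is hit, the class
is left unbalanced with a warning; exact balance is guaranteed only when
supply allows.

## Grading network

A fully-convolutional per-pixel six-class classifier implemented directly
on NumPy (im2col convolutions with explicit backward passes, float32,
single CPU, deterministic under a seeded generator):

- residual encoder with ReLU-only pre-activation blocks; the stem and the
  inter-stage convolutions downsample by 2 each, so total downsampling is
  `2**encoder_depth`;
- one atrous context convolution followed by atrous spatial pyramid
  pooling: parallel dilated 3×3 branches (default rates {2, 4, 8}) whose
  concatenation is pooled by the next 1×1 convolution. A *rate* here
  counts skipped pixels between samples, so a rate-4 3×3 kernel spans an
  11×11 region (standard dilation = rate + 1);
- a transposed-convolution decoder (kernel = stride = total downsampling,
  an exact-tiling upsample) followed by a 3×3 convolution and the 1×1
  six-way head.

Two presets: `faithful` mirrors published-scale stage widths
(64/128/256/512, depth 4) and exists as configuration; `desk`
(depth 2, base width 8–16, ≪ 200k parameters) is what the test suite
trains. Loss is pixelwise cross-entropy with uniform class weights — the
library is pre-balanced by area — and Background pixels are excluded from
the loss because the classifier never predicts Background: non-tissue is
masked afterwards (OD norm ≤ 0.15 ⇒ Background). Training uses Adam on
shuffled minibatches with a fixed learning rate (the canonical
configuration is 20 epochs, 128-patch minibatches, lr 0.01; no schedule
or weight decay), per-epoch validation pixel accuracy, and returns the
best-validation weights. Non-finite loss aborts with a diagnostic.

Whole-slide inference tiles the image with overlapping tiles (default
stride 112 = half a tile), averages the per-pixel class probabilities
across overlaps, takes the argmax, and applies a window-wise modal filter
(default 5×5). Both steps target classification artifacts at patch edges;
with stride = tile and window 1 the result equals plain per-patch argmax
on tissue. Inputs must be divisible by the downsampling factor; there is
no implicit resizing.

## Tumor analytics

Tumors are connected components of the union of Grade 1–4 pixels
(default 8-connectivity; 4 is available). Normal tissue severs
components; normal holes inside a tumor are not filled and are excluded
from composition, which therefore sums over graded pixels only.
Components below `min_pixels` (default 1) are dropped; ids are assigned
in (top row, left col) order.

The overall tumor grade is the highest grade whose share of the tumor's
graded area is at least the threshold (default 10%, boundary inclusive),
the same rule human raters use; with a threshold ≤ 25% the rule is always
decidable. Intratumor heterogeneity is the Shannon diversity index
`SDI = −Σ p_i ln p_i` in nats over the present grades (0·ln 0 := 0), so
0 means monomorphic and ln 4 maximal four-way mixing. Slide summaries
report lung area (all non-Background pixels), tumor burden (tumor over
lung area), and per-grade tumor areas both by overall-grade attribution
and by raw pixel grade (both sum to the same total).

## Rater agreement and detection metrics

Tumor-level agreement uses a confusion matrix over the ordered categories
Normal < Grade 1 < … < Grade 4; a rater who never used a category gets
zero marginals rather than a dropped row. Cohen's kappa is
`(p_o − p_e)/(1 − p_e)`; the linear-weighted variant uses
`w_ij = 1 − |i−j|/(k−1)`. The standard error is the large-sample
(Fleiss–Cohen–Everitt) estimate with a normal 95% CI; the identity-weight
case reduces to the usual unweighted formula. The CI method is
documented as approximate (asymptotic, not bootstrap).

Manual-tumor matching: a manually segmented region counts as detected iff
at least one pixel inside it carries a tumor grade; its automated overall
grade applies the ≥10% rule to the in-region grade composition, and
undetected regions are recorded with the modal normal class inside them.
Pixel-level agreement uses area-based precision/recall/F1 per class with
a pooled micro average; zero-denominator metrics are reported as missing,
never as 0. Effect sizes follow Cohen's `d = (x̄₁ − x̄₂)/s` with pooled SD
and the rank-test standardized `r = z/(n₁ + n₂)`.

## IHC integration

Registration maps IHC coordinates to the H&E frame in three stages. The
*rigid* stage is a correlation search: both images become smoothed
tissue-on-dark grayscale maps (a light blur turns stain-specific detail —
nuclear point patterns vs. H&E texture — into comparable tissue-density
maps); on 8×-downsampled copies, a rotation grid (±15°, 1° coarse then
0.1° fine) with per-angle phase-correlation translation is scored by
warped mean-squared error, followed by a full-resolution subpixel
translation polish. The *affine* stage perturbs the rigid solution by a
6-parameter matrix fitted with L-BFGS capped at 20 iterations and small
bounds — applied lightly to avoid undesired deformation — and is rolled
back if it does not improve the fit or would introduce a reflection. The
*local* stage estimates one residual translation per tumor by phase
correlation over the tumor's bounding box expanded by the search radius
(default 50 px); shifts beyond the radius or from flat windows are
rejected. Manual per-tumor offsets can be substituted where automated
refinement is not trusted.

Cells are detected by H-DAB color deconvolution (base-10 OD,
least-squares unmixing against the standard hematoxylin and DAB vectors),
nuclei as local maxima of the smoothed hematoxylin + DAB OD with a
minimum separation, and a cell is DAB-positive iff its mean DAB OD in a
3-px-radius disk exceeds 0.2 OD. All thresholds are arguments. Detected
cells are mapped through the composed transform, assigned the grade-map
class at their landing pixel and the containing tumor if any;
out-of-bounds cells are dropped and counted.

Tumors below 2000 µm² or with fewer than 50 assigned cells are excluded
(boundaries: exactly 2000 µm² and exactly 50 cells are kept — the printed
rules exclude strictly-less / strictly-fewer). For each eligible tumor
the expected positive count per grade region is the tumor's total
positives times that grade's area fraction among graded pixels, and
`G = 2 Σ O_i ln(O_i/E_i)` (0·ln 0 := 0) is referred to a chi-squared
distribution with df = (grades with positive expectation) − 1 — the
expectations consume one constraint because they derive from within-tumor
area fractions. Tumors with no positives or a single grade are
not-testable rather than significant or p = 1. Significance is p < 0.01.
Both `O_i/E_i` and its log are reported, since either may be the quantity
a reader wants to plot. A tumor counts as "positively stained" iff its
positive-cell fraction is at least 5% (explicit knob; the notion is
otherwise underdetermined).

## Synthetic fixtures

The generators exist so every stage is testable with no external data,
and they define the conditions under which the test suite's claims hold.

- **Texture tiles**: each class is a distinct hematoxylin/eosin
  concentration pair plus a spatial motif (sparse septal lattice for
  alveoli, concentric rings for airway, nuclear stippling whose density
  rises with grade), rendered through the same H&E stain matrix the
  estimator assumes. Mean hematoxylin OD rises strictly from Grade 1 to
  4. The palettes are deliberately separable — a linear classifier on
  color histograms exceeds 95% accuracy — so network benchmarks measure
  pipeline wiring, not representational capacity. Passing them says
  nothing about accuracy on real histology, where class appearance
  overlaps heavily.
- **Slides**: a lung ellipse of alveolar texture, ring-textured airway
  discs, and disjoint circular tumors partitioned by angle into grade
  sectors matching a specified composition (±2% discretization). The
  randomized layout guarantees all four grades per slide (first four
  tumors cycle the pure grades; extras are mixed mosaics).
- **IHC patterns**: cells placed by seeded dart throwing (uniform in
  tissue with a minimum separation of 2.5 nucleus radii), positive with
  probability baseline × per-grade enrichment (clipped to [0, 1]),
  rendered as hematoxylin disks with DAB disks on positives using the
  same H-DAB vectors as the detector — so the detection oracle is exact
  by construction.
- The published 5×5 rater-agreement count table (1958 tumors) ships as a
  printed fixture with its row/column totals asserted.

## Problem sizes in the test suite

The suite and the acceptance script run on one CPU in minutes by scaling
the *data*, never the claims: the training benchmark uses 12 synthetic
slides of 416×416 px, 64-px tiles at stride 48 (64 px is a supported tile
size; 224 remains the default), a base-width-16 desk network, and 18
epochs of Adam at 3e-3 on 8-patch minibatches, reaching ≥ 95% held-out
pixel accuracy in a few minutes. The learning rate is below the canonical
0.01 because the desk network trains without normalization layers on
small minibatches, where 0.01 is unstable. Enrichment simulations use
maps at 2 µm/px with two mixed-grade tumors per map (~250 cells each at
6000 cells/mm²), 3× Grade-4 enrichment over a 15% baseline, and 20 seeds.

## Known limitations

- The faithful-scale network is provided as configuration but is not
  trained anywhere in the test suite; no claim is made about reproducing
  published real-data accuracy, which requires the original slides and
  weights.
- Registration handles rotation ±15°, translation, and mild affine
  refinement; large deformations, tears and folds are out of scope, and
  the local stage corrects translation only.
- Cell detection is a deliberately simple maxima-plus-threshold scheme;
  on real DAB slides with touching nuclei or vesicular chromatin a
  dedicated segmenter should replace it (the interface is the
  `CellRecord` list, so substitution is local).
- Kappa confidence intervals are asymptotic; for small tables a bootstrap
  would be preferable.
- The stain estimator assumes exactly two stains; necrosis, pigment or
  mounting artifacts violating the two-stain model bias the percentile
  directions.
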