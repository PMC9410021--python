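# Methods

`spine-uda` implements a two-stage pipeline for locating and naming vertebrae
in spine CT, with an unsupervised domain-adaptation (UDA) scheme that lets the
identification stage adapt to a new scanner/protocol ("target" domain) without
target labels.  This note records the model, its assumptions, the parameters
that matter, and the design decisions taken where the design was genuinely
open.

## Pipeline overview

**Stage 1 — detection.**  A binary segmenter labels every voxel spine /
background.  Training patches of `[80 x 80 x 96]` voxels are cut from labeled
scans (10 per scan, at least 8 containing spine voxels) and the model is
trained with Adam (lr `1e-3`, batch 16, 70 epochs by default) on a
class-weighted binary cross-entropy: weight 1.0 for spine, 0.1 for background.
The asymmetric weighting deliberately over-detects the spine so that it
survives post-processing as one large component.  At test time the scan is
tiled without overlap, tiles are reassembled, probabilities are thresholded at
0.5 (ties labeled spine), and a 3D connected-component analysis
(26-connectivity) keeps only the largest component.  Bright but compact
structures — the classic failure case is the scanner bed — are discarded as
artefacts.  Ties between equal-sized components go to the component whose
first voxel comes earliest in scan order.

**Stage 2 — identification.**  A per-pixel regressor predicts a *continuous*
vertebra value on the sagittal plane (1 = C1 … 26 = S2); rounding half-up
yields the label.  Regressing a continuous value lets a plain L1 loss respect
vertebra order: for true label C1, predicting C2 costs less than predicting
C3.  Patches are `[8 x 80 x 320]` (a thin sagittal slab with a wide
craniocaudal field of view), 300 per labeled training scan, each guaranteed to
contain a vertebra; unlabeled scans sample patches from the detected spine
region instead.  Predictions are multiplied by the detection mask, so the
background is exactly 0.  Dense predictions are converted to centroids by the
per-axis *median* voxel coordinate of each label, which ignores outlying
pixels.

**2-way training.**  Training alternates strictly between (S) a labeled
source mini-batch optimized with L1, and (T) an unlabeled target mini-batch
optimized with the Domain Sanity Loss below (Adam, lr `5e-4`, batch 32,
100 epochs by default).  With an empty target stream the procedure reduces —
bit-exactly — to the supervised baseline.  Optionally, a few labeled target
scans join the source stream ("semi-supervised" arm).  Each stream keeps its
own Adam state: the two loss families have gradient magnitudes several orders
of magnitude apart, and a shared second-moment estimate lets either stream
stall the other.  A separate target-stream learning rate is exposed
(`target_learning_rate`, default equal to the source rate).

## The Domain Sanity Loss

Let ŷ be the detection-masked sagittal prediction with rows *i*, columns *j*
(columns run craniocaudally), `n_pix` its pixel count.  A pixel is a *spine
pixel* if its value rounds to a vertebra (ŷ ≥ 0.5); for integer label grids
this coincides with "nonzero".  Four label-free anatomical checks are
combined as

```
L(wm, ŷ) = c1·s1 + c2·s2 + c3·s3 + c4·s4,
c1 = 20, c2 = 1, c3 = 1/40, c4 = 1/100.
```

* **s1 — craniocaudal order.**  For every shift s = 1..n_shift (default 30)
  and every same-row pair (j, j+s) of spine pixels, a violation is counted
  when ŷ(i,j) − ŷ(i,j+s) > 0; the count is divided by `n_pix`.  Strictly
  positive differences are violations — equal values inside one vertebra are
  not (a strict margin and the literal ≥ variant are configurable).
* **s2 — column consistency.**  Pixels orthogonal to the spine should share
  one label; the per-column median over spine pixels is taken as the column's
  label and deviating spine pixels are counted, again divided by `n_pix`.
* **s3 — inter-centroid distances.**  Rounded labels are reduced to centroids
  (median coordinate, in mm); for every adjacent pair (k, k+1) present, the
  absolute deviation of the Euclidean centroid distance from a reference
  table is accumulated and divided by 25 (the number of adjacent pairs of a
  full spine).  The reference table ships as an editable YAML resource with
  literature-plausible adult values (cervical ≈ 18 mm, thoracic 22–28 mm,
  lumbar 30–35 mm); integer mm defaults keep median recovery exact on 1 mm
  grids.
* **s4 — shift check via a weak mask.**  An unsupervised Felzenszwalb
  segmentation of the thresholded (180 HU), detection-masked image yields a
  *weak mask* of vertebra-like components; for each component the number of
  distinct nonzero rounded labels minus one is accumulated and divided by the
  component count.  A prediction that is internally consistent but spatially
  shifted along the spine straddles component boundaries and is caught here —
  the one check the first three cannot perform.

**Exact vs surrogate mode.**  The four checks are counting losses with zero
gradient almost everywhere.  Exact mode (evaluation, tests) implements the
counts literally.  Surrogate mode (training) replaces s1 by the mean positive
part of the pairwise differences and s2 by the mean absolute deviation from a
*detached* column median; both are zero exactly when their exact counterparts
are zero, and their subgradients are verified against finite differences.
s3/s4 involve medians and unique-counts of rounded values; they are evaluated
exactly for monitoring but contribute no gradient.  This is an explicit
design decision, not a reconstruction of the original training internals.

**Weak-mask construction.**  Computed in 2D on the sagittal plane: the scan
is collapsed over the thin slab axis (mean intensity — a maximum projection
would let noise peaks pierce the 180 HU threshold and bridge neighbouring
vertebrae), multiplied by the detection mask, thresholded at 180 HU, and
segmented with Felzenszwalb-Huttenlocher (scale 100, sigma 0.8,
min_size 150; tuned on phantoms — the `min_size` floor absorbs the thin
boundary-gradient fragments the internal smoothing produces around strong
edges while staying below the smallest plausible vertebra face).  Segments
dominated by zero-intensity pixels are background; survivors are filtered by
area (25–5000 px) and bounding-box aspect ratio (≤ 3), and components whose
bounding box lies inside another's are merged.  The mask is deliberately
imprecise; it is a consistency reference, never ground truth.

## The phantom generator

All tests and the end-to-end demo run on synthetic spine phantoms:

* a chain of bright cuboid "vertebrae" (700 HU) whose centroid spacing
  follows the same reference-distance table the loss uses, centred in a
  soft-tissue background (40 HU) with Gaussian noise (sd 15 HU);
* cuboid extents come from a per-vertebra size table (odd integer mm), leaving
  a ≥ 20 % inter-vertebral gap so unsupervised segmentation resolves
  individual vertebrae;
* a continuous sub-threshold "posterior element" bar (165 HU, 13 x 13 mm
  cross-section, sagittally offset behind the bodies) bridges the cuboids so
  the spine forms a single 26-connected component, as real vertebrae do via
  discs and posterior elements; it stays below the 180 HU weak-mask threshold
  so vertebrae remain separable.  The bar is row-symmetric and its ends
  overhang the first/last centroid by exactly half the adjacent reference
  distance, which keeps the per-label median of sagittal projections exactly
  on the centroid — ground-truth labels therefore score exactly zero on all
  four sanity checks;
* an optional bed artefact: a thin bright (400 HU) slab spanning the grid,
  disconnected from the spine;
* a **target-domain** variant: global intensity scale 0.9, noise sd 60 HU,
  and a random crop of up to 8 columns — the kinds of shift a scanner or
  protocol change induces.  These distribution-shift settings are the study
  conditions of every adaptation experiment in the package and are fixed.

What the phantom does **not** emulate: real CT texture, anatomy-shaped
vertebrae, pathologies, rotation/scoliosis, partial-volume effects, scanner
physics.  Passing tests therefore demonstrate the *mechanics* of the method —
the loss terms measure what they claim, post-processing removes artefacts,
the adaptation signal has the right direction — not clinical performance.

## Default trainable models

The pipeline defines model *contracts* (detection: 3D patch → per-voxel
probability; identification: patch → continuous sagittal plane), and ships
small default networks: a fixed featurizer followed by a trainable pixelwise
MLP (one tanh hidden layer) with hand-written Adam and backpropagation,
fully seeded and bit-reproducible.  Detection features are multi-scale box
means (1, 3, 7, 13 voxels) of the HU volume — the larger scales provide the
context that separates dim voxels *surrounded* by bone (posterior elements)
from bright but isolated structures (the bed).  Identification features are
the sagittal maximum projection at three Gaussian scales plus the absolute
row/column mm coordinate of each pixel (patch origin + index), giving the
tiny model the spatial context a large-receptive-field CNN would learn.  The
identification output is scaled by a gain of 10; larger gains amplify Adam's
per-step jitter of the global offset to a size comparable with the rounding
margin and destabilize training.  Architecture fidelity to any particular
U-Net is explicitly out of scope.

## Numerical choices and edge cases

* mm positions are voxel index x spacing, origin at voxel (0,0,0); centroid
  files store mm so the 20 mm evaluation threshold is spacing-independent.
* Rounding of continuous predictions is half-up; values above 26 clip to 26;
  on-mask values rounding to 0 floor to 1 (a spine pixel cannot be
  background).  Masking and rounding commute.
* Overlapping dense-label boxes assign contested voxels to the nearer
  centroid, ties to the lower id.
* Detection binarization threshold 0.5, ties labeled spine; component
  analysis uses 26-connectivity; equal-size component ties keep the earliest
  component in scan order; an empty mask passes through with a warning.
* `n_pix` (total pixels) normalizes s1/s2 as published even though the result
  is described as a fraction of spinal pixels; a spine-pixel normalizer is a
  config flag.  Zero weak-mask components define s4 = 0.
* Population (divide-by-n) standard deviation in centroid distance stats.
* Identification rate matches by vertebra id only — label-swapped
  predictions count as errors; the 20 mm threshold is inclusive.
* Segmentation metrics report the vertebra class and a micro-average over
  both classes ("overall"); dice = 2·IoU/(1+IoU) holds for every reported
  pair.

## The scaled-down demonstration experiment

Reproducing the original experiments needs two real CT corpora and days of
GPU training; the package instead asserts the *orderings* the method claims,
on phantoms sized for a single CPU.  Problem sizes: 33 x 64 x 224 voxel
phantoms with 6 thoracic vertebrae (T3–T8); 4 source + 4 target training
scans, 3 held-out target scans; detection patches 16 x 16 x 24, lr 2e-2,
40 epochs; identification patches 8 x 32 x 160, 40 per scan, lr 5e-3
(target stream 2e-3), batch 16, 35 epochs.  Three arms share one detector
and one seed per replicate: source-only baseline, + sanity loss on the
unlabeled target stream, + 2 labeled target scans.  Across three seeds the
suite asserts that post-processing does not reduce detection IoU, that the
sanity loss raises target per-pixel accuracy over the baseline in at least
2 of 3 seeds, and that the labeled-target arm does not reduce the mean
identification rate.  In a typical run, target-domain per-pixel accuracy
moves from ≈ 0.57 (baseline) to ≈ 0.71 (with adaptation) and detection
vertebra IoU from ≈ 0.70 to ≈ 0.85 after post-processing.

A finding of this scaled-down setting worth recording: the labeled-target
arm matches the adaptation arm on identification rate but does not improve
per-pixel accuracy here — with a pixelwise model that sees absolute
coordinates, labeled target scans whose random crop shifts the
coordinate-to-label mapping add supervision noise that a convolutional
architecture would not experience.

## Known limitations

* The surrogate loss drives adaptation through s1/s2 only; s3/s4 influence
  training only by monitoring.  A uniform relabeling of the whole spine by
  ±1 is undetectable by *any* of the four checks — label-free sanity checks
  cannot anchor absolute identity; that anchor comes from the shared model
  and the source stream.
* Reference distances are adult population averages; patients deviating
  from them (children, anomalous lumbosacral anatomy) violate the s3
  assumption.  Per-patient scaling (ratios instead of absolute distances)
  is out of scope.
* The default networks are deliberately tiny; they demonstrate the training
  machinery, not attainable accuracy.
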