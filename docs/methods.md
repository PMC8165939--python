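# Methods

## The Delta segmentation model

A well's time-lapse is a sequence of grayscale frames `I_1 … I_T` (unsigned
integers, one frame per hour by default). The method assumes the scene
decomposes into a static background — vessel, illumination gradient, halo
rings, dust — and a single slowly growing or moving foreground object. For
each consecutive pair the pipeline computes the **Delta image**

    D_t = | G_σ(I_t) − G_σ(I_{t−1}) | ,    t = 2 … T,

where `G_σ` is an optional Gaussian pre-smoothing (σ = 1 px by default).
The subtraction is done in floating point, so no unsigned wraparound can
occur, and the *absolute* difference is used: a spheroid edge both darkens
(body) and brightens (phase halo) as it advances, so both signs of change
mark motion. Static pixels give exactly zero and are classified as
background; pixels with `D_t ≥ threshold` (default 1 native intensity unit,
i.e. any nonzero integer change) are classified as moving spheroid. Each
Delta is assigned to the *later* frame's timepoint — the mask describes
where the spheroid is now — so a T-frame series yields T−1 masks and
tables start at the second timepoint.

The raw thresholded Delta is a thin motion band plus isolated noise. It is
refined into one mask per timepoint by: (1) removing 8-connected components
smaller than `min_object_area` (default 50 px²); (2) dilating survivors by
a disk of `expansion_radius` (default 5 px) — the pixel expansion that
recovers the object's body from its advancing edge; (3) filling holes;
(4) keeping the largest component (configurable to keep all). The centroid
is the mean pixel coordinate of the final mask. An empty survivor set is a
flagged state (`empty=True`), not an error: a static scene legitimately
produces no mask.

**Global-shift guard.** A medium change or illumination jump shifts every
pixel at once and would masquerade as scene-wide motion. The median Delta
value is background-dominated and near zero for an honest pair of frames,
so any Delta whose median exceeds `intensity_guard_multiple` (default 10×)
times the series-typical median — with a floor of one intensity unit — has
its mask marked `low_confidence` rather than silently used. The median was
chosen over a high quantile because a legitimate motion band already pushes
high quantiles to tens of intensity units, leaving no headroom within an
8-bit range for a multiplicative trigger.

## Morphometry

Features are measured on the refined Delta mask (not the raw frame) with
standard region properties: area (px², and µm² when a pixel size is
supplied), perimeter, form factor 4πA/P², eccentricity, solidity, extent,
moment-ellipse major/minor axis lengths, and width-to-length ratio
(minor/major). The perimeter uses the Crofton estimator (4 directions):
for smooth rasterized outlines it is accurate to well under 2%, whereas
pixel-edge counting overshoots a disk's perimeter by ~5% and would bias the
form factor of a perfect disk down to ≈ 0.91. Empty masks produce
empty-flagged records with missing feature values; downstream profiling
excludes them.

## Divergence profiling

Because features mix units and scales, each is z-scored over all non-empty
(well, timepoint) records; zero-variance features are dropped with a
warning. PCA is fit on the pooled records of the full time course and the
per-timepoint slices of the first two component scores quantify condition
separation: the Euclidean distance between condition centroids and the
silhouette score of the condition labelling at that timepoint. Pooling the
fit keeps all timepoints in one coordinate system, so distances are
comparable along the trajectory; slicing per timepoint is what turns
"morphologies diverge" into a number. A 10-timepoint centred rolling mean
(edges truncated) smooths the distance trajectory. The PCA sign convention
— each component's largest-magnitude loading is positive — makes results
independent of record order and run-to-run reproducible.

## Phenotype classifier

Each segmented timepoint contributes one training image: a square crop of
the raw frame centred on the Delta-mask centroid (empty masks fall back to
the frame centre, counted by the dataset builder). The crop (default
224 px, padded at frame borders) must contain the whole object at its final
size — a crop that sees only the interior makes the phenotypes
indistinguishable — and is rescaled to [0, 1] by the dtype range. A config
switch crops the mask silhouette instead of the raw frame.

The network is a compact, fully deterministic numpy implementation: a 3×3
convolution expanding 1→3 channels (so single-channel microscopy images
feed an RGB-style trunk), three conv/ReLU/max-pool blocks (8, 16, 32
channels), global average pooling and a 2-class linear softmax head.
Inputs are bilinearly resized to the network's working size (default
96 px, must be divisible by 8) and centred on the train-set mean intensity;
without that centring the constant background term dominates early
gradients and the optimiser stalls at the chance plateau. Training
minimises mean cross-entropy with Adam (default lr 2·10⁻³, batch 32, 10
epochs), with random horizontal/vertical flips and a random 87.5% crop
resized back as augmentation; evaluation applies none. Weight
initialisation, shuffling and augmentation all derive from one seed, and
identical seeds reproduce identical weights bit for bit. Checkpoints are
snapshotted every `checkpoint_every` steps; the final checkpoint's curve is
reported and all checkpoints are stored.

**Leakage control.** The train/evaluation split is decided at the well
level: all timepoints of `n_holdout_wells_per_group` wells per condition
(default 4) form the evaluation set. Consecutive frames of one spheroid
are nearly identical, so an image-level split would leak; `evaluate`
re-checks the disjointness and raises on any overlap. The readout is
accuracy per timepoint over held-out wells plus a 10-timepoint centred
rolling mean.

## The synthetic phantom

The generator emulates the phenomenology the pipeline consumes, not the
optics. A phantom well is a disk of radius `initial_radius + (t−1)·
growth_rate` (defaults 12 px, 0.5 px/h, 96 hourly frames at 256×256,
8-bit) with a dark interior (level 80) and a bright 2-px phase rim
(background 180 + 40), drifting by per-frame Gaussian centroid jitter
(σ = 0.5 px). The branched phenotype is identical until `branch_onset`
(default t = 20), after which `n_branches` (3) elliptical lobes grow
outward at `branch_growth_rate` (0.6 px/h) along axes drawn once per well —
budding happens at fixed neck regions, so the morphogenesis axes are
static. The static background carries a bright halo ring at 45% of the
frame side and 30 dust specks placed outside it; both are identical in
every frame and deliberately independent of the phenotype's geometry, so
matched round/branched configurations share one background and a
classifier cannot separate the classes by their artifacts. Per-frame
i.i.d. Gaussian noise (σ = 2 by default) is added last and clipped to the
dtype range.

All randomness flows through independent streams (jitter, dust, lobe axes,
noise) spawned in a fixed order from the config seed, so matched
configurations are pixel-identical before the branch onset — the property
that forces early-timepoint classification to sit at chance. Ground truth
records the per-timepoint foreground mask, its pixel-counted area, the
true centres and the static artifact mask. `generate_plate` lays out round
wells in plate columns 1–3 and branched wells in columns 10–12 (the
left/right layout of a two-condition screen) and derives a distinct child
seed per well; the defaults produce 18 + 18 wells of 96 frames.

Validation enforces that the object stays inside the frame and never
reaches the halo ring (otherwise artifacts would stop being static). The
disk is rasterized about the true raster centre ((h−1)/2): pixel-counted
areas then stay within 2% of πr² for radii ≥ 10 px, whereas a
lattice-aligned centre produces isolated Gauss-circle excursions above 2%.

What the phantom does *not* model: phase-contrast point-spread optics,
cell-scale texture, focus drift, spheroid fusion or detachment, and
medium-change intensity shifts (the guard is exercised with synthetic
jumps instead). Passing tests therefore demonstrate the pipeline's
mechanics and its claimed invariants — background cancellation, late
divergence, chance-level early accuracy — not robustness to every
real-world acquisition artifact.

## Problem sizes and numerical choices

The full-scale checks (tests and `scripts/acceptance.py`) use the plate the
generator defaults describe: 36 wells × 96 timepoints at 256×256 — 3 420
segmented records — with PCA over all records and classifier training on
the 28 non-held-out wells (2 660 crops, 10 epochs). Delta arithmetic is
verified exactly against a double-loop reference on 100 random 32×32
pairs. Shape recovery uses analytic figures (disk r = 30, rectangle
20×80). Chance bands for early-timepoint accuracy come from the binomial
distribution over the 8 held-out wells scored at each timepoint.

Degenerate inputs are contracts, not crashes: series shorter than two
frames, single-class training sets, all-empty feature tables and oversized
PCA ranks raise informative errors; empty masks, empty records and
single-condition timepoints are flagged or skipped with warnings.
Tie-breaks are deterministic throughout (largest component by pixel count,
PCA sign convention, mergesort for table ordering).

## Known limitations

- One object per well is assumed; multi-spheroid wells collapse to the
  largest moving component.
- The Delta mask of a growing object is its motion band dilated outward,
  so mask area systematically exceeds the object's true area; comparisons
  across conditions are valid because the bias is shared.
- If growth stalls below the motion-detection floor (ring area under
  `min_object_area`), timepoints come back empty; longer frame intervals
  are the remedy, as the acquisition guidance suggests.
- The classifier is desk-scale by design; it demonstrates the
  accuracy-over-time property on phantoms and is not a tuned architecture
  for real microscopy.
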