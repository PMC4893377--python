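# Methods

## Problem setting

Slit-lamp video of the retina shows, in each frame, a narrow vertical band
of illuminated fundus surrounded by darkness, with glare blobs from the
optical path, border illumination falloff, and sensor noise.  The goal is
to segment the usable content of every frame, recover the global 2-D
position of every frame, and composite all frames into one wide-field
mosaic.  Motion is modeled as pure translation: at slit-lamp magnification,
rotation about the optical axis and perspective distortion are small enough
to neglect, and modeling them is explicitly out of scope here.

## Slit segmentation

Foreground is estimated per pixel by gradient-boosted regression trees with
a squared loss on 0/1 labels: 200 boosting rounds, shrinkage 0.1, row
subsampling 0.5, maximal tree depth 3.  Frames are downscaled by a factor
of 4 (local averaging) before feature extraction, which suppresses sensor
noise and cuts the training cost 16-fold.  Three feature scenarios are
supported:

| scenario | planes | content |
|---|---|---|
| A | 9  | RGB, CIELAB, HSV |
| B | 11 | A + normalized x, y pixel coordinates |
| C | 21 | A + Gabor bank (3 scales x 4 orientations) |

Scenario B exploits the fact that the slit sits near the frame center;
scenario C measures oriented texture energy, which separates content
(vessels, fundus granularity) from featureless glare.  Choices the
underlying procedure leaves open, fixed here as package defaults:

* every plane is rescaled to [0, 1] (Lab from its nominal gamut, Gabor
  magnitudes by each kernel's L1 norm) so tree splits see comparable ranges;
* the Gabor bank uses orientations 0°, 45°, 90°, 135° and octave-spaced
  wavelengths of 4, 8 and 16 px on the downscaled grid;
* raw regression outputs are clipped to [0, 1] and read as votes; the
  binary mask is `upscale(gaussian(votes, 2 px) >= 0.5)` with
  nearest-neighbor upscaling — threshold 0.5 and smoothing scale 2 px are
  configurable defaults, and the smoothing is what removes isolated vote
  spikes (e.g. glare borders) before thresholding;
* all downscaled pixels of every annotated frame enter training (no
  subsampling beyond boosting's own 0.5 row subsample).

The fixed color threshold `r - 0.7 g > 0` is provided as the comparison
baseline; on footage with glare its false-positive rate is structural
(white glare satisfies the inequality), which is exactly what the learned
model improves on.

## Pairwise registration

Keypoints are difference-of-Gaussian blobs (sigma 1–6 px) detected on the
grayscale frame divided by a heavily smoothed copy of itself
(`gray / (gaussian(gray, 15 px) + 0.1)`).  This local illumination
normalization counteracts the slit's border falloff so that the same
retinal detail looks alike regardless of where in the slit it appears.  The
additive 0.1 in the denominator is deliberate: without it, barely-lit
pixels get divided by a near-zero illumination estimate, sensor noise is
amplified into strong frame-fixed pseudo-features at the slit border, and
those can form spurious zero-motion consensus between frames that do not
overlap at all.  The detection threshold is set low (0.02) so that many
interest points survive; only keypoints inside the frame's foreground mask
are kept.

Descriptors are 512-bit BRIEF patterns (patch 25 px, fixed sampling seed),
which are computed without any orientation normalization — upright by
construction, matching the no-rotation motion model.  Matching is
nearest-neighbor in Hamming distance with cross-checking and a Lowe-style
ratio test at 0.8.

RANSAC over translations: each hypothesis is the displacement of a single
match; matches within 3 px (Euclidean) are inliers; the best hypothesis is
refined as the mean displacement over its inliers, with ties between equal
inlier counts broken toward the smaller refined RMS residual.  When a pair
has no more matches than the iteration budget (100), every match is tried
as a hypothesis, which is deterministic and dominates random sampling;
otherwise 100 hypotheses are drawn with a seeded generator.  A pair is
accepted only with at least 6 inliers — fewer correspondences indicate a
non-overlapping or unusable pair.  "6 correspondences" is interpreted as 6
RANSAC inliers, not raw matches, since only inliers support the estimated
transformation.

## Bundle adjustment

Each accepted edge (i, j, Δ) adds one row per axis to a sparse system:
+1 in column i, −1 in column j, right-hand side Δ, encoding
`x_i − x_j = Δx` (and likewise for y; both axes share the matrix and are
solved independently).  The translation gauge — adding any constant to all
positions preserves every constraint — is fixed by pinning frame 0 (or a
chosen anchor) at the origin and dropping its column, after which the
system has full column rank on the anchor's connected component and is
solved by dense least squares (exact for consistent constraint sets;
problem sizes here are hundreds of frames at most, so sparsity tricks are
unnecessary beyond assembly).  Nodes not connected to the anchor cannot be
positioned; they are reported and excluded from the mosaic.  All
constraints are weighted equally by default; weighting rows by
`sqrt(inliers)` is available but off.

The point of the global solve is drift removal: integrating only
consecutive-frame estimates accumulates error linearly along the sequence,
while least squares over all pairwise constraints (including long-range and
loop-closing ones) distributes it.  `drift_report` quantifies this by
returning per-edge residuals and the sequentially chained positions for
comparison.

## Blending

Each frame's feather weight is the Euclidean distance transform of its
binary foreground mask — distance to the nearest background pixel, zero
outside the mask.  Computing the distance map on the mask rather than the
full frame matters for slit-lamp footage: most of the frame is unlit, and
the map must fall to zero at the content border, not the frame border.
A mask with no background at all (degenerate but legal) treats the image
border as background so weights stay finite.

The mosaic is the weighted mean `Σ w_i I_i / Σ w_i` at every covered
pixel.  The explicit normalization is a deliberate choice: without the
denominator, intensities would scale with coverage count.  Dim slit borders
get small weights and are outvoted by frames seeing the same location near
their slit center; small wrongly-segmented patches can never accumulate
large distance values and are suppressed the same way.  Frames at integral
positions are placed exactly (important for exactness tests); fractional
positions are spread bilinearly over the four neighboring placements.
Never-covered canvas pixels are encoded as zero alpha in the output RGBA
PNG, not as black.  Three straw-man compositors (overwrite, unweighted
mean, per-pixel median) are implemented for comparison, scored by the mean
Sobel gradient magnitude across frame-boundary pixels (a seam-visibility
proxy).

## Evaluation harness

ROC curves are computed over the threshold sweep of unique scores with
trapezoidal AUC (equal to Mann–Whitney pair concordance).  The operating
point defaults to the Youden index (max TPR − FPR); closest-to-(0,1) is
selectable.  Cross-validation assigns whole frames to folds (never pixels,
which would leak training content into the test set), pools pixels within
each fold, and averages fold curves vertically (mean TPR on a fixed
201-point FPR grid, taking the largest TPR per repeated FPR before
interpolating); the reported AUC is that of the mean curve.  Point metrics
(precision, accuracy, sensitivity, specificity) follow the standard
confusion-matrix formulas, reporting NaN — never zero — when a denominator
vanishes.  Field-of-view gain between two coverage masks is
`100 · (A − B) / B`.  Trajectory error against a planted trajectory removes
the global offset (both re-anchored at frame 0) and reports per-frame RMSE
and final-frame drift.

## Synthetic data

The simulator renders a latent 512x512 "fundus": an orange base modulated
by a low-frequency field, multi-scale granular texture (amplitudes
0.09/0.12/0.11/0.08 at Gaussian scales 0.8/1.2/2.5/5 px), ~24 dark
random-walk vessel curves radiating from a bright optic-disc analogue.
Frames of 128x170 px — one eighth of the 1024x1360 clinical sensor
resolution, with slit geometry scaled accordingly — are crops at planted
integer offsets, multiplied by a separable slit profile: a boxcar of the
slit width (default 40 px) convolved with a Gaussian of the falloff scale
(default 6 px) horizontally, and an analogous slower vertical profile
(boxcar of the slit height, 4x the falloff).  Per frame, 2 additive
near-saturated Gaussian glare blobs land uniformly in the illuminated
region, and Gaussian sensor noise (sigma 0.01) is added.  The ground-truth
mask marks pixels with at least 20 % of slit-center illumination that are
not glare-saturated (glare envelope < 0.5).  One seed drives fundus, glare
and noise through per-frame seed sequences, so rendering is bit-identical
across runs.  Trajectory presets cover the three acquisition scenarios of
interest: `sweep` (monotone horizontal scan), `loop` (closed circuit whose
per-step motion stays below the slit width — the drift test case) and
`static` (non-moving slit, the denoising case).

What the simulator does *not* emulate: optical blur/defocus gradients, eye
rotation and perspective, treatment laser spots, interlacing, and the
spatial statistics of real choroidal texture.  Passing tests therefore
demonstrate the pipeline's correctness and its behavior under the modeled
artifact types, not clinical-grade performance; the quantitative results on
real footage (segmentation AUC, field-of-view gains) depend on annotated
clinical data that is not publicly deposited.

## Problem sizes and numerical choices

The test and acceptance workloads use 40-frame loops, 60 annotated frames
for tenfold cross-validation, and 100 random pose graphs of up to 10 nodes
and 30 edges — sizes chosen so the full suite runs in minutes on one CPU
while still exercising every stage at its default hyperparameters.
Degenerate inputs are defined, not crashed on: empty masks yield empty
keypoint sets and zero weights, empty match sets yield rejected edges,
disconnected pose-graph components are excluded with a report, and
single-frame mosaics are legal.  Known limitations: subpixel accuracy is
bounded by the integer-located blob detector (~0.1–0.3 px per edge after
inlier averaging); acceptance of a frame pair is a hard 6-inlier rule, so
adversarially self-similar scenes can in principle produce false edges
(the illumination-normalization regularizer exists to prevent the common
case); and the per-pixel median compositor materializes the full frame
stack and is intended for short sequences.
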