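# Methods

`poolreg` registers pairs of single-channel 2D biomedical images acquired in
different modalities (e.g. H&E histology against MALDI or LA-ICP mass
spectrometry ion maps) by matching unsupervised, parameter-free local
features and fitting a 2D affine transform. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic test
bed does and does not demonstrate.

## The descriptor

The feature of a pixel is computed over the square *working window* of side
`W` centred on it, by hierarchical average pooling. Layer `l` (1-based, `L`
layers in total) partitions the window into `2^(l-1)` equal-area blocks and
records each block's mean intensity. Split axes alternate as depth grows:
layer 2 halves the window into left/right columns, layer 3 gives the 2×2
quadrants, layer 4 splits each quadrant into left/right again (2 rows × 4
columns), and so on; for window sizes not divisible by the grid, block edges
are placed by rounding equal fractions, so blocks may differ by one pixel.
The pooled values are concatenated (layers ascending, row-major within a
layer), and the single layer-1 whole-window mean is removed from the vector
and subtracted from every remaining entry. The descriptor length is
therefore `2^L − 2`, and the construction makes it *exactly* invariant to a
constant intensity offset: pooling is linear, and every entry has the
window mean subtracted. Averaging over blocks also damps independent pixel
noise — the mean descriptor perturbation under i.i.d. noise of standard
deviation σ is well below σ (verified as a test property).

The axis order of the block splits is a free choice (any fixed order gives
equal-area blocks); it lives in one helper (`pyramid.layer_grid`) so it can
be swapped without touching callers, and the test oracle implements the
same documented geometry independently.

## Feature magnitude map and keypoint selection

The *feature magnitude map* assigns every interior pixel the Euclidean norm
of its descriptor; bright values mark high local intensity variation. A
border of width `⌈W/2⌉` is invalid (the window must fit inside the image).
The dense map is computed from a single integral image, a few array
operations per pooling block, so evaluation is cheap at stride 1.

Keypoints are selected greedily in descending magnitude under *distance
regulation*: a candidate is accepted only if it lies strictly farther than
`D` pixels from every previously accepted keypoint, enforced by masking a
disc of radius `D` around each acceptance; selection stops at `N` accepted
points. Ties in magnitude break in row-major scan order, so selection is
fully deterministic. The magnitude is defined as the descriptor norm (the
natural choice for "brightness" of the map); zero-magnitude pixels
(constant neighbourhoods) are never selected.

Defaults: `W = 32` px, `L = 4` (descriptor length 14), `D = W/2 = 16` px,
`N = 500`. These are configuration values, echoed into every output's
provenance block. `W` trades locality against noise damping; `D` controls
feature density (and hence how well the affine fit is spatially
conditioned); `N` caps cost. An optional evaluation stride exists for very
large images and is recorded in output metadata.

## Matching

Descriptor distances between the moving and fixed keypoint sets form the
correlation matrix `H` (rows: moving). For each row, the best candidate is
accepted iff `H[0] ≤ 0.75 · H[1]` (best against second-best, the Lowe ratio
test; the threshold is configurable, 0.75 by default). Equality at the
printed threshold counts as a match; this boundary is implemented with a
relative tolerance of 1e−9 so decimal-printed boundary cases behave as
printed. Because the rule is row-wise, several moving points can claim one
fixed point; only the closest claimant is kept, making matches one-to-one.
(The plain row-wise rule, for which acceptance is provably monotone in the
ratio, remains available via `unique_fixed=False`.)

For matching (not for selection) descriptors are scaled to unit length by
default. Rationale: a monotone intensity remap between modalities acts on
the pooled descriptor approximately as a local gain — the descriptor is
linear in intensity, and a smooth monotone map is locally affine — so unit
scaling cancels the gain and leaves the spatial pattern, which is what
should be compared across modalities. A full contrast inversion flips the
descriptor sign and is handled separately (below).

Ratio-test survivors are filtered by *perspective consistency*: the two
images view one planar section, so matched locations must be related by a
plane-to-plane projective map. A seeded RANSAC consensus fit
(scikit-image `ransac` with `ProjectiveTransform`; minimal sample 4, inlier
reprojection threshold 3 px, up to 2000 trials, early stop at consensus
probability 0.9999) keeps the inlier pairs. Fewer than 4 input pairs is an
error (`InsufficientMatchesError`); a consensus below 3 inliers, or a
rank-deficient sample set, is `DegenerateGeometryError`.

## Affine estimation

The final transform minimises the summed Euclidean projection error between
fixed keypoints and affine-mapped moving keypoints over the inlier pairs.
Points are homogeneous column vectors, `p_F = M · p_M`, with `M` a 3×3
matrix whose last row is (0, 0, 1); the least-squares problem is solved by
orthogonal decomposition (`numpy.linalg.lstsq`), never by normal equations,
for conditioning on near-collinear sets; a rank check rejects collinear
configurations. The residual projection error is reported alongside the
transform. The transform is estimated from geometry-filter inliers only
(filtering precedes estimation in the pipeline's phase order).

Warping into the fixed frame is inverse-mapped resampling
(scikit-image `warp`): bilinear for images, nearest-neighbour for masks to
preserve binarity, constant fill (default 0) outside the source.

## Pipeline robustness layers

Registered image pairs from different instruments differ in more than a
smooth intensity remap, and the descriptor is not invariant to rotation,
scale, or contrast inversion. The pipeline wraps the core
detect→match→filter→estimate sequence in three layers, all deterministic
and configuration-exposed:

* **Preprocessing.** Hotspot clipping at the 0.99 quantile (the clip level
  is the *lower* order statistic at the quantile, which makes clipping a
  true projection — applying it twice equals applying it once), then affine
  normalisation to [0, 1] (clip before normalise, so a single saturated
  pixel cannot compress the dynamic range), then Gaussian smoothing with
  σ = 1 px to suppress pixel noise before any descriptor is computed. An
  optional signed quarter-turn pre-rotation handles modality pairs acquired
  90° apart (counter-clockwise for +1). Multichannel stacks are collapsed
  to one registration channel first — per-pixel mean by default
  (deterministic), first principal direction or a seeded 1D t-SNE embedding
  behind the same pluggable contract.

* **Intensity-representation trial.** Three moving-image candidates enter
  matching: the image as-is (with a descriptor-sign polarity trial, exact
  whenever the modalities are affinely related — including inversion), and
  the image and its complement `1 − I` histogram-matched onto the fixed
  image. Histogram matching undoes *any* monotone increasing remap up to
  noise; the complemented variant covers contrast inversion at the image
  level. Keypoint locations are identical across polarity flips (the
  magnitude map is a norm), so the trials only redo matching. The winner is
  chosen by the alignment score below, not by raw inlier counts, which are
  not comparable across intensity representations.

* **Coarse-to-fine geometry.** The descriptor tolerates only ~10° of
  relative rotation, so a small set of candidate pre-rotations (0, ±10,
  ±20, ±30°) of the moving image is searched first, stopping early once a
  candidate reaches 30 consensus inliers. The estimate is then refined:
  (a) up to two global re-matching passes on the warped pair, and (b) a
  *local descriptor search* — for every fixed keypoint, the best-matching
  descriptor within a radius in the dense descriptor field of the warped
  moving image becomes its correspondence (with sub-pixel parabolic
  interpolation of the distance surface), and the residual affine is
  re-estimated under the same RANSAC consensus. Local search radii cycle
  coarse-to-fine (16, 8, 4 px, up to 15 iterations): the coarse pass
  catches corner displacements a fine pass cannot see.

Every refinement step is accepted only if it improves a ground-truth-free
**alignment score**: the median, over fixed keypoints, of the best
unit-normalised descriptor distance within 2 px in the warped moving
image's dense descriptor field. This guard prevents a noise-biased
correction from degrading a good estimate, and iteration stops at a score
fixed point.

## Evaluation metrics

* **Dice**: `2|A∩B| / (|A| + |B|)` on binary masks.
* **Hausdorff**: symmetric max of directed max–min Euclidean distances over
  foreground pixel coordinates (the full maximum, not a percentile
  variant), in pixels, scaled by a micrometre-per-pixel factor when given.
* **Mutual information**: from the joint intensity histogram with equal-
  width bins over each image's own min–max range (default 32 bins per
  axis), reported in nats (natural log). A constant image has zero marginal
  entropy; MI is then 0 with a warning.

## Synthetic test bed

The fixture generator draws a smooth "tissue" — anisotropic Gaussian blobs
plus band-limited texture at two spatial scales (σ = 4 and 10 px),
modulated by the tissue so the background stays clean — on a 256×256 fixed
frame, then produces the moving image by resampling through a known affine
(composed scale → shear → rotation about the frame centre → translation),
applying a monotone intensity remap, adding Gaussian noise, and optionally
sprinkling saturated hotspot pixels (to exercise hotspot clipping). Masks
are thresholded from the blob field and carried through the same geometry.

The four remaps model the modality gap: identity; gamma 0.7; inversion
`1 − x`; and a three-segment piecewise-linear tone curve
(0, 0.3, 0.7, 1) → (0, 0.15, 0.85, 1). All are monotone, so structure is
preserved while absolute intensities differ — the regime the descriptor
targets.

The default recovery suite runs 20 cases with rotations drawn uniformly in
±30°, scales in 0.9–1.1, translations up to 15% of the frame, shear up to
±0.05, the four remaps cycling, and noise σ ∈ {0, 2%, 5%} of the dynamic
range, all from one seed. Reported per case: corner displacement of the
recovered affine against ground truth (mean/max over the four frame
corners), mask Dice before/after registration, and per-stage match counts.

What passing this suite does **not** show: robustness to non-rigid tissue
deformation, to section-to-section content differences (serial sections
are different physical slices), to structured or multiplicative noise, or
to non-monotone intensity relations between modalities. Real magnitude
maps can also be dominated by a single high-contrast region under the
global magnitude ranking, which thins keypoints elsewhere; an optional
per-tile normalisation of the magnitude map is a known extension and is
not enabled by default.

## Numerical and degenerate-input choices

* Offset invariance of the descriptor is exact for integer-valued rasters
  (real sensor data) with power-of-two windows, because every block then
  averages a power-of-two pixel count and no rounding residue survives the
  mean subtraction; for arbitrary floats it holds to ~1e−12.
* Constant images: normalisation maps them to zeros; the magnitude map is
  zero everywhere and no keypoints are selected; MI warns and returns 0.
* The problem sizes used by tests and the acceptance script (256×256
  frames, 20-case suite, 10 noiseless transforms, 200 oracle windows) were
  chosen to exercise every condition of the study design while keeping a
  full run in minutes on one core.
* All stochastic steps (RANSAC, fixture generation, t-SNE collapse) take
  explicit seeds; identical inputs and seeds reproduce outputs bit-for-bit.
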