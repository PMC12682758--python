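# Methods

This note records the models implemented in `acukit`, the parameter
choices that matter, the numerical details a reimplementation would need,
and what the synthetic fixtures can and cannot demonstrate.

## Exemplar-based de-labeling

Marker removal follows the classical exemplar-inpainting scheme: the
region to fill Ω (the marker footprint) shrinks patch by patch, each
iteration choosing the fill-front pixel p of highest priority, copying
the best-matching source patch Ψq over the unknown pixels of Ψp, and
propagating confidence.

**Priority.** The confidence term C(p) is the sum of per-pixel
confidences over the patch window divided by the full patch area
(confidence starts at 1 on the source region Φ, 0 on Ω).  The data term
is D(p) = |∇I⊥ · n_p| / α, where ∇I⊥ is the 90°-rotated luminance
gradient (Rec.601 weights), n_p the unit normal of the front, and
α = 255 normalizes 8-bit intensities.  Two priority rules:

* `baseline`: P(p) = C(p) · D(p), the classical product.  Once either
  factor reaches zero — confidence decays toward the center of a large
  region; D vanishes on texture-free skin — the product stops ordering
  the front meaningfully.
* `improved`: P(p) = exp(C(p) + D(p)) with C floored at
  `k_thr` (default 0.2).  The exponential sum is strictly positive and
  the floor keeps late-stage confidence from collapsing the ordering.
  The floor applies to the priority only; the confidence propagated to
  newly filled pixels is the raw patch mean, capped at 1, so the
  classical bookkeeping is unchanged.

The data term is identical in both modes.  Gradients are computed by
central differences restricted to known pixels (one-sided where only one
lateral neighbour is known, zero otherwise), and D(p) uses the
strongest known gradient within Ψp — a front pixel's own value sits on
the marker and is unreliable.  The front normal comes from the gradient
of a 3×3 box-smoothed Ω indicator.

**Matching.** The source patch minimizes the sum of squared RGB
differences over the already-known pixels of Ψp, over all candidate
centers whose full patch lies in bounds and contains no unfilled pixel
(previously filled pixels are legitimate source content).  Ties break
toward the candidate nearest p, then row-major order, which makes every
run bit-reproducible.  SSDs of 8-bit inputs are exact integers in double
precision, so the ordering is platform-independent.

**Elliptic search.** In improved mode each marker component is summarized
by its moment ellipse (centroid, half-axes = twice the square roots of
the second-moment eigenvalues — a disc of radius r maps to half-axes
≈ r, orientation from the leading eigenvector).  Candidates are
restricted to that ellipse scaled by `ellipse_margin` (default 2.5,
i.e. a band roughly 1.5 marker radii deep around the label).  The band
is screened quadrant by quadrant along the symmetry axes starting from
the quadrant containing p; because the final selection uses the
deterministic tie-break above, the screening order affects cost, not
results.  If the band offers fewer than `min_candidates` (default 50)
valid centers, the search falls back to the whole image, so the local
search never starves.  With `ellipse_margin = inf` the band covers the
image and the fill order provably equals a whole-image search — the
equivalence is asserted in the test suite.

**Patch size.** `patch_radius` defaults to 4 (9×9 patches), the common
choice for exemplar inpainting at these marker scales.

**Fill mask.** Rendered (and physical) labels have soft boundaries; the
marker mask marks pixels at least half-covered, so a thin partially
darkened fringe lies just outside it.  De-labeling therefore fills
`fill_mask(mask)` — the mask dilated by one pixel — covering the full
label footprint.  Filling only the half-coverage mask leaves a visible
dark ring and dominates the restoration error.

**Termination.** Each iteration fills at least the chosen front pixel,
so the loop completes in at most |Ω| iterations; a mask covering the
whole image is rejected (no source region).  Pixels outside the fill
mask are returned bit-identical.

## Restoration-quality and efficiency metrics

`psnr3` evaluates per-channel MSEs and offers the three-term sum
10·Σ_c log₁₀(255²/MSE_c) (`channel_sum`) and its third (`channel_mean`,
the conventional PSNR and the reporting default; the sum form runs ≈3×
higher).  A zero MSE in any channel yields an explicit +inf sentinel.
`ssim_global` is the single-window SSIM from global means, variances and
covariance per channel, channels averaged, with c₁ = (0.01·L)²,
c₂ = (0.03·L)², L = 255; no sliding window.

Processing efficiency: `per_marker_time` averages per-image times either
directly (`per_image`) or divided by each image's marker count
(`per_marker`, the default — the quantity is stated in seconds per
acupoint).  `efficiency_gain` reports (1 − T_improved/T_baseline)·100
either as a mean of per-image ratios (default, invariant to rescaling
all times) or as a ratio of mean times.

## Keypoint accuracy metrics

Predictions and ground truth match by label; no assignment problem is
solved (labels are authoritative in both Labelme files and fixtures).
APE is the mean over matched visible pairs of
max(‖P − G‖₂ − `tolerance_px`, 0).  The tolerance defaults to 0 — the
plain mean pixel error, the only reading consistent with a mean error of
a few pixels coexisting with ~90% recall — and is configurable for
sensitivity analyses.  APDE multiplies by `scale_k` (default 1.3 mm/px,
the working-distance conversion of a 640×480 camera about 1 m above the
bed).  The effective acupoint region is a 10 mm-diameter circle around
both the truth and the prediction; the two regions overlap iff the
center distance is strictly below 10 mm (boundary contact counts as FN).
Recall is the mean of per-image recalls — images with different keypoint
counts weigh equally — in percent.  Sample variance of per-image APEs
uses the n−1 divisor.

## Augmentation

Scale resamples bilinearly (nearest for masks) and multiplies keypoint
coordinates exactly; crop clamps the window, shifts keypoints by the
window origin, and marks points outside the window invisible while
keeping their coordinates for audit; horizontal flip mirrors pixels,
maps x → W−1−x (0-based pixel centers), and renames labels through an
involutive swap map (L_i ↔ R_i, M_i fixed) because mirroring a back
exchanges anatomical sides.  The seeded random pipeline draws a scale
from (0.7, 1.3), retries the crop up to 10 times until at least half the
visible keypoints survive, and flips with probability 0.5.  Matched
augmentation of prediction and truth leaves APE invariant (scaled
exactly by the factor under scaling) — asserted in the suite.

## SimCC coordinate coding and the two-stage harness

An axis of E pixels is split into round(E·ratio) bins
(`splitting_ratio` default 2); bin b represents coordinate b/ratio.
Encoding places a Gaussian of `sigma_bins` (default 6) bins' width at
coord·ratio, truncates at the borders and renormalizes to sum 1.
Decoding takes the expectation of bin centers under the normalized
weights (argmax decoding available); for coordinates at least 3σ from
the borders the round-trip error is below half a bin, 1/(2·ratio).
The training objective is KL(target‖pred) with epsilon flooring and
renormalization — non-negative, zero iff equal.

The harness composes an injected detector (image → bounding box) and
localizer (ROI raster → keypoints in ROI coordinates).  The box is
expanded about its center by `padding` (default 1.25), widened on the
shorter side to the output aspect, and mapped by a uniform-scale affine
onto the ROI raster (default 256×192); keypoints map back through the
exact inverse.  Localizer outputs outside the ROI raster are marked
invisible.  Detector failure and localizer failure raise distinct
errors.  The package ships oracle mocks (ground-truth box and
coordinates) and a noisy mock whose Gaussian error is specified in
original-image pixels; neural detection and pose networks are out of
scope by design — the harness exists to exercise contracts, transforms
and metrics.

## 3-D localization chain

Depth registration scales color pixels by the resolution ratios
(u′ = u·s_w, v′ = v·s_h), reads the nearest depth pixel (bilinear
interpolation behind a flag), and treats depth 0 as "no return",
raising a typed error that `localize_keypoints` converts into an
explicit invalid-label list.  Back-projection uses the pinhole model
x_c = (u − u₀)·ρ_w·z/f, y_c = (v − v₀)·ρ_h·z/f, z_c = z, consuming
intrinsics either as physical quantities (f in mm, pixel pitch in
mm/px) or as pixel-unit focals (only the ratios enter).  The camera→base
step multiplies by a validated homogeneous matrix (orthonormal rotation,
det +1, last row 0 0 0 1).  All depths and 3-D coordinates are
millimeters; pixel indexing is 0-based with pixel-center sampling
throughout the package.

## Synthetic fixtures

`make_back_image` renders base tone + two low-frequency cosine shading
fields (amplitude 18 intensity units — enough texture to make matching
non-trivial) + seeded Gaussian noise (σ = 2.5), then composites
anti-aliased dark discs (default radius 8 px) at each keypoint of a
34-point layout shaped like the M/L/R grid of a prone back at 640×480,
the camera resolution of the intended deployment.  The marker mask is
the at-least-half-covered footprint, giving component areas within a few
percent of πr².  `pristine_back_image` renders the identical scene
without markers, so restoration error is measurable exactly.
`make_depth_frame` produces a plane plus an optional cosine bump at a
configurable resolution ratio; `mock_predictions` displaces truth by
isotropic Gaussian noise (radial errors are then Rayleigh(σ), mean
σ·√(π/2)) with an optional miss rate.

What the fixtures do *not* emulate: real skin texture (pores, hair,
moles), specular lighting, perspective foreshortening, body-shape
variation, occlusion, or correlated prediction errors of a trained
network.  Passing the fixture suites therefore demonstrates the
correctness of the algorithms and metrics — fill ordering, search
equivalence, metric arithmetic, transform inverses — not the recognition
accuracy achievable on human data.

## Problem sizes in the shipped suites

The restoration-quality suite uses twenty 128×128 images with five
radius-6 markers — large enough for ~400 fill iterations per mode while
keeping the whole suite under a minute; the metric-recovery suite uses
200 mock-predicted 34-point images per noise level; codec and geometry
sweeps use 1000 points each.  These sizes make the statistical bounds in
the tests (5% on Rayleigh means, 2 recall points) comfortably tighter
than the sampling error.

## Known limitations

* The exemplar filler reproduces texture, not new structure; markers
  covering genuinely unique detail would be replaced by plausible skin.
* Global (windowless) SSIM saturates for small defects in large images;
  it is the intended restoration metric here, not a perceptual one.
* The elliptic band assumes compact, roughly convex marker components;
  pathological shapes fall back to whole-image search via the
  `min_candidates` floor.
* The harness's mocks model error as isotropic Gaussian noise;
  systematic detector bias (e.g. a consistently shifted box) is
  representable only through custom injected stages.
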