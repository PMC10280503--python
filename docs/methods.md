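# Methods

This note records the modelling assumptions, default parameters and
numerical choices behind the package, and what the synthetic benchmark does
and does not demonstrate.

## Golden Eagle Optimization

Each eagle keeps an elitist memory of the best point it has visited.  Per
iteration and eagle: prey = the memory of a uniformly drawn flock member
(self allowed); attack `A = prey − x`; cruise `C` = a random destination on
the hyperplane through `x` perpendicular to `A`, minus `x` (destination
drawn by fixing a random coordinate `k` with `|A_k| > ε`, sampling the
others uniformly in the box, and solving coordinate `k` from the hyperplane
equation).  This construction makes `C ⟂ A` testable to machine precision.

The step is `Δx = r1·pa(t)·A + r2·pc(t)·‖A‖·Ĉ` with `r1, r2 ~ U(0,1)` and
linear propensity schedules (defaults `pa: 0.5→2.0`, `pc: 1.0→0.5` over the
run).  Both terms are proportional to the prey distance `‖A‖`.  This is a
deliberate design choice over normalizing the attack and cruise vectors to
unit length: with fixed-magnitude steps the flock cannot refine the optimum
below the step length (on the 5-D sphere a unit-step variant stalls around
1e-3), whereas distance-proportional steps contract geometrically as the
flock converges and reach ~1e-20 under the same budget.  The orthogonal
cruise geometry and the propensity schedule are unchanged by this choice,
and the step-norm bound becomes `‖Δx‖ ≤ (pa+pc)·‖A‖`.

Degenerate cases: if `‖A‖ ≤ ε` (eagle sitting on its prey) the cruise
direction is a uniform random unit vector with unit scale, which keeps the
eagle moving; zero-norm terms drop out of the step.  Positions are hard
clipped to the box after every step.  Non-finite objective values during
the run are treated as `+∞` and logged; a non-finite value at
initialization is an error naming the point.  `ε = 1e-12`.  Minimization
throughout; identical seeds give bit-identical results.

## Random forest

Canonical CART/bagging: each tree trains on a bootstrap resample (N draws
with replacement); at each node `ceil(feature_fraction·F)` features are
drawn without replacement; the split is chosen by exhaustive search over
midpoints of sorted unique values, minimizing the size-weighted child Gini
impurity.  Ties break toward the lowest feature index, then the lowest
threshold.  Nodes stop at purity, `max_depth`, or when a split cannot give
both children `min_samples_leaf` rows.  A zero-impurity-decrease split is
accepted when the node is impure and a valid split exists, which is what
lets a single full-depth tree shatter any consistent dataset (the
single-tree oracle disables bootstrap so every training row reaches the
tree).  Posteriors are the mean over trees of leaf class frequencies;
`predict_label` takes the argmax with ties to the lower class index.  The
split search and traversal inner loops are numba-compiled; each tree's RNG
is seeded from a per-tree child of the forest seed, so training is
bit-reproducible.  Models round-trip exactly through a nested-node JSON
schema (feature, threshold, children, leaf counts).

The forest exposes a `posterior_bias` field — an additive offset applied to
the lesion-class posterior by the segmentation stage before thresholding
(default 0, tunable in [−0.2, 0.2]); it leaves `predict_proba` untouched.

## Preprocessing and per-pixel features

Preprocessing: per-channel median filter of radius `r` (window `2r+1`,
reflect padding; default r=1), then a per-channel linear stretch mapping
the 1st/99th intensity percentiles to 0/255 with clipping (constant
channels pass through).  The 12 feature planes are: R, G, B on [0,1]; HSV;
gray local mean and standard deviation in 5×5 and 11×11 reflect-padded
windows; gradient magnitude of the σ=1 Gaussian-smoothed gray image
(central differences); and Euclidean distance from the image center
normalized so corners are 1.  All planes are deterministic and finite; the
fixed bank covers color, texture, edge and location cues at comparable
scales, so no separate learned nonlinearity is applied.

## ABCD features

* **Asymmetry**: principal axes from the mask's second-moment matrix;
  lesion pixel coordinates are projected into the principal frame, rounded
  to the integer lattice, reflected about each axis, and the symmetric
  set difference is divided by twice the area; the two axis scores are
  averaged.  A centered disk scores < 0.05 (rounding noise only); the
  score is invariant to 90° rotations within ±0.02.
* **Border irregularity**: isoperimetric quotient `P²/(4πA)` with `P` the
  Crofton perimeter estimate (4 directions).  Discretization keeps a disk
  below 1.15 and all masks above 1 − 0.05.
* **Color**: per-channel mean and std of pixels inside the mask on [0,1].
* **Diameter**: maximum Feret (caliper) diameter computed exactly as the
  largest pairwise distance between convex-hull vertices of the boundary
  pixels' corner points, normalized by the image diagonal; plus the area
  fraction.  (For an axis-aligned `a×b` rectangle this gives `√(a²+b²)`
  exactly.)

The 10-column order is `asymmetry, border_irregularity, color_mean_{r,g,b},
color_std_{r,g,b}, diameter_frac, area_frac`.

## Segmentation and classification

The segmenter samples `pixels_per_image` pixels per training image
(default 500; half lesion / half background where available, without
replacement, from a per-image child of the forest seed; an empty mask
contributes background only and is logged).  At inference the posterior map
(+ bias, clipped to [0,1]) is binarized at `threshold` (strictly greater),
opened then closed with a disk of `morph_radius` (removes speckle, then
fills gulfs), and reduced to the largest 8-connected component (ties go to
the component containing the lexicographically smallest pixel; an empty
mask is legal).  The classifier trains on ABCD features from the *true*
masks of the training split; at evaluation time ABCD features come from the
*predicted* masks, and an empty predicted mask falls back to a full-frame
mask so the objective stays total (logged).  Verdict: malignant iff the
posterior exceeds 0.5; exact ties go to benign (arbitrary but fixed).

Default hyperparameters (the "documented defaults" the tuner is seeded
with): segmentation forest 30 trees, depth 12, feature fraction 0.5,
min leaf 2; threshold 0.5, morphology radius 2, keep-largest on, bias 0;
classification forest 60 trees, depth 8, feature fraction 0.6, min leaf 1.

## Joint GEO tuning

The 11 search coordinates and bounds: segmentation forest trees [10,200],
depth [2,20], feature fraction [0.1,1.0], min leaf [1,20]; threshold
[0.2,0.8]; morphology radius [0,5]; posterior bias [−0.2,0.2]; and the four
classification-forest analogues.  Integer coordinates decode by rounding
then clipping, so decoding is idempotent.  Fitness of a position: train
both models on the training split (tuning uses 200 sampled pixels per
image to keep evaluations cheap), then `1 − (w_seg·mean Dice + w_cls·
balanced accuracy)` on the validation split, weights 0.5/0.5 by default.
Tuning is joint rather than staged — a single reproducible search.  Pixel
feature stacks and training-mask ABCD vectors are position-independent and
computed once per tuning run.  Forest seeds inside the fitness are fixed
children of the tuning seed, so the objective is deterministic.  After the
search, final models are retrained on train+val at the best position.

## Synthetic data generator

Each image is a skin-toned background (default RGB (225,185,160)), a ±10%
linear illumination ramp in a random direction, and Gaussian pixel noise
(σ=6), carrying one star-convex lesion with boundary
`r(θ) = r0·s(θ)·(1 + Σ_{k=2..6} a_k cos(kθ + φ_k))`, `s` an elliptical
scaling, random phases, center jittered ±10% of the frame, radii clipped to
keep a 4 px margin.  Class-conditional ranges: base radius fraction benign
0.10–0.18 vs malignant 0.16–0.28; harmonic amplitudes 0–0.05 vs 0.08–0.25;
axis ratio 0.85–1.0 vs 0.55–0.9; pigment patches 0–1 vs 2–5 (darker/reddish
overlay blobs).  The lesion is alpha-blended into the skin with a 2 px
Gaussian border; the ground-truth mask is the exact pre-blend polygon
rasterization — truth is geometric, not photometric.  A `separation`
scalar (default 1) shrinks all class-conditional ranges toward their
common midpoint for stress testing; the defaults are intentionally well
separated so that end-to-end checks are stable.

What the generator does **not** emulate: hair and ruler/gel artifacts
(hair is off by default and not rendered), multi-lesion frames, flat or
amelanotic lesions, camera vignetting, color-calibration differences
between devices, and the long-tailed diversity of real dermoscopy.
Passing the end-to-end checks therefore demonstrates that the pipeline's
mechanics (features → forests → morphology → tuning) work and are
deterministic, not that this feature set or any reported score would hold
on clinical images.

## Metric modes

`standard` uses the textbook definitions (sensitivity `tp/(tp+fn)`,
specificity `tn/(tn+fp)`).  `paper_fidelity` reproduces a published
variant in which both sensitivity and specificity are normalized by
`(tp+tn)`; it is nonstandard (on a balanced, perfectly classified split
both values are 0.5) and is provided for auditability only.  Every report
carries an explicit mode tag.  Accuracy, precision and F1 are mode
independent.  Dice is defined as 1 when both masks are empty (IoU
likewise).

## Problem sizes and determinism

The test suite and the acceptance script work at desk scale, chosen as the
package's own benchmark conditions: 128×128 frames; 100 training / 40
held-out images for the end-to-end checks; a 60/20 split with 8 eagles and
10 iterations for the tuning check; 64×64 frames and a 3-eagle search for
the byte-identical full-loop determinism check.  All randomness fans out
from a single seed through named substreams (generator, sampling, forest,
GEO), so every artifact — masks, model JSON, metrics CSVs — is
byte-reproducible for a given seed.

## Known limitations

* The ABCD descriptor is a 10-number summary; it cannot represent fine
  pigment-network texture, and the classifier inherits that ceiling.
* Pixel features are purely local (≤ 11 px windows); very large or very
  low-contrast lesions rely on the center-distance prior.
* The GEO fitness is a point estimate on one validation split (no nested
  cross-validation); tuned hyperparameters can overfit small splits.
* `keep_largest` enforces the single-lesion assumption by construction.
* The morphological post-processing interprets "spatial smoothing" of the
  posterior map; no CRF/level-set refinement is attempted.
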