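# Methods

`plantar-qc` implements two independent quality-control detectors for
standardized plantar pressure maps — 64×64 grids of [0, 1]-normalized
vertical pressure intensity — together with the synthetic data model,
the evaluation harness that compares them, and the survey statistics
used to assess how experts perceive their explanations.  An *outlier*
here is a technically corrupted recording (incomplete capture, both
feet in one frame, upside-down map, swapped left/right annotation),
not a clinically abnormal foot.

## Standardized representation

Raw plates differ in sensor pitch and grid size.  A raw H×W grid with
row/column spacings is resampled (bilinear) so that its longer
*physical* side spans 64 pixels, preserving the physical aspect ratio,
then centered and zero-padded; intensities are divided by the grid
maximum.  Row 0 is distal (toes), row 63 proximal (heel).  Centering is
a convention choice — only "zero-padding around the pattern" is fixed
by the design — and duplicate records are defined as byte-identical
standardized grids with identical subject/side/condition metadata.

## Synthetic data model

Real acquisitions are not redistributable, so the package ships an
analytic stand-in.  A left foot is a sum of Gaussian pressure blobs
with anatomically placed means: a heel ellipse, a lateral midfoot band,
five metatarsal heads (first metatarsal strongest, medial), a hallux
and four lesser toes, plus a multiplicative medial arch void.  A right
foot is the column mirror of the left pattern.  The model is strongly
chiral (hallux and arch mark the medial side), which is what makes a
swapped side annotation detectable at all.

Variation has two levels, emulating a multi-subject cohort:

* subject effects, drawn once per subject: foot length ±8%, width
  ±10%, pose rotation ±6°, translation ±2 px, regional loading gains
  ±15%, arch depth ±15%;
* per-sample noise: a smooth multiplicative intensity field (sd 0.10,
  spatial scale 3 px), pose jitter ±2°/±1 px.  Dynamic-condition maps
  shift load toward the forefoot (+12%) and off the heel (−8%),
  mimicking roll-over composites.

Intensities below 0.02 are set to exact zero (real maps have a hard
background), the map is renormalized to max 1, and the support is a
single connected region covering 10–45% of the canvas.  All generators
are pure and deterministic per seed.

What the generator does **not** emulate: pathological morphologies
(hallux valgus, flat foot), footwear artifacts, sensor noise textures,
or inter-plate resolution differences.  The study's hardest real-data
failure mode — pathological but valid feet being flagged by the
normative test — therefore does not occur here, and passing results on
synthetic data bound the method's behaviour only under clean
conditions; they say nothing about pathological cohorts.

### Outlier injection

* **General acquisition error (label 1)** — forefoot crop: the distal
  `ceil(f·64)` rows are zeroed with f ~ U(0.45, 0.55); heel crop: the
  proximal rows with f ~ U(0.60, 0.70).  Untouched pixels are preserved
  bit-exactly; the side annotation is retained.
* **Double foot (label 2)** — the subject's left and right maps are
  each downscaled to 32×32 and placed in the upper-left and lower-right
  quadrants (which foot goes upper-left is random), each tile shifted
  0–2 px in a random cardinal direction; the side annotation is
  assigned at random because it is undefined for a two-foot frame.
* **Inverted orientation (label 3)** — row reversal (upside-down map).
  A literal 180° rotation additionally mirrors columns; both readings
  are implemented (`inversion_mode` `flip_rows` | `rot180`) with row
  reversal as default.
* **Swapped side annotation (label 4)** — the grid is untouched; only
  the side flag is toggled.

When a sample could carry several labels, the swapped-side label is the
lowest priority and is superseded by any other outlier class; no
ranking is defined among the remaining classes, so their co-occurrence
is treated as an error.  Augmentation tops every outlier class up to a
target count (500 in the study design) by applying these generators to
randomly chosen valid samples; derived samples inherit the source
subject, so grouped cross-validation keeps them with their origin.

## Registration

The SPM branch requires pixel-wise anatomical correspondence.  Each map
is aligned to a per-side reference template — the pixel-wise mean of
centroid-centered valid maps of that side, renormalized to max 1 — by
a 4-parameter affine transform (rotation about the canvas center,
isotropic zoom, row/column shifts; bilinear interpolation, zero fill).
Parameters minimize the mean squared intensity error under box bounds
(±30°, ±10 px, zoom 0.8–1.25) with L-BFGS-B and finite-difference
gradients (step 1e-3, with an optional refinement pass at 1e-4 used
when parameter-level accuracy matters; cohort-scale registration skips
the refinement for speed).  Optional multi-start (identity plus ±10°
and ±5 px starts) guards against local minima for large rotations;
ties go to the smallest parameter norm.  Alignment quality is the IoU
of the binarized (pressure > 0) footprints.

## Normative SPM outlier detection

Analyses are per side: a test map is compared against the cohort of
registered valid maps of its *recorded* side.  This is deliberate — a
swapped annotation sends a right foot into the left-foot norm, which is
the only mechanism by which this branch can catch label 4.

1. **Pixel-wise rank test.**  For intensity t against cohort values
   x₁..xₙ, the two-tailed empirical p-value is
   `p = min(1, 2·min(1+#{x≥t}, 1+#{x≤t})/(n+1))` — add-one corrected
   (never 0) with ties counted on both tails.  All 4096 pixels are
   tested, including background pixels where the whole cohort is zero:
   off-footprint pressure (double feet, inverted maps) must be able to
   form clusters there.  The smallest attainable p is 2/(n+1), so the
   cluster-forming threshold only bites when α_forming > 2/(n+1).
2. **Cluster-level FWER control.**  Contiguous suprathreshold pixels
   (p < α_forming; 8-connectivity by default) form candidate clusters;
   clusters below `min_cluster` pixels are discarded.  A null
   distribution of maximum surviving cluster sizes is built by
   leave-one-out resampling: each of 1000 permutations draws one cohort
   member uniformly and tests it against the remaining n−1.  (Member
   p-maps are deterministic, so they are computed once and reused.)
   A candidate is significant only if its size *strictly exceeds* the
   nearest-rank (1−α_FWE) percentile of the null (α_FWE = 0.05); the
   map is an outlier iff at least one significant cluster remains.

The leave-one-out scheme preserves exchangeability between the null
statistic and a fresh valid map tested against the cohort, giving
empirical per-map false-positive rates at or below α_FWE (measured
0.046 at α_forming = 0.05 with n = 150).  One quantization caveat: the
null tests against n−1 members while a real test sees n, so the integer
count cutoff implied by α_forming can differ by one between the two at
some α values (e.g. 0.04 at n = 150), inflating the false-positive rate
above nominal there.  At the package defaults (α_forming 0.05) and at
the tuned-search endpoints the cutoffs agree.

`α_forming` (uniform in [0.01, 0.05]) and `min_cluster` (integer in
[0, 30]) are tuned by randomized search on the inner validation split,
maximizing binary F1; ties prefer the more conservative setting (larger
`min_cluster`, then smaller `α_forming`).  One null distribution is
computed per (cohort, configuration) and reused across test samples.

## CNN classifier

The classifier consumes *unregistered* standardized grids plus the
integer side label; spatial invariance is left to the network.  The
backbone is three convolutional blocks of two 3×3 convolutions each
(32, 64, 128 filters; batch norm + ReLU after every convolution), 2×2
max-pooling and channel-wise dropout (0.25) per block, halving
64→32→16→8.  The flattened 8192-vector is concatenated with an
8-dimensional embedding of the side label and classified by a
256-unit hidden layer (batch norm, ReLU, dropout 0.25) and a 5-way
output.

Because no deep-learning framework is part of the runtime, the network
and its backpropagation are implemented directly on numpy: convolutions
are evaluated as nine (cin×cout) GEMMs on shifted contiguous copies of
the padded input (a single 9-column GEMM for the 1-channel input
layer), and batch-norm reductions go through BLAS.  Training throughput
is ~30 ms per sample per optimizer step on one CPU core.

Two initialization details matter and are deliberate:

* the embedding table is drawn at scale 1.0 and the hidden-layer
  columns that read the embedding are initialized with fan-in equal to
  the embedding width (not the full 8200 concatenated width).  With a
  naive shared fan-in the side signal is ~30× weaker than the
  convolutional features at initialization, and the valid-vs-swapped
  discrimination — an XOR of map chirality with the side flag, the only
  class pair not separable from the grid alone — fails to train in any
  reasonable budget.  Balanced, it converges within a few epochs.
* head dropout is 0.25 (0.5 destabilized the same boundary).

Training: Adam (lr 1e-3), weighted cross-entropy with class weights
inversely proportional to training frequency, *and* class-balanced
sampling (both mechanisms are part of the design; either can be
disabled).  An epoch is 1024 balanced draws in batches of 32 —
decoupling epoch length from the imbalanced dataset size.  Early
stopping watches the validation loss with patience 10 and a minimum
material improvement of 5e-3; the retained checkpoint is the absolute
validation-loss minimum.  Inputs are standardized by the scalar
mean/sd of the current fold's *training* pixels only.  All randomness
(init, sampling, dropout) is seeded; training is bit-reproducible.

## Attributions

Per-pixel explanations use *expected gradients*: integrated gradients
along the straight line from each background sample to the explained
sample (midpoint rule, 64 steps by default), averaged over a background
set drawn from the training data (100 samples by default).  The side
label is attributed through its continuous embedding vector, so grid
and side contributions satisfy the Shapley-style additivity identity
`Σ attributions ≈ f_target(x) − mean_b f_target(b)` — the network is
piecewise linear, so the midpoint quadrature is exact away from ReLU
kink crossings; the contract enforced in tests is 1% relative
tolerance on trained models.  (The identity is ill-conditioned when the
output difference is near zero, as on an untrained network — gaps are
reported relative to that difference.)

For display, values below 20% of the maximum absolute attribution are
zeroed, then the map is smoothed with a bilateral filter (window 5 px,
range σ 0.1 of the normalized scale, spatial σ 2 px), positive and
negative parts filtered separately and confined to the surviving
support.  The three-panel figure shows the raw grayscale map, green
contours of SPM-significant clusters over the map, and the diverging
attribution overlay (blue = toward the predicted class, red = away).
A survey-parity mode titles the figure with only "outlier/valid",
hiding the subtype so both branches convey the same label information.

## Evaluation protocol

Outer 5-fold cross-validation with an inner 80/20 train/validation
split, both grouped by subject and approximately stratified by the
5-class label via a greedy heuristic: subjects are visited by
decreasing sample count and assigned to the partition that minimizes
the spread of target-normalized per-label counts (exact grouped
stratification is combinatorial).  Both branches see identical
partitions.  Per fold: the SPM branch builds per-side templates from
inner-training valid maps, registers the normative, validation and
test maps, tunes (α_forming, min_cluster) on the validation split and
classifies the test fold; the CNN branch trains on the inner-training
split with early stopping on the validation split and predicts the
test fold.  CNN predictions are reduced to binary for the head-to-head
comparison; metrics are MCC and F1 (outlier = positive), reported per
fold and pooled, and additionally with synthetic test samples excluded.
A branch failure on a fold is recorded and the run continues.

## Survey statistics

Eight bipolar attributes on a 7-point scale, ten images per approach
per participant.  Ratings are reduced to the subject median per
attribute and approach (midpoint convention), then compared between
approaches with the Wilcoxon signed-rank test — zero differences
dropped, average ranks for ties, and the p-value computed by exact
enumeration of all 2ⁿ sign patterns for up to 20 informative pairs
(normal approximation beyond) — Bonferroni-corrected over the eight
attributes.  Median confidence intervals are percentile bootstrap
(5000 resamples) over subject-level medians.  Post-hoc power for a
paired design uses the noncentral-t approximation with the Wilcoxon
asymptotic relative efficiency discount (n′ = 0.955·n): dz = 0.8,
n = 16, two-sided α = 0.05 gives ≈ 0.83.  The Bonferroni-corrected
power figure is not reproduced: it depends on the number of
comparisons entering the correction, which the design leaves open.
The 5-point similarity and preference questions are summarized
descriptively (median, MAD, shares) without inference.

## Problem sizes and numerical choices

The default synthetic study uses 200 subjects × 4 valid maps (left /
right × static/dynamic), outlier classes augmented to 500 — 2800
samples, mirroring the curated-study scale (798 + 2000 ≈ 2798).  The
shipped verification runs exercise one outer fold of this dataset for
the branch comparison, a 150-map cohort with 500 held-out null maps
for false-positive calibration, and 100 perturbed maps (rotations to
±20°, shifts to ±8 px, zoom 0.85–1.18) for registration quality;
these sizes keep a full run on a single CPU core within tens of
minutes.  Degenerate inputs fail loudly rather than silently: all-zero
grids cannot be normalized, single-class validation sets cannot tune,
missing training classes cannot be weighted, empty cohorts cannot form
a normative model.

## Known limitations

* The synthetic cohort has no pathological inliers, so the SPM branch's
  real-world false-positive mode is absent; synthetic comparisons can
  (and do) come out cleaner than the curated-data results.
* The null-permutation scheme is one reading of "permuting the
  normative data"; alternatives (label or pixel permutation) would
  change the null's granularity.  Leave-one-out resampling was chosen
  for preserving the one-vs-cohort exchangeability of the test
  statistic.
* Registration is affine only; deformable alignment and per-region
  aggregation are out of scope.
* The attribution backend is a path-integral approximation, not an
  exact Shapley decomposition over feature coalitions; its guarantee
  here is the additivity contract.
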