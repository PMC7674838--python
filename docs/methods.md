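# Methods

This note documents the models and procedures implemented in `mriens`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Problem setting

Input is a cohort of preprocessed 3-D structural brain MRI volumes:
re-oriented, skull-stripped, co-registered to a common template space and
segmented into gray-matter probability maps *before* they reach this
package (those steps are out of scope; the package consumes the result).
Co-registration is the load-bearing assumption: a voxel index addresses
the same anatomical location in every subject, so voxels can be treated
as features and slices as comparable images across subjects.  At full
scale registered volumes are 121 × 145 × 121 voxels; cropping to the
`k = 100` central slices per axis (window start `floor((extent − k)/2)`,
the extra voxel dropped from the high-index side) yields the
100 × 100 × 100 inner-structures volume containing the hippocampal
region.  The axis convention is RAS: axis 0 sagittal, axis 1 coronal,
axis 2 transaxial; files with other orientations are re-indexed at load.
Slice indices are 0-based internally and reported 1-based in logs.

## Slice decomposition

An RGB-like image stacks the slices at indices *n*, *n* + gap,
*n* + 2·gap as its R, G, B bands; approaches A/B/C use one orientation
(sagittal/coronal/transaxial) for all three bands, approach D mixes one
slice of each orientation.  Open choices resolved here:

* **Anchor stride.**  The anchor sequence starts at the first slice and
  advances by a configurable stride; the default is 1 for gap 0 and
  2·gap + 1 for gap > 0, i.e. non-overlapping triplets that together
  cover the volume.  Overlapping anchors (stride 1) are available.
* **Approach-D shape harmonization.**  On non-cubic volumes the three
  planes differ in shape; bands are zero-padded symmetrically to their
  element-wise maximum shape (no interpolation; a no-op on cubic
  volumes).  Resizing is left to backends that need a native input size.
* **Intensity scaling.**  Each volume is min–max scaled to [0, 1] once
  before slicing so that backends expecting bounded inputs see
  commensurate bands; a `scale=False` switch preserves raw intensities
  (used by the reconstruction identities in the tests).

Per-slice training groups images by the key (approach, gap, *n*): a
slice model is trained only on images of the other subjects centered on
the same slice, never across keys.

## Aggregate Selection

Three ranking criteria are computed per voxel feature:

* Fisher score `Σ_c n_c(μ_cj − μ_j)² / Σ_c n_c σ_cj²`.  Degenerate
  cases: 0/0 → 0; positive numerator over zero denominator (a perfect
  separator with no within-class variance) → largest finite score + 1.
* |Welch two-sample *t*| (same sentinel convention).
* Sparse logistic importance: |coefficient| of an L1-penalized logistic
  regression on internally standardized features (liblinear coordinate
  descent), the inverse penalty C chosen by inner stratified CV over
  {0.1, 1.0} by log-loss.  This is a frequentist stand-in for the
  Bayesian-L1 formulation of the original criterion; at adequate penalty
  most importances are exactly zero.

Each criterion's scores are made strictly positive by shift-and-floor
(`s′ = s − min(s) + δ`, `δ = 10⁻⁶ · range(s)`; a constant score vector
maps to the uninformative uniform vector) and define a ratio comparison
matrix `M_ij = s′_i/s′_j`.  Such matrices are reciprocal, transitive and
perfectly consistent by construction: the principal eigenvalue equals
the order *n*, so the consistency index `CI = (λmax − n)/(n − 1)` and
ratio `CR = CI/RI(n)` vanish.  `RI` uses Saaty's random-index table for
n ≤ 15 and the asymptote `1.98·(n − 2)/n` beyond.  Conventions:
CR = 0 whenever |CI| ≤ 10⁻¹² (covering orders 1–2 where RI = 0); a
non-zero CI with RI = 0 is an error.  The principal eigenvector of a
ratio matrix is the normalized score vector, so the aggregation uses
that closed form directly — necessary at voxel dimension (D ~ 10⁴–10⁶),
where an explicit D × D matrix is impossible; the dense eigensolver path
exists for analysis and is verified against the closed form in tests.
The performance matrix stacks the per-criterion eigenvectors as columns
(each summing to 1); final scores are its product with the criterion
weight vector, fixed a priori to 1/3 each to avoid bias.  Top-k features
are selected with ties broken by feature id (deterministic).

## Kernel PLS

Labels enter through the label kernel `K_y = y_c y_cᵀ` (centered
labels); the data kernel is double-centered.  Components are extracted
iteratively: `t_l` is the unit-norm dominant eigenvector of the current
`K_X K_y`, sign-oriented so that corr(y, t_l) ≥ 0, after which both
kernels are deflated by `P = I − t_l t_lᵀ`, giving pairwise-orthogonal
components.  With a linear kernel the first component coincides with the
classical (NIPALS) PLS first score — the oracle used in tests.  Dual
coefficients `α_l = K_y t_l / λ_l` satisfy `t_l = K_X α_l` and, with the
matching test-kernel centering and deflation, make out-of-sample
projection reproduce the training components exactly.

Open choices resolved here: the default kernel is Gaussian with the
median-pairwise-distance bandwidth (`γ = 1/(2 m²)`); the correlation
function Ψ is the Pearson correlation; the feature loadings `v_il` are
correlation loadings of feature *i* on component *l* (zero for constant
features).  Explanatory weights follow
`w_i = D·Σ_l Ψ(Y,t_l) v_il² / Σ_l Ψ(Y,t_l)` (non-negative by the sign
convention).  The component contribution is implemented literally as the
class-size-weighted mean of the class centroids,
`γ_l = Σ_i N_i m_il / Σ_i N_i`; note that for centered components this
weighted grand mean is near zero — it is reported for fidelity to the
printed formula, with the class centroids `m_il` themselves available on
the model.  The discriminative form (projection vector α with
inter/intra-class scatter S₁, S₂) is exposed as a diagnostic in
component space, not used for extraction.  A rank-deficient kernel that
yields fewer than the requested components (common for an RBF kernel on
high-dimensional data, where distance concentration makes the centered
kernel nearly spherical) triggers a warning and returns the achievable
components.

## Classifiers and fusion

* **SVM** — linear kernel by default (voxel features ≫ subjects), C
  chosen on the inner-CV grid {0.01, 0.1, 1, 10} by held-out AUC, then
  refitted with Platt-scaled (sigmoid-calibrated) probability outputs so
  all fusion operates on commensurate [0, 1] scores.
* **Slice backends** — any object with `fit(images, labels, seed)` and
  `score_images(images) → [0,1]` registers as a backend.  The shipped
  desk backend is a standardized L2-logistic scorer on flattened bands:
  deterministic, fast, and sufficient to exercise the full ensemble
  machinery.  The backend spec carries the iterative-training
  hyperparameters (learning rate 10⁻⁴, mini-batch 30, epoch cap 20) that
  neural backends honor; the closed-form desk backend maps the epoch cap
  to its iteration limit.
* **3-D patch CNN** — volumes are tiled into non-overlapping patches on
  a grid anchored at index 0 (leftover margins dropped; count =
  Π floor(extent/patch extent); 28 × 28 × 121 patches at full scale,
  20 per volume).  The network is a fixed sequence
  conv → ReLU → max-pool → fully-connected → soft-max, with conv and
  pool strides of 4 and pooling window ≤ 3 at full scale, trained from
  scratch by mini-batch SGD with momentum 0.9 and initial learning rate
  10⁻⁴ on the cross-entropy loss.  It is implemented directly in numpy
  (einsum convolution over strided windows, argmax-routed pooling
  gradients); analytic gradients are verified against finite differences
  in the tests, and training is bit-reproducible per seed on one thread.
  Each patch inherits its volume's label; a volume's score is the
  sum-rule merge of its patch scores.  Desk-scale runs shrink the patch
  shape, strides and filter count, and use a larger step size (0.05) —
  at toy problem sizes the full-scale learning rate of 10⁻⁴ moves the
  weights negligibly within a short run.
* **Sum rule** — fusion is the unweighted mean of member scores
  (AUC-equivalent to the plain sum, keeps every level in [0, 1]); the
  per-subject sum uses exact (compensated) summation so member order
  cannot perturb results.  Method #2 fuses bottom-up — slices, then
  (approach × gap) configurations, then backends — with a flat
  all-members mean available as an alternative (identical when level
  sizes are equal).  Method #1 fuses the AS+SVM and kPLS+SVM pipelines.
  Fused AUC is invariant under a common strictly increasing transform of
  member scores only for a single member; for several members
  commensurate calibration matters, which motivates the [0, 1]
  probability-style outputs throughout.

## Evaluation

Nested cross-validation: stratified outer folds (default 10; the inner
hyperparameter loop defaults to 5 folds) with fold assignment seeded
from the plan.  All fitting — feature reduction, hyperparameter choice,
model training — happens inside each outer training fold; the harness
records the exact subject ids passed to each fold's builder, and
`assert_no_leakage` verifies the intersection with the fold's test
subjects is empty.  AUC uses the Mann–Whitney equivalence with midranks
(ties count one half); no smoothing, no multiple-testing correction.
The whole-volume vs. inner-structures comparison runs the same plan on
the original and centrally cropped volumes, giving a paired design with
identical fold splits.  Results serialize to JSON plus a flat CSV of
out-of-fold scores; identical seeds reproduce results bit-identically on
one thread.

## Synthetic cohorts

The generator emulates exactly what the pipeline relies on and nothing
more: a smooth non-negative "gray-matter-like" template shared by all
subjects (smoothed ellipsoidal support plus smoothed random blobs at a
fixed density per unit volume, periodic boundary handling — so the
infinite-smoothing limit is a constant field), additive per-voxel
Gaussian subject noise (SD 0.08, lightly smoothed with σ = 0.5 voxels),
and, for the affected class, intensities inside an effect region scaled
by (1 − d).  The default effect region is the central-crop window with
`k = round(min_extent · 100/121)`, mirroring the full-scale crop
proportion, so the region comparison isolates an inner-localized effect
by construction; a uniform region and custom masks are available.
Defaults: 40 × 48 × 40 voxels, 20 subjects per class, d = 0.3 —
conditions at which effect recovery is essentially certain while a null
cohort (d = 0) stays exchangeable.

What this does **not** emulate: real neuroanatomy, the spatial
covariance of biological inter-subject variability, scanner artifacts,
registration error, or the distributed (non-localized) atrophy pattern
of real disease.  Passing benchmarks on these cohorts demonstrates that
the machinery is correct (no leakage, calibrated nulls, sensitivity to a
planted localized effect), not that the methods attain any particular
accuracy on clinical data.

## Benchmark problem sizes

The packaged benchmarks run the full nested-CV pipelines at
40 × 48 × 40 voxels with 20 + 20 subjects over 5 generator seeds, with 5
outer and 3 inner folds; unit tests use 16 × 20 × 16 cohorts and the CNN
benchmark uses 12³ volumes with 6 × 6 × 12 patches at stride 2.  Null
calibration is judged on the mean out-of-fold AUC across the 5 seeds:
at 40 subjects a single null CV AUC has a standard deviation of roughly
0.1 (rank statistics at this sample size, confirmed by a pure-noise
simulation), so individual seeds legitimately wander while the 5-seed
mean is a sharp test of bias.

## Known limitations

* The desk slice backend is linear; conclusions about convolutional
  backends transfer only at the interface level.  Fine-tuned pretrained
  2-D architectures are deliberately out of scope.
* The sparse-logistic criterion approximates the original Bayesian-L1
  formulation; coefficients (and hence one third of the aggregate
  ranking) depend on the penalty grid.
* γ_l as printed is a weighted grand mean and nearly vanishes for
  centered components; use the per-class centroids for interpretation.
* The RBF-kPLS branch often extracts fewer than the requested 10
  components on high-dimensional inputs (rank warning); the SVM then
  operates on the achievable components.
* Fold-seeded determinism holds on a single thread; BLAS threading can
  perturb floating-point sums across machines.
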