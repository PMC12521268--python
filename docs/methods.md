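# Methods

This package re-implements a multi-view multimodal 3D classification
architecture for Alzheimer's staging from paired structural-MRI tissue maps
(grey matter, white matter) and PET volumes, together with a synthetic
phantom generator that makes every mechanism testable offline.  This note
records the model as implemented, the parameters that matter, the synthetic
study conditions, and the design choices made where the architecture left
genuine freedom.

## Numerical core

No deep-learning framework is assumed: all networks run on a compact
reverse-mode automatic-differentiation engine over numpy arrays
(`admvnet.nn`).  It provides broadcasted arithmetic, batched matmul,
reductions, zero-padded slicing, dense and depthwise 3D convolution (im2col
with explicit scatter-gradients), and axis-wise linear resampling; adaptive
average pooling and trilinear interpolation are expressed as constant
row-stochastic matrices applied per axis, which makes their gradients exact
and their algebraic properties (idempotence at the target size, convexity)
trivially checkable.  Every analytic gradient is validated against central
finite differences in the test suite.  All computation is CPU-only,
single-process, and deterministic given the seeds.

## Backbone: hybrid convolution with guided diffusion

Each modality has an independent four-stage backbone (no weight sharing;
the modalities carry different physics).  A stage combines:

* **Standard convolution path (SCP)** — two conv–BN–ReLU blocks, the first
  with stride 2, giving the stage contract: channel width doubles along
  (32, 64, 128, 256) by default, spatial dims halve.
* **Semantic-difference-guided diffusion path (SDP)** — explicit nonlinear
  anisotropic diffusion on the stage's pre-features `F`:
  `Fhat_p = Σ_{pe∈δ_p} h(‖G_pe − G_p‖²)(F_pe − F_p)`, then
  `F ← λF + νFhat`, iterated `T` times.  `δ_p` is the 6-connected face
  neighborhood (the smallest stencil that realises anisotropic diffusion);
  boundaries are zero-flux.  The guide `G` comes from an in-stage
  down/up-sampled branch (1×1×1 conv at stride 2, trilinear resize back),
  so guidance reflects a coarser semantic view of the same features; below
  4³ the round trip is skipped because a 1-voxel guide would be spatially
  constant and carry no boundary information.  `h` is a two-layer
  perceptron on the scalar squared guide difference with a softplus output
  times a squared gain — nonnegative by construction, so the update is
  diffusion-like; setting the gain to zero switches the path off exactly,
  which the closed-form tests exploit (`h ≡ 0 ⇒ F^T = λ^T F⁰`).
  `λ, ν` are learnable scalars initialised to 1.0 and 0.1; `T = 2` by
  default.  With `h ≥ 0` the iteration obeys
  `sup|F^T| ≤ (λ + 6 ν h_max)^T sup|F⁰|`, asserted on random fields.
* **Direct mapping path** — a strided 1×1×1 projection of the input.

SCP and SDP are fused by a per-channel sigmoid gate computed from their
concatenated spatially-pooled outputs, then added to the direct path.
Inputs whose spatial dims are not divisible by 16 are zero-padded with a
logged warning (24³ phantoms run at 32³ internally).

## Three fusion views

**Global (GPM).**  Stage-4 maps pass per-modality multi-head attention in
which the key/value streams are pre-mixed by a depthwise-separable 3D
convolution (convolutional position information; no positional-encoding
table).  The modalities are then chained through a multimodal normalizer:
the WM stream has its batchwise affine predictability from the processed GM
stream removed, and PET likewise from the processed WM stream.  The
normalizer is a ridge-regularised least-squares projection with intercept,
computed per training batch and frozen into buffers for evaluation; it has
no learnable parameters, and its contract — residuals uncorrelated with the
predictor stream — is enforced in the tests against an independent lstsq
oracle.  Gradients flow through the features but not through the fitted
coefficients, which are treated as batch statistics.  A window-attention
branch over the summed modalities (non-overlapping windows, default 2³,
clipped to the available extent; padding cropped after attention) models
local interactions cheaply; window locality is exact and tested.  The four
streams are summed (the combining operator is not dictated by the
architecture; summation is consistent with the additive pre-alignment), fed
through a two-layer FFN and global-average-pooled to the global vector
`F_g ∈ R^{c4}`.

**Local (MLCA).**  The cross-modal per-stage sums of stages 1–3 (the
architecture does not define the initial fusion; elementwise sum keeps the
spatial registration) are projected to a common width (128 by default) by
1×1×1 convs, then refined by a bidirectional pass of weighted fusion
nodes, BiFPN-style: top-down coarse→fine, then bottom-up.  A node computes
`Σ w_i·U(F_i) / (Σ w_i + ε)` with rectified (hence nonnegative) learnable
weights, `ε = 1e-4`, and resampling `U` by trilinear interpolation upward
and a learnable strided conv downward (nodes whose wiring can never
receive a finer map do not instantiate the downsampler).  The normalized
combination is a convex combination of its inputs up to `ε` and is
invariant to rescaling all weights; both properties are tested, as is
equivalence to an independently coded evaluation of the formula.  A
pointwise conv + ReLU refinement follows so nodes are not purely affine.
The three refined maps are adaptively pooled to 4³, concatenated,
flattened and linearly projected to `F_m ∈ R^{c4}`.

**Latent (BCAM).**  Each stage-4 map is gated by channel attention: local-
and global-average-pooled descriptors pass a kernel-3 convolution along the
channel axis, a sigmoid, and a learnable convex mix (α through a sigmoid,
initialised to 0.5); the attention logits are computed on per-sample
channel-standardized descriptors so the gate responds to the channel
pattern, not overall intensity.  Gated maps are pooled to `(c4, da²)`
descriptors (`da = 4` by default, `da = 2` in the smallest test
configurations), combined pairwise by per-channel outer products
(PET–GM, GM–WM, PET–WM), summed, sum-pooled over both interaction axes and
L2-normalized to `F_b ∈ R^{c4}`.  Unit norm and invariance to positive
input rescaling are enforced to 1e-5; an exactly-zero pre-normalization
vector returns zeros with a degeneracy flag instead of dividing by zero.

The three view vectors are concatenated, linearly projected to `c4` with a
ReLU, passed through dropout (0.1) and a linear head to the trunk logits
`y_c`.  Any view can be ablated (its vector replaced by zeros) to mirror
module-combination experiments.

## ROI weighting (RIPM)

A 90-element region-weight vector ω is refined for `t` iterations.  Region
tokens `R0` and a hidden token are formed from the trunk logits by learned
expansions plus a learnable affine "deficit" encoding of per-region mean
intensities pooled over the parcellation (initialised as minus the summed
standardized modality means: a token starts near zero for cohort-typical
tissue and grows with atrophy/hypometabolism).  Grounding region index i
in parcellation region i is what makes planted-region recovery a
well-posed claim; logits alone carry no regional information.  Each
iteration maps the hidden token and `R0` through learnable 90×90 query /
key / value matrices, modulates all three elementwise by ω, forms a 90×90
row-stochastic attention (scaled by √90 for stability), produces the
salient-region feature `R_h = A(ω∘V)`, and updates ω with a GRU cell
(input `R_h`, hidden ω; update-gate convention such that a closed gate
leaves ω unchanged).  After `t` rounds (default 7), `R_h` maps to ROI
logits `y_cr`, fused as `ŷ = y_c + σ(α)·y_cr` with learnable α.  Reported
importance is softmax(ω), averaged over evaluated subjects for the ranked
region report.

Initialisation matters here: Q/K/V start at identity plus 1e-3 noise, the
GRU candidate at identity with zero-initialised gates (flat z = r = 1/2).
Randomly initialised gate weights imprint a fixed per-region pattern of
roughly ±1σ that swamps the evidence signal and makes the importance
ranking data-independent; with the identity-grounded start the ranking is
driven by regional evidence from the first forward pass and refined by
training.  All of these remain fully trainable, and the test suite checks
that every parameter receives gradient.

## Training protocol

SGD with momentum 0.9 and weight decay 1e-4; cosine-annealed learning rate
`lr(e) = lr₀(1 + cos(πe/E))/2`; global gradient-norm clipping at 5 (the
multiplicative attention/diffusion interactions otherwise diverge within a
few steps at usable learning rates); loss = cross-entropy on the fused
logits plus deep supervision (weight 0.3) on the trunk and ROI logits.
Deep supervision is load-bearing: once the trunk memorizes a small
training set its loss is ≈0 and the ROI head stops receiving gradient,
leaving its (well-generalising) logits orders of magnitude smaller than
the overfit trunk's.  Inputs are standardized per modality (z-scored
inside the brain mask) with statistics estimated on the training split
only and reused for held-out data; background stays exactly zero.

The documented defaults for the full protocol are lr 0.001, batch 16, 40
epochs, 10-fold stratified cross-validation with per-fold re-estimated
normalization statistics, subject-disjointness asserted on every split.
Metrics are ACC/SEN/SPEC, BAC = (SEN+SPEC)/2, and rank-based (midrank-tie)
AUC; paired two-sided t-tests compare per-fold metrics between
configurations, with a degeneracy flag when the fold differences have zero
variance.  Predictions use the argmax operating point.  The ROI-iteration
sweep (`t ∈ {1,3,5,7,9}`) reruns cross-validation per `t` and emits a
table; no ordering across `t` is asserted on synthetic data.

## Synthetic phantoms and study conditions

The generator emulates preprocessed, skull-stripped, co-registered
GM/WM/PET triplets: an ellipsoidal brain mask (semi-axes at 45% of each
dimension) partitioned into 90 Voronoi regions seeded inside the mask
(region identity is arbitrary but fixed by the parcellation seed), baseline
intensity 1 inside the brain, 0 outside; class-1 subjects get a mean shift
of −(effect × noise SD) in every planted region (GM/WM effects 1.0, PET
effect 1.5 by default — hypometabolism is typically the stronger signal);
i.i.d. Gaussian noise (SD 0.1) and an optional shared per-subject site
offset act inside the mask only.  Default cohort for the benchmark
experiment: 24³ voxels, 8 planted regions spread across the label range,
30 subjects per class for training and 15 per class held out, no site
offsets.

What the phantoms do not model: anatomy, partial-volume effects, texture
or shape change, scanner physics, longitudinal drift.  Passing tests
therefore demonstrate that the implementation is faithful and that the
architecture can detect and localise modality-consistent regional mean
shifts at realistic contrast — not clinical performance on real cohorts.

## Desk-scale configuration

The benchmark experiment runs a reduced configuration chosen to keep a
full training run around two minutes on one CPU core: widths
(8, 16, 32, 64) so `c4 = 64`, MLCA alignment width 32, 10 epochs, batch 8,
lr 0.01 (≈80 SGD steps cannot move a freshly initialised network at the
full-protocol 0.001).  The full-size defaults remain in place for real
data.  Under these conditions the held-out metrics land around ACC 0.87 /
AUC 0.91 with 8/8 planted regions recovered in the top 8 of the ROI
ranking (seed 0); `scripts/acceptance.py` recomputes these quantities from
scratch for any seed.

## Degenerate inputs and numerical choices

Batch-of-one normalizer calls pass features through with a warning;
single-class label vectors report AUC as missing; a zero pre-normalization
latent vector returns zeros plus a flag; non-finite losses abort training
and restore the last completed epoch's weights; non-finite attention or
backbone activations raise diagnostic errors naming the module.  Ranked
ROI reports use competition ranking with region id as the stable
tie-break.  Checkpoints store parameters and normalization buffers
(npz) beside a JSON copy of the configuration.

## Known limitations

Single-machine determinism is guaranteed, bit-identity across BLAS
implementations is not.  The attention in the ROI branch is structurally
rank-one per sample (queries and keys are ω-modulated vectors), which
limits how much inter-regional structure it can express; the grounding
through regional profiles, not the attention, carries most of the
localisation signal.  The printed dimensionality of the local view's
output and of its inputs is internally inconsistent in the source
architecture; this implementation keeps the backbone's true per-stage
shapes and projects the local view to `c4` so the three views are
concatenable.  `RegBN` here is a contract-faithful reformulation
(predictability removal without learnable parameters), not a reproduction
of the published optimizer's internals.
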