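# Methods

## Overview

`hemofuse` classifies intracranial haemorrhage subtypes on 2-D CT slices
with a four-stage pipeline: median-filter denoising, seagull-optimized
multilevel Otsu segmentation, fused capsule/inverted-bottleneck feature
extraction with entropy-based selection, and a fuzzy SVM whose
hyperparameters are tuned by deer hunting optimization. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic benchmark does and does not establish.

## Median filtering

Both filters compute the *lower median* of the window (exact for odd
windows, which reflect padding guarantees). The bisection variant never
builds a histogram: it maintains a candidate intensity range [lo, hi] and
a count of window pixels already discarded below `lo`; each round the
range is halved and the half that brings the cumulative count to at least
⌈n/2⌉ is kept (ties to the lower half, matching the lower-median
convention). This is exactly equivalent to the sorting median on every
input, which the suite checks on 100 random images. Defaults: 3×3
window, reflect padding — CT slices are smooth, and reflect padding
avoids a dark halo at the image border. The filter never introduces
intensity values absent from its input; idempotence is *not* claimed.

## Multilevel Otsu segmentation

The criterion is the pairwise between-class variance
d(t₁..t_k) = Σ_{n<m} ω_n ω_m (u_n − u_m)², over segments
(t_{n−1}, t_n] with t₀ = −1, t_{k+1} = L−1; empty segments contribute 0.
For k = 1 this satisfies σ²_total = σ²_within + σ²_between at every
threshold (asserted to 1e−9). The exhaustive solver enumerates all
tuples for k ≤ 3 (refusing when the enumeration exceeds a ~300k-tuple
budget) and breaks ties lexicographically.

The SOA solver searches k continuous coordinates in [1, L−2]; candidates
are sorted, rounded, and assigned −∞ fitness when rounding collapses two
thresholds (no repair — the objective stays pure). When every agent in
an iteration is degenerate the iteration simply produces no elitist
update; an error is raised only if the entire run never sees a finite
fitness. Defaults k = 2 (background / brain tissue / hyperdense lesion),
lesion mask = highest-intensity segment.

A note on the bimodal test fixture: with two *narrow* modes the criterion
is exactly constant across the inter-mode gap (the tails underflow to
zero mass), so the argmax is a tie plateau resolved to its left edge.
The oracle fixture therefore uses overlapping Gaussian components
(σ = 30 at levels 60/190), which keep d(t) strictly varying and put the
unique maximiser at the symmetric midpoint (≈125).

## Seagull optimization (SOA)

Control parameter A = f_c − x·(f_c/Max_iteration) with f_c = 2 decays to
exactly 0 at the final iteration; B = 2A²·r_d with r_d ~ U[0,1];
per-agent position update P′ = D_s·x′·y′·z′ + P_bs with
D_s = |A·P_s + B·(P_bs − P_s)| element-wise and (x′, y′, z′) drawn from a
logarithmic spiral r = u·e^{kv}, k ~ U[0, 2π], u = v = 1. Positions are
clipped to the box; the best-so-far agent is elitist and updated
synchronously at the end of each sweep. r_d and k are drawn per agent
per iteration. Because D_s ≥ 0 and the spiral factor is a scalar, a
single update step perturbs all coordinates with a common sign; the
spiral's heavy tail (r³ up to e^{6π}) supplies exploration and the decay
of A supplies contraction. Convergence is budget-dependent: on the 2-D
sphere the suite uses population 30 and 300 iterations (the same
iteration budget as the companion DHO test) and checks the median best
fitness over 20 seeds; the random-search comparison uses 3000 iterations,
where the multiplicative late-stage refinement dominates the 1/N rate of
uniform sampling.

## Deer hunting optimization (DHO)

Per iteration: wind angle θ = 2πa (a ~ U[0,1]); Z = ¼·log(j + 1/j_max)·b
with b ~ U[−1,1] and natural log (j starts at 1, so the argument is ≥ 1);
K = 2c with c ~ U[0,1]; p ~ U[0,2] per hunter. Branching per hunter:
|K| < 1 → successor update X′ = X_s − Z·p·|K·X_s − X|; else p < 1 →
leader encircling X′ = X_l − Z·p·|K·X_l − X|; else → angle update
X′ = X_l − p·cos(θ)·|X_l − X|. The leader is elitist (best ever); the
successor is the runner-up of the current population. The angle-update
angle is taken to be the current wind angle — the formulation leaves it
open, and this choice makes the leader an exact fixed point of that
branch. a, b, c are drawn once per iteration, p per hunter, maximising
within-iteration diversity while keeping runs bit-reproducible.

## Capsule encoder

Conv (16 filters, 5×5, stride 2, ReLU) → primary-capsule conv (4 maps of
4-D capsules, 3×3, stride 2) → squash → routing-by-agreement (3
iterations: softmax couplings over output capsules, coupling-weighted
sums, squash, logit update by prediction–output dot product) → entity
capsules. The feature vector is the flattened entity capsules. The
default is 6 entity capsules × 31 dimensions = 186 features: the one hard
constraint on the fused representation is its printed total length 1186,
and with the bottleneck path at 1000 the capsule path must contribute
186, which no uniform (count × dim) layout reaches with 9 capsules. A
9-capsule configuration remains supported and tested. Transform weights
are shared across spatial positions within each primary-capsule map
(conv-style sharing) so memory stays flat between 64×64 and 512×512
inputs; per-position weights would need ~400 MB at 512×512 for no benefit
to an untrained encoder.

## Inverted-bottleneck encoder

Stem conv (8 filters, 3×3, stride 2) with a variance-guarded channel
normalisation (ε = 1e−5, so all-zero input stays finite), then three
MBConv-style blocks (pointwise expand ×4 → depthwise 3×3 → pointwise
compress) at widths 16/24/32 with stride 2, one stride-1 residual block
at width 32, a pointwise head to 1000 channels, swish activations, and
global average pooling. Output length m = 1000.

Both encoders are *untrained but seeded*: they act as fixed random
projections (random-features sense), deterministic given their seed.
This is a deliberate desk-scale choice — the synthetic lesions are
geometrically separable, so fixed random convolutional features carry
enough signal, and training would add nothing the tests could verify
cheaply. Consequently the pipeline's absolute accuracy on *real* CT data
says nothing until the encoders are trained; the package's claims are
about the pipeline mechanics, not ImageNet-scale representation quality.

## Entropy-based feature selection

Each fused feature column is discretised into 16 equal-width bins over
its observed range; the score is the Shannon entropy −Σ p log₂ p
(constant columns score 0). The `keep` highest-entropy columns are
retained, ties resolved to the lower index. Default keep = 512 of 1186.
Selected features are standardised with training-split statistics before
classification.

## Fuzzy SVM

Dual: max_α Σα_i − ½ΣΣ α_i α_j y_i y_j K(x_i, x_j) subject to
Σ y_i α_i = 0 and 0 ≤ α_i ≤ s_i·C. Solved by a maximal-violating-pair
SMO with incremental gradient maintenance; stopping tolerance 1e−8
(tests that compare against an independent SLSQP solve of the same dual
use 1e−10 and agree to better than 1e−6 on the coefficients). The bias
averages y_i − f_i over free support vectors; if none are free it falls
back to the midpoint of the KKT interval and flags the model degenerate.

Memberships default to the centroid-linear scheme
s_i = 1 − d_i/(d_max + δ), δ = 1e−6·d_max, clamped to [σ, 1] with
σ = 0.05, computed per class; a uniform scheme (s ≡ 1, recovering the
plain C-SVM exactly) is available. Multiclass is one-vs-rest with argmax
decision values, memberships recomputed per binary problem. Kernels:
linear, RBF (γ defaulting to 1/(n_features·Var(X))), polynomial. Note
that duplicating the training set is equivalent to doubling C, so the
boundary is duplication-invariant only while no α sits at its cap (all
support vectors free); the test constructs that regime explicitly.

## Synthetic benchmark

Slices are 64×64 by default (512×512 supported): background 60, brain 80,
skull ring 90, lesion intensities U{200..235}, then Gaussian noise
(σ = 4) and salt-and-pepper corruption of exactly round(0.02·N) pixels.
The dark structures span a tight band while the lesion sits far above
it, so even single-threshold Otsu isolates the lesion exactly on clean
slices (IoU 1.0 in the suite). Lesion geometry per subtype: EPI biconvex
lens at the inner skull margin, SBD thin crescent hugging the skull, IPC
compact parenchymal blob, IVT small flattened central blob, SAD 2–3 thin
streaks. These are cartoon proxies of radiological appearance, not
anatomy: no Hounsfield calibration, no partial-volume effects, no 3-D
context, no inter-patient variability. A linear model on four mask
descriptors (area, eccentricity, skull-contact fraction, log elongation)
separates the five classes at ≈98%, which guarantees the end-to-end
pipeline has signal to find — and bounds what a pass means: recovery of
*geometric* class structure, not clinical performance.

Class counts default to the benchmark distribution (EPI 171, IVT 24,
IPC 72, SBD 56, SAD 18; 341 total), scalable by a factor.

## Pipeline protocol and problem sizes

Each run: stratified 70/30 train/test split (run-index-offset seeds);
entropy selection fitted on the training split; DHO tuning (population 4,
6 iterations) of (log₁₀C ∈ [−1,3], log₁₀γ ∈ [−6,0]) by validation
accuracy on a 75/25 sub-split of the training data; final FSVM trained on
the full training split. Segmentation uses SOA with population 15 and
40 iterations per slice — the 64-level-scale landscapes are easy and the
full 341-slice run completes in well under a minute on one CPU. Whether
the published evaluation used held-out data is not stated anywhere;
held-out is the defensible default and is what the macro numbers here
mean.

## Known limitations

* Encoders are untrained; see above. A training loop is intentionally
  out of scope.
* SOA's printed update couples all coordinates through one scalar spiral
  draw, which slows high-dimensional refinement; for the k ≤ 3 threshold
  searches used here this is immaterial.
* The DHO angle-update angle and the SOA best-update schedule
  (synchronous) are documented interpretations of an under-specified
  formulation; both are configurable in code.
* One-vs-rest FSVM with plain accuracy as the tuning objective can
  under-serve the rarest subtype (SAD, 18 of 341 slices); the per-class
  tables make this visible rather than hiding it in a pooled accuracy.
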