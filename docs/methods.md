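# Methods

## Protocol

The network is cut after the first hidden layer.  Every end-system holds one
copy of that layer — one same-padding 3×3 convolution + ReLU + 2×2 max-pool
for image tasks, one dense layer + leaky-ReLU (slope 0.01) for the tabular
task — and the server holds everything after the cut.  Per round, each
end-system forwards a local mini-batch, and the resulting feature maps are
concatenated **along the sample axis** in ascending client order.  We chose
the sample axis (rather than channels) because end-systems hold disjoint
patients: the server's input shape must not depend on how many hospitals
participate, and each sample's features come from exactly one hospital.

Labels travel with the feature map; this is the vanilla (non-U-shaped)
variant of split learning in which the server computes the loss.  Label
privacy is therefore *not* provided, only input privacy.

The joint loss is the mean over the joined batch, so the gradient the server
returns to client $k$ is exactly $\partial \mathcal{L} / \partial A_k$, and
the sum over clients of the client-parameter gradients equals the gradient
of centralized training on the pooled batch.  Two client-weight regimes:

- **independent** (default): each hospital's layer evolves on its own
  gradient slice with its own Adam state.  Held-out evaluation then uses the
  element-wise mean of the client layers as the deployed first layer — the
  pragmatic choice, since a single deployable model is needed and the mean
  coincides with every client's copy under synchronization.
- **sync_mode**: the summed client gradients are applied through every
  client's optimizer each round (followed by a parameter-mean
  synchronization, which is then a no-op).  Because the summed slice
  gradient *is* the pooled-batch gradient and all clients start from the
  same initialization, a sync-mode run is step-for-step identical to
  training the monolithic network centrally on the identical batches.  The
  test suite verifies per-step losses agree within 1e-5 relative (measured:
  ~1e-15) against an independently coded centralized loop.  Parameter-mean
  averaging *alone* would not give this equivalence (Adam is nonlinear, and
  averaging K independent SGD steps rescales the effective step by 1/K),
  which is why synchronization operates on gradients.

An epoch is `ceil(n_train / global_batch)` rounds.  Each client shuffles its
indices once per epoch and deals them into that many near-equal chunks, so
every client traverses its own data exactly once per epoch and per-round
contributions are proportional to local dataset size (an `equal` batch
policy, cycling smaller clients' data, is available).  Global batches are
apportioned over clients by the same largest-remainder rule used for data
partitioning.

## Partitioning

Ratio strings like `8:1:1` are apportioned by the largest-remainder
(Hamilton) method computed in exact integer arithmetic: floors of the exact
quotas, leftovers by descending remainder with ties to the lower client
index, then a repair pass that guarantees every client at least one sample
by donating from the client whose count most exceeds its quota (ties to the
higher index).  This makes the result the lexicographically-greatest L1
minimizer of |count − quota| subject to sum preservation and count ≥ 1,
verified exhaustively against brute-force enumeration for n ≤ 30 and up to
4 clients.  Float remainders are deliberately avoided: quota ties (e.g.
n=10 at 1:1:1) must be genuine ties, and last-ulp noise would otherwise
break the documented tie-break.

Classification partitions are stratified by default: classes are dealt
largest-first by apportioning each class over the clients' remaining
capacities, keeping each client's class mix within about one sample of the
global proportions (exact to ±1 for binary labels; multi-class mixes can
drift slightly more).  A class with fewer samples than clients is assigned
round-robin with a warning.  A stratified 20% held-out split is carved out
*before* any client partitioning and shared by all configurations of a grid;
the imbalance ratios apply to the remaining 80% only.

## Models

Layer widths are the smallest configurations consistent with the declared
layer counts: the image client layer has 8 filters (3×3, stride 1, same
padding); the custom CNN server has three conv+pool blocks of 16/32/64
filters then flatten + dense(1, sigmoid), i.e. 4 server hidden layers; the
tabular split is dense(32, leaky-ReLU) on the client and dense(16,
leaky-ReLU) + dense(1, linear) on the server.  The VGG19-style split places
the client conv (+ its 2×2 pool) *in front of* the standard 19-weight-layer
VGG19 stack (16 convs + two dense(4096) + a 1-unit sigmoid output in place
of the 1000-way classifier), giving 1 + 19 = 20 weight layers on a grayscale
input; no pretrained weights are used (none exist for 1-channel 224×224
inputs).  Transmitted feature maps are post-activation.

The layer engine is pure NumPy (float64): im2col convolutions, argmax-routed
max pooling (odd trailing rows/columns are dropped), Glorot-uniform
initialization from per-run seed streams, and Adam (β₁=0.9, β₂=0.999,
ε=1e-8).  The sigmoid/BCE and linear/MSE output pairs use the fused
closed-form gradient at the output pre-activation, avoiding the unstable
d(loss)/d(probability) route; BCE clips probabilities at 1e-7.  Analytic
gradients are verified against central finite differences (relative 1e-3;
measured ~1e-7) for every layer kind, both for client parameters through the
full split pipeline and for the gradient at the cut.

**Learning rate.**  The default Adam step is 3e-3.  Desk-scale budgets give
the optimizer only ~100 steps for the image tasks, so the textbook 1e-3 is
too timid to move Glorot-scale weights to a solution; on the synthetic image
benchmark 3e-3 converges reliably where 1e-2 is erratic and 2e-2 can
diverge.  Tabular runs use 1e-2 (the loss surface of the near-linear
standardized problem is benign) with a global batch of 64 at desk scale, so
the 50-epoch budget provides ~3000 steps.  All of this is configurable per
run.  The built-in specs carry the canonical epoch/batch values (100/64,
50/128, 200/2048); tests and the acceptance script override them downward to
desk scale.

Regression preprocessing: features and target are z-scored with training-set
statistics inside `train`; predictions are mapped back to mg/dL and floored
at zero before the RMSLE is computed.

## Synthetic data

**Images.**  Negatives are a smoothed Gaussian texture (σ = size/16),
mean-centred per image, scaled to peak amplitude 0.25 around a 0.5
background — so at zero pixel noise every negative has pixel mean exactly
0.5.  Positives add 1–3 soft elliptical blobs (radii in [size/10, size/5],
peak `lesion_contrast`), so their mean is strictly larger: the classes are
separable by a pixel-mean threshold *by construction*, which the tests
exploit as an exact oracle at `noise_sd=0`.  Defaults for experiments are
400 images of 32×32 at contrast 0.5 and pixel noise 0.1.  The generator
emulates the *structure* of two-class grayscale medical imaging (lesion
present/absent), not its difficulty: real CT/X-ray classification has no
such mean shortcut, so accuracy numbers on this data say the pipeline can
learn, not how well the architectures would do clinically.

**Cholesterol.**  Covariates: age ~ U(20, 80), sex ~ Bernoulli(0.5), height
~ N(165, 10), weight ~ N(70, 15), TC ~ N(190, 35) truncated below at 60,
TG ~ LogNormal(ln 120, 0.4) truncated above at 5(TC − 6), HDL-C ~ N(55, 12)
truncated to (0, TC − TG/5 − 1).  The truncations guarantee the clean
Friedewald value TC − HDL-C − TG/5 is strictly positive, so at `noise_sd=0`
the identity holds *exactly* (and ordinary least squares recovers
(1, −1, −0.2) to machine precision), while the flooring of noisy targets at
0 almost never binds.  Age/sex/height/weight are nuisance covariates with no
effect on the target — a trained model must learn to ignore them.

A caution on RMSLE at the default `noise_sd = 5` mg/dL: about 1% of rows
have small LDL-C, where the log metric amplifies the ±5 noise, so even the
*true clean values* score ≈ 0.086 on a held-out fifth (exact OLS ≈ 0.087).
A converged split-trained MLP therefore lands in the 0.08–0.13 range
depending on the run seed — near the statistical floor of the task, not far
above it.

## Experiments and reproducibility

The grid runner trains every (end-system count × ratio × seed) cell on a
shared dataset and shared held-out split, writes one tidy CSV row per cell
plus a pivoted one-row table, and resumes from per-cell JSON markers.  All
randomness flows from per-purpose `SeedSequence` streams (data, test split,
partition, initialization, shuffling), so a grid rerun with the same seeds
reproduces its CSVs byte for byte; wall-clock timings are kept out of the
reproducible outputs.  Default grid problem size — 400 images of 32×32,
10 epochs, the 8-filter CNN — was chosen so the full nine-cell grid runs in
about a minute on one CPU.  The summary ranks cells by the final metric
with ties broken toward more clients and then toward more imbalance
(variance of the normalized shares), reflecting a preference for the
configuration that lets the most hospitals participate; a delta-to-best
column quantifies the cost of that preference.  No monotone trend in
accuracy versus imbalance is asserted anywhere: on IID synthetic data there
is no reason the real-data imbalance effects should reappear.

## Privacy audit

The audit quantifies what is otherwise shown visually.  Each feature-map
channel is bilinearly upsampled to the input size and scored by absolute
Pearson correlation with the input (zero-variance channels score 0); a
linear-inversion score fits the input pixels by least squares on the
upsampled channels plus intercept and reports RMSE normalized by the
mean-baseline RMSE (1 = nothing recovered linearly, 0 = perfect inversion).
Degenerate cases anchor the scale exactly: a feature map equal to the image
scores correlation 1 and nRMSE 0; an all-zero map scores 0 and 1.  Scores
for trained layers are *reported, not thresholded*: a single conv+pool layer
is a weak obfuscator and no formal privacy guarantee (differential privacy,
resistance to nonlinear reconstruction) is claimed or tested.

## Known limitations

- The protocol is simulated in-process; serialization, transport, and
  asynchrony are out of scope by design (the message boundary is explicit
  and auditable, nothing more).
- Labels are exposed to the server; no U-shaped variant.
- Multi-class outputs, data augmentation, and pretrained backbones are not
  supported.
- The VGG19-style configuration is buildable and shape-checked but too large
  to train meaningfully at desk scale; tests exercise it at reduced input
  sizes.
- Stratification guarantees ±1 class balance only for binary labels.
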