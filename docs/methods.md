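# Methods

This note documents the models and procedures implemented in `ipclbrain`,
the assumptions behind them, the synthetic data they are exercised on, and
the numerical and design choices a user should know before trusting or
extending the results.

## Instance-prototype contrastive learning

### Objective

Each training image is sampled with `n_views` (default 5) stochastic
augmentations. The encoder maps every view to a 128-dimensional embedding
`v` that is L2-normalized onto the unit hypersphere, so similarity is the
dot product (cosine). The *instance prototype* `p_i` is the renormalized
mean of instance *i*'s view embeddings. With a FIFO memory queue `Q` of
recently encountered items (one slot per image, holding its prototype,
stored detached), the per-view loss is a non-parametric softmax

    l(v) = -log [ exp(v·p_i / τ) / ( exp(v·p_i / τ) + Σ_{q∈Q} exp(v·q / τ) ) ]

and the training loss is the mean of `l` over all views and instances. The
positive term pulls views toward their prototype (alignment); the queue term
pushes them away from recent items (uniformity over the hypersphere). An
empty queue makes the ratio 1 and the loss exactly 0. Gradients flow through
both the view and the prototype (the prototype is a function of the same
batch); `prototype_gradient=False` stops the prototype path for ablations.
An optional flag (`batch_negatives`) adds the other instances' prototypes in
the current batch to the negative set, with gradient, so batch members
mutually repel; the default objective uses queue entries only.

Temperature τ defaults to 0.07, the convention of the instance-
discrimination lineage this objective belongs to. The queue holds 4096
items by default.

### Encoders

Two group-normalized convolutional encoders share one contract (named
blocks, flattened activation extraction, an L2-normed embedding head or a
classifier head for the category-supervised comparand):

* `alexnet_gn` — AlexNet (conv1…conv5, fc6, fc7) with group normalization
  (32 groups) after every convolution and fully connected layer, 224×224
  input, 128-d embedding. This is the reference architecture; training it
  to convergence is a cluster-scale undertaking and is not attempted here.
* `tiny_gn` — a desk-scale encoder for 32×32 inputs: three conv blocks
  (16/32/64 channels, each conv–GN–ReLU–maxpool) and two 128-wide fully
  connected blocks, with the same layer-naming and extraction contract.

Group normalization normalizes groups of channels *per image* (no batch
statistics), with learnable per-channel scale and shift. Convolutional
activations are flattened channel-major then spatial row-major; any fixed
order is equivalent for the downstream analyses (they are permutation-
invariant over units), but the order is pinned so caches are reproducible.

The whole stack — convolution (im2col), group norm, max pooling, linear
layers, L2 projection, SGD with momentum and cosine decay — is implemented
in NumPy with hand-derived backward passes. Every backward pass is verified
against finite differences in the test suite, and the contrastive loss
gradient additionally against an independent scalar-loop oracle.

### Small-scale training dynamics and their stabilizers

At the scale this package trains (hundreds of images, a tiny encoder), the
objective has a degenerate optimum that large-scale training rarely visits:
a *constant encoder*. View alignment is perfectly satisfied by mapping every
input to one point, and once embeddings are tightly clustered the queue term
provides almost no differential pressure (all negatives are equidistant).
Worse, while the queue is shorter-lived than the dataset is large, the
encoder can reduce the loss each step by translating the entire embedding
cloud away from the queue's recent entries — a treadmill that terminates in
the constant map. We verified that the gradients are exact (finite
differences, end to end) and that the same encoder trains fine with a
supervised objective; the collapse is a property of the optimization
landscape at small scale, not of the implementation.

Four stabilizers keep the desk-scale model out of this regime; all are
config-exposed, all default off for the large-scale configuration, and the
shape-world study configuration (`ipclbrain.config.shape_world_training`)
enables them:

1. **Batch-centered embedding head** (`tiny_gn` only): the pre-normalization
   embedding is centered across the batch during training (a running mean is
   subtracted at evaluation). A constant encoder output becomes structurally
   impossible. The `alexnet_gn` head is kept plain.
2. **Queue warmup**: before the first update, one forward pass over the
   dataset fills the queue with prototypes, so hard negatives exist from
   step 0 (otherwise the first few steps are pure alignment, which erases
   feature variance within ~15 updates).
3. **Learning-rate warmup** (3 epochs linear), protecting the same early
   transient.
4. **Study hyperparameters**: temperature 0.15, learning rate 0.01, momentum
   0.5, constant learning rate after warmup, queue capacity 256 (smaller
   than the dataset, so an image's own recent prototype is usually not among
   its negatives), and within-batch prototype negatives (translation cannot
   separate an item from negatives that co-move with it).

Under these conditions, on the default shape world (4 classes × 100
instances, 25 epochs, ~2.5 minutes on one CPU core), the weighted-kNN
readout of the trained embedding reaches roughly 80% against a 25% chance
level and a ~50% untrained-control baseline; the training loss decreases
monotonically. None of this says anything about ImageNet-scale behavior; it
demonstrates the mechanism, not the benchmark.

## Augmentation

Views are produced by random resized crops (area fraction 0.2–1.0 by
default, aspect 3/4–4/3), horizontal flips, random grayscale (p = 0.2), and
brightness/contrast/saturation/hue jitter (±0.4, hue as a fraction of the
full circle), then resized and channel-normalized with the conventional
natural-image statistics. Rotation is deliberately absent from the default
scheme (orientation is never jittered across samples); a flag exists for
ablations. Pixel values are clamped to the valid range after jitter;
normalization is applied last.

The shape-world study uses the same family with less extreme parameters
(crop 0.6–1.0, jitter 0.2, hue 0.05, grayscale 0.1): at 32×32 with a single
object per image, an aggressive crop frequently contains only background,
and views that share no content make the alignment term destructive.

## Synthetic fixtures

### Shape world

`generate_shape_world` draws one procedural shape per image (triangle, disc,
square, cross, ring, diamond — class = shape) on a noisy gray background.
Within a class, position (±12% of the frame), size (radius 30–45% of the
frame) and hue (free) vary per instance, so category identity is carried
only by geometry — exactly the "statistical structure of the input" premise
that emergent category structure relies on. Labels accompany the images for
*readout only*; the contrastive objective never sees them. Generation is
deterministic per seed. The generator makes no attempt to mimic natural
image statistics beyond this; a passing emergent-category test shows that
the objective extracts shared geometry from image covariance, not that it
would reproduce published benchmark accuracies.

### Synthetic subjects

`generate_synthetic_subjects` emulates the voxel model assumed by the
encoding analysis: every voxel is a weighted combination of one layer's
units. The generating feature matrix (conditions × units) is standardized
per unit and row-centered (both operations leave the layer's correlation-
distance RDM unchanged; row-centering additionally makes the voxel-mixture
geometry converge to exactly that RDM as voxels accumulate). Mixture weights
are half-normal, |N(0,1)|/√units, shared across subjects; each subject adds
independent Gaussian noise per voxel and condition. Consequently:

* `noise_sd = 0` gives every subject identical responses, hence identical
  RDMs and a split-half noise ceiling of 1;
* `noise_sd` is in units of the (≈ unit-variance) voxel signal, so 1.0 means
  a one-to-one signal-to-noise ratio;
* the ground-truth weights are returned for recovery tests;
* an optional `weight_seed` fixes the mixture while the subject noise varies
  — "replicate worlds" sharing one planted voxel model, used for ceiling
  calibration;
* `calibrate_noise_sd` finds, by simulation, the noise level whose expected
  split-half ceiling matches a target (the default study setting of 0.5–1.0
  brackets the 0.6–0.9 ceilings typical of reliable condition-rich data).

No hemodynamics, spatial smoothness, or GLM estimation is modeled.

## Voxel-wise-encoding RSA (veRSA)

For each layer and subject, every voxel's response profile over conditions
is fit with ridge regression on the layer's units in a leave-one-condition-
out loop: the held-out condition's response is predicted from a fit that
never saw it; assembling all held-out predictions gives a cross-validated
predicted response matrix R̂. Features are standardized per unit with
statistics frozen from each training fold (ridge penalties are scale-
sensitive and conv-layer unit scales vary wildly). The ridge is solved in
the sample (dual) space via an eigendecomposition of the training Gram
matrix, so very wide layers cost the same as narrow ones; the penalty λ is
selected *per voxel* by the closed-form leave-one-out error within the
training fold over a 9-point grid, log-spaced 1e-3…1e5 (ties go to the
smaller λ). λ is strictly positive; the λ→0 limit equals ordinary least
squares when units < conditions.

The predicted geometry Ĝ is the correlation-distance RDM of R̂; the measured
geometry G is the RDM of the measured responses. For every unordered
split-half of subjects, each half's predicted RDMs are averaged
(arithmetically, entrywise — a flag switches to Fisher-z averaging) and
correlated (Pearson over the strictly-lower triangle, row-major order
pinned) with the same half's group-mean brain RDM. Both orientations of
every split contribute an r value. Layer summaries are Fisher-z means
(|r| clipped at 1−1e-7 before atanh, since noise-free fixtures legitimately
reach r = 1) with a non-independence-adjusted 95% CI (below). Split-half
enumeration is exhaustive up to 126 bipartitions and a seeded uniform
subsample beyond. Fit values are not corrected for using half the subjects;
they are directly comparable to the identically-estimated noise ceiling.

**Classic RSA** uses the same split scheme but correlates the RDM of the raw
layer activations with the group-mean brain RDMs — no encoding model, no
unit weighting.

**Noise ceiling**: per split, the two halves' group-mean brain RDMs are
correlated; the ceiling is the Fisher-z mean over splits (negative values
are reported as-is).

**Cross-validated max layer (cv max-r)**: per split and orientation, the
layer with the highest veRSA correlation on the selection half is chosen
(ties break toward the earlier layer) and the *other* half's correlation for
that layer is recorded; the cv max-r is the Fisher-z mean of those held-out
values. Selection never sees the evaluation data, which removes the
optimistic bias of taking the max over layers directly (property-tested on
null data).

**Explained proportion**: 100 × (model mean r) / (ceiling mean r); a flag
computes the squared-ratio reading instead. The plain ratio is consistent
with how such percentages are conventionally reported alongside ceilings.

### Known property: same-subject encoding bias

The predicted RDM of a subject is built from encoding fits to that same
subject's (noisy) data, and the split-half correlation compares it to a
brain RDM from the same participants. Leave-one-out removes the held-out
condition, but the *geometry* of R̂ still shares subject-level noise with G.
Two consequences, both visible in the fixtures and documented rather than
hidden: (a) with flexible feature bases, veRSA correlations can exceed the
noise ceiling (explained proportions slightly above 100% on synthetic
worlds); (b) a refit-on-shuffled-data null is not centered on zero. The
permutation null we test instead breaks the correspondence *after* fitting
(permuting the brain RDMs' condition labels), which is centered on zero. A
related generic property: leave-one-out predictions of a shrinkage estimator
are slightly *anti*-correlated with held-out noise (prediction ≈ training
fold mean), so the pure-noise encoding check is one-sided (no positive
predictivity).

### Layer identifiability at desk scale

When a layer has more units than there are conditions, the leave-one-out
ridge interpolates and held-out predictions are governed by the layer's
condition-similarity kernel rather than by the planted mixture, so *every*
wide layer predicts planted voxels about equally well. The demo pipeline
therefore subsamples layers to `max_units = 24` units (seeded) before
encoding, keeping units below the 40 conditions; planted-layer recovery is
then exact in the noise-free limit. Unit subsampling is off by default in
the library functions.

## Emergent-category readouts

* **Weighted kNN**: neighbors are the top k = 200 bank items by cosine
  similarity (the whole bank when it is smaller); each neighbor contributes
  exp(similarity / 0.07) to its class; the top-weighted class is the
  prediction, with ties broken toward the lowest class index. A flag
  excludes self-matches when the queries are the bank itself.
* **Linear probe**: a softmax classification layer trained by full-batch
  gradient descent from zero-initialized weights on frozen, standardized
  features (penultimate layer, fc7, by convention). With zero epochs the
  untrained probe ties all classes and the argmax policy makes the analytic
  accuracy 100/C on balanced classes — a pinned degenerate case used as a
  test anchor. The probe is cross-checked against scikit-learn's logistic
  regression on separable problems.

## Corrected statistics

Scores computed on overlapping subject split-halves are not independent.
Following the corrected repeated-resampling t-test, the paired t statistic
over J splits uses variance inflated by (1/J + n2/n1), where n2/n1 is the
test/train size ratio — ⌈n/2⌉/⌊n/2⌋ for split-halves. With ratio 0 the
statistic reduces exactly to the classical paired t-test. Differences
between correlations are taken on the Fisher-z scale (an explicit flag;
pipeline callers enable it). Confidence intervals use the same inflated
variance on the z scale, mapped back through tanh. Two-sided p-values come
from a t distribution with J−1 degrees of freedom. Family-wise control is
Bonferroni (α/m; the demo uses α = 0.05, m = 30). Degenerate input policy:
identical score lists return t = 0, p = 1; zero variance with a nonzero mean
difference raises an error rather than reporting an infinite t.

On simulated null worlds the corrected test rejects no more often than the
naive paired t (which is badly anti-conservative there); the correction is
an approximation, not an exact calibration, and with few subjects it can
remain somewhat liberal.

## Problem sizes used by the test suite and the acceptance script

Training: 4 classes × 100 images at 32×32, 5 views, batch 32, 25 epochs.
Encoding analyses: 18–40 conditions, 10–24 units after subsampling, 30–200
voxels, 4–8 subjects (35 exhaustive split-halves at n = 8). Monte-Carlo
checks: 15–30 replicate worlds; null calibrations: 200 worlds. These sizes
were chosen so the full suite runs on a single CPU core in minutes while
every qualitative property of the method is exercised.

## Limitations

* The collapse stabilizers above are *necessary* at desk scale; nothing here
  validates the large-scale defaults beyond unit correctness.
* Synthetic subjects share one set of mixture weights; real subjects differ
  in functional architecture, so between-subject variance is understated.
* The correlation-distance RDM and Pearson RDM comparison are the only
  distances implemented; no crossnobis/Euclidean variants.
* The same-subject encoding bias means absolute veRSA levels on these
  fixtures should not be read as unbiased estimates of model-brain fit; the
  package's claims are about orderings, recoveries, and calibrations, each
  of which is tested.
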