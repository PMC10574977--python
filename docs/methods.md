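# Methods

## Problem setting and model

`trustauc` addresses binary image classification where negatives heavily
outnumber positives and where the *trustworthiness* of predictions matters
as much as raw accuracy. The pipeline has three stages: contrastive
self-supervised pre-training of a convolutional backbone, supervised
fine-tuning with an AUC min-max margin surrogate, and question–answer trust
quantification on the held-out test split. Each stage is a plug-in: the
backbone is any callable mapping an image batch (n, c, h, w) to a feature
matrix (n, d), the pre-training stage can be skipped (`use_ssl=False`), and
the fine-tuning loss can be switched to cross-entropy, which together define
the three ablation arms SL, SL+SSL and SL+SSL+AUC.

### Contrastive pre-training

Two independently sampled augmentations of each image form a positive pair;
the other 2N−2 views in a batch of N images are negatives. Views are
embedded by the backbone plus a two-layer projection head (linear → ReLU →
linear, 128-d output), L2-normalised, and scored with the
normalised-temperature cross-entropy (NT-Xent) loss at temperature τ = 0.5.
The projection head exists only during pre-training and is stripped from the
checkpoint. Labels are never read in this stage (enforced by a test).

Default augmentation suite (grayscale-safe): random resized crop retaining
50–100 % of the area, horizontal flip with probability 0.5,
brightness/contrast jitter of ±0.4, optional Gaussian blur (off by default).
The identity policy is expressible and is a verified no-op.

### AUC margin fine-tuning

The surrogate objective on sigmoid scores h ∈ [0,1] is

    F = mean_pos (h−a)² + mean_neg (h−b)² + 2α(m − mean_pos h + mean_neg h) − α²

minimised over network weights and auxiliaries (a, b), maximised over the
dual α ≥ 0. Its analytic saddle is a = mean_pos h, b = mean_neg h,
α = max(0, m − mean_pos h + mean_neg h), where F reduces to
VarPos + VarNeg + max(0, m − mean_pos + mean_neg)² — the property the test
suite checks on random batches. Updates are primal–dual stochastic
gradient: weights and (a, b) descend, α ascends and is projected onto
[0, ∞) after every step; (a, b, α) persist across batches. Because the
objective is undefined on single-class batches, the AUC path uses a
stratified batch sampler that deals shuffled positives and negatives across
batches so each batch contains at least one of each.

Defaults: margin m = 1 (the canonical choice for scores confined to [0,1],
where mean_pos − mean_neg = 1 means perfect confident separation); dual
learning rate equal to the primal rate; SGD with momentum 0.9.

**Auxiliary initialisation.** (a, b) start at 0.5, not 0. An untrained head
emits scores near 0.5; starting the auxiliaries at 0 makes the first updates
drag every score toward 0, where the sigmoid saturates and score gradients
vanish before the dual variable can grow — a collapse we observed
reproducibly at desk scale. Starting at the score-range midpoint removes the
transient entirely.

### Trust quantification

Threshold t maximises positive-class F1 on the validation split; candidates
are the midpoints between consecutive distinct sorted scores plus
0.5·min(s) and 0.5·(1+max(s)), so the search is finite and complete. Ties
at the threshold classify as positive, and among equal-F1 candidates the
smallest wins — both choices favour sensitivity for the minority class.
Scores are then normalised by the piecewise-linear map anchored at
(0, t, 1) → (0, 0.5, 1); the map is anchored at the theoretical sigmoid
score bounds rather than observed min/max so it is dataset-independent and
deterministic. Confidence in a positive answer is the normalised score p;
in a negative answer, 1−p. Per-sample trust is Q = C^α for correct answers
and (1−C)^β for incorrect ones (α = β = 1 by default), and the headline
number is the mean Q over ground-truth-positive test samples. A symmetric
negative-class mean is computed as auxiliary output.

### Model selection and protocols

During fine-tuning, a class-balanced validation split is carved from the
train split: validation size is round(fraction × n_train) with
fraction = 0.10 by default, each class contributes floor(val_size/2), an odd
leftover slot goes to the majority class (preserving scarce positives for
training), and a class smaller than its quota is taken whole with a warning.
Five checkpoints are kept per run — best validation accuracy, AUC, F1 (at
threshold 0.5; the calibrated threshold is computed post hoc to avoid
circularity between selection and calibration), lowest validation loss, and
last epoch — with first-epoch-wins tie-breaking. Cross-arm comparisons use
the best-validation-F1 checkpoint.

Cross-validation stratifies folds by class (unstratified folds on heavy
imbalance can produce positive-free validation sets, making F1 selection
undefined); folds govern training/validation while the fixed test split is
the common evaluation target, and with SSL enabled the backbone is
pre-trained once on the full train split and shared across folds. The
summary prints mean ± half-range, (max−min)/2 in percent of the metric
scale; the dispersion convention is recorded in the output metadata.

## Evaluation and explanation

ROC AUC is the exact Mann–Whitney pairwise statistic (half credit for
ties), computed via average ranks and cross-checked against a double-loop
enumeration in tests. Confusion-matrix metrics with zero denominators are
reported as NaN and flagged rather than raised. Grad-CAM weights each
channel of a target convolutional layer (default: the last one) by the
spatial mean of the class-logit gradient, rectifies the weighted sum,
bilinearly upsamples to input resolution and min-max normalises to [0,1];
all-zero maps stay all-zero, and a constant positive map normalises to all
ones. Embeddings for cluster plots are the penultimate (pre-head) features;
2-D projection of those embeddings is left to external tools — the tested
surface is the embedding matrix itself.

## The CNN engine

No deep-learning runtime is part of the dependency set; the package ships a
small float64 numpy engine (valid-padding 3×3 convolutions implemented as a
sum over kernel offsets, 2×2 max pooling, global average pooling, dense
layers, SGD with momentum) whose every layer is verified against central
finite differences in the test suite. The default backbone for desk-scale
work is conv(8)–relu–pool–conv(16)–relu–pool–GAP (16-d features). The
engine is single-threaded-deterministic: identical seeds reproduce
bit-identical training histories. Checkpoints are `.npz` weight archives
with a JSON sidecar describing architecture and provenance.

## Synthetic data

The generator emulates a small, heavily imbalanced grayscale screening
dataset. Every image is a flat background (0.35) plus i.i.d. Gaussian pixel
noise (sd 0.15 by default); positives additionally receive one additive
Gaussian-profile bright blob of random radius (4–8 px at 32×32) at a random
location, scaled by `signal_amplitude` — the simplest controllable,
localisable class signal, which lets Grad-CAM output be checked against the
planted blob geometry (recorded in a `blobs.json` sidecar that models never
see). At `signal_amplitude=0` the classes are indistinguishable by
construction; at 0.75 (5× the noise sd) whole-image mean intensity already
separates the classes linearly, the regime used for the "separable"
training checks. The ablation condition uses amplitude 0.4 at 20:1
imbalance (train 2000/100, balanced 150/150 test) so that arm ordering is
informative rather than saturated. Generation is bitwise deterministic from
the `SyntheticSpec` seed.

What the generator does **not** emulate: anatomical structure, acquisition
artefacts, inter-device variation, label noise, or positives whose evidence
is texture rather than intensity. Passing tests therefore demonstrate the
correctness and directional behaviour of the pipeline, not clinical
performance; real benchmark numbers require real datasets and much larger
backbones and budgets.

## Problem sizes and numerical choices

Desk-scale protocol used by the test suite and the acceptance script:
32×32 single-channel images; separable runs with 120 images, 25 fine-tune
epochs at lr 0.1; the ablation trend with five seeds, three SSL epochs
(batch 16 pairs) and eight fine-tune epochs per arm at lr 0.05; five-fold
cross-validation at 105 train images, three epochs per fold. The ablation
uses `val_fraction=0.04` because a balanced 10 % validation split of a 20:1
dataset would consume the entire minority class.

Other numerical details: cross-entropy scores are clamped to
[1e-12, 1−1e-12] with a warning at the boundary; non-finite gradients abort
optimisation with a diagnostic rather than propagating; `round()` (banker's
rounding) fixes the validation size; k-fold assignments are fully
determined by (seed, k, record order).

## Known limitations

The engine is CPU-only and unsuited to real 224×224 training; for real data
one would swap in a deep residual backbone behind the same plug-in contract.
The trust score is reported for the positive class (the clinically critical
one); the negative-class analogue is computed but not part of the headline
report. The AUC surrogate can still destabilise at high learning rates
(lr ≥ 0.15 at desk scale diverges); constant learning rates only, no
schedules.
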