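# Methods

`semgrej` implements an open-set recognizer for wrist movements recorded
with a low-density (8-channel, 200 Hz) surface-EMG armband. The system has
three stages: time-domain feature-image encoding, a small CNN trained with
joint softmax + center loss, and an autoencoder novelty gate that rejects
movements outside the trained vocabulary. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Signal model and the synthetic generator

Real sEMG at a fixed electrode montage is, to first order, band-limited
zero-mean noise whose per-channel power tracks the activation of the
muscles under each electrode. The generator reproduces exactly that and no
more: for each repetition of a movement with per-channel gains
`a[ch]` it emits Gaussian noise filtered to 20–95 Hz (the energy band
representable at a 200 Hz rate), scaled so the per-channel standard
deviation is `base_amplitude * a[ch] + noise_sd`, under a trapezoidal
onset/offset envelope with 200 ms ramps. Repetitions last 5 s and are
separated by 3 s of baseline-noise rest; each movement is repeated 6 times
per session.

The default vocabulary is 6 active targets plus neutral. Target
activations are near-orthogonal (a dominant channel plus a weaker
secondary two channels over, mimicking crosstalk); neutral's gains are
≤ 2 % of the largest target gain. The 5 unrelated movements are convex
mixtures of two target activations plus a small seeded perturbation, with
the mixing weight solved by bisection so each lands at a prescribed cosine
similarity to its nearest target inside a configurable band (default
[0.5, 0.95]). The band's upper edge is the difficulty dial: pushing it up
makes unrelated movements more target-like and lowers downstream rejection
AUC. No quantitative similarity between real unrelated and target wrist
movements is available to anchor this band, so it is an explicit free
parameter, not a measured value.

What the generator deliberately omits: motor-unit physiology, force and
kinematics, electrode shift, inter-subject variability, non-stationary
fatigue effects, and power-line artifacts. Tests passing on this data
therefore demonstrate that the *pipeline machinery* is correct and that
the method behaves as designed when its core assumption (different
movements ⇒ different spatial power signatures) holds; they say nothing
about accuracy on real recordings.

## Preprocessing

Windows are 250 ms long with a 100 ms step (50×8 matrices at 200 Hz), cut
strictly inside trial boundaries; a trial of `n` samples yields
`floor((n − L)/S) + 1` windows. A window counts as muscle-active when its
mean rectified amplitude strictly exceeds `mu + 3*sigma`, both statistics
computed over the rectified neutral-state signal with the population
(1/N) standard deviation. Rectification matters: raw sEMG is zero-mean,
so an unrectified mean would collapse the threshold to ≈ 3σ regardless of
amplitude. The statistic compared to the threshold (mean rectified
amplitude over the whole window, strict `>` at the boundary) is a
deterministic choice among several defensible readings of "the amplitude
of a window signal".

Each active window is reduced to a 3×8 row — per-channel RMS, MAV, and
waveform length — and `T` consecutive rows are stacked into a 3×T×8
feature image (default `T = 53`). A 5 s repetition yields 48 windows, so
at the defaults each repetition produces exactly one image, padded by
repeating its final row (the pad count is recorded). The stack depth is
configurable; the padding rule preserves amplitude statistics without
inventing values.

One consequence of calibrating the activity gate on neutral data is that
neutral's own windows can never pass it, yet neutral is one of the seven
classes the classifier must label. The pipeline therefore exempts
neutral-labelled trials from the gate and encodes their windows directly;
their near-zero feature rows make the class trivially separable.

## Classifier

The CNN maps 3×T×8 images through three convolutions — 16×2 kernel,
stride (2,2), no padding; 8×3, stride (2,1), padding (2,1); 3×3, stride 1,
padding 1 — all leaky-rectified (slope 0.01), then a 1024-wide dense
layer, dropout 0.2 (training only), and a 512-wide dense layer whose
activation is the "deep feature"; a linear head produces the 7 class
logits. Stride/padding pairs are read as (rows over T, channel columns).
The convolution channel widths (32, 64, 64) and the 1024-wide fc layer
are reconstructions — only the 512-wide feature layer and the conv
kernels are fixed points of the design — and all are configurable.

Training minimises `L = L_softmax + λ·L_center` with
`L_center = (1/2N) Σ ‖x_i − c_{y_i}‖²` (λ defaults to 2.5e-4), by Adam
(lr 1e-4, batch 32, 200 epochs), with all randomness — init, shuffling,
dropout — derived from one seed. The center loss is implemented in its
standard non-negative form and differentiated exactly, so the feature
gradient carries the 1/N batch factor and passes central finite-difference
checks at 1e-5. Class centers start at zero and move once per batch by the
damped centroid rule `c_j ← c_j − α·Σ_{y_i=j}(c_j − x_i)/(1 + n_j)` with
`α = 0.5` (no principled value exists; any α in (0,1) converges to the
class mean on a frozen batch, which the tests verify). Centers update
after the weight step; the ordering is unobservable in the loss but fixed
for determinism. Feature planes are passed raw to the network — amplitude
is the discriminative signal here, and standardization would partially
discard it — with an optional per-plane z-scoring switch, off by default.

The networks are implemented in a compact NumPy layer stack with
hand-derived backprop (`semgrej.nn`). At this scale (thousands of
parameters per layer, dozens of training images) that is faster to audit
than a deep-learning framework and exactly reproducible from a single
integer seed; every layer's gradient is finite-difference tested.

## Rejection gate

A mirror autoencoder (512-256-128-64-128-256-512, leaky-rectified hidden
layers, linear output) is trained for 1000 epochs of Adam (lr 1e-4,
batch 32) on *target-class training features only*, minimising MSE; the
CNN is frozen throughout. The rejection score is `1 − ρ(x, AE(x))` with ρ
the Pearson correlation — a scale-free reconstruction error in [0, 2].
MSE trains the AE; the correlation form is used for scoring because it
normalises away feature magnitude, which varies strongly across classes.
Constant vectors (correlation undefined) score the maximal error 2 with a
warning rather than failing.

Thresholds come from the validation split at a preset recall factor
`r`: per class, `τ_c` is the `⌈r·n_c⌉`-th smallest validation error — the
smallest cutoff covering at least a fraction r of that class. A pooled
global threshold is recorded too and can be enabled by a flag; per-class
is the default because class-conditional error scales differ. A test
sample predicted as class c is accepted iff its error ≤ τ_c; the boundary
accepts, which makes the recall guarantee on the calibration set exact
rather than approximate. Two exact monotonicity properties follow and are
tested: τ_c is non-decreasing in r, so target acceptance never falls and
unrelated rejection never rises as r grows.

The rejection model records a fingerprint of the CNN checkpoint it was
calibrated against and refuses to run against a different CNN unless
forced.

## Evaluation

Binary rates follow the standard definitions (accuracy, precision,
recall/TPR, FPR, F-score); zero-denominator rates are reported as NaN
("undefined"), never as silent zeros, and macro averages skip undefined
entries — the text report states how many classes had a defined F-score,
since a macro-F over few defined classes can read optimistically. The
open-set confusion matrix has one row per target class plus one pooled
"unrelated" row, and one column per class plus "reject"; both a macro
(per-class mean of diagonal rates) and a per-sample target accuracy are
reported because "mean accuracy" is ambiguous between the two. The ROC
treats "target sample accepted" as the positive event, sweeps all distinct
error thresholds with ties grouped (scikit-learn's curve machinery), and
integrates by the trapezoidal rule; tests pin the result to brute-force
pairwise concordance at 1e-12.

## Data split and problem sizes

Target images are class-stratified 60/20/20 into train/validation/test
with largest-remainder rounding (partitions sum exactly); every unrelated
image goes to test only, since rejection must work on movements the model
has never seen. Splitting pools all data by default; a per-subject flag
stratifies within subjects instead.

At the default protocol (6 repetitions, one image per repetition) a run
holds 42 target and 30 unrelated images: 28 train, 7 validation, 37 test.
One consequence worth stating plainly: with a single validation image per
class, every per-class threshold is that one sample's error, and a fresh
test error falls below it only about half the time, so *open-set* target
accuracy at the default protocol hovers near 0.5 regardless of model
quality. This is a small-sample property of the calibration rule, not of
the networks — the threshold-free measures (closed-set accuracy, AUC) are
near 1.0 at the same settings, and open-set accuracy recovers as soon as
validation classes hold a handful of images (see `examples/02`, 25
repetitions: open-set accuracy 0.914, rejection 0.824, AUC 0.969). The
reduced configurations used in tests and examples (shorter repetitions,
T = 26, fewer epochs) are chosen so the full pipeline runs in seconds
while exercising every stage.

## Known limitations

- The generator's movements are separable by per-channel amplitude alone;
  real gestures overlap far more, so absolute synthetic metrics are upper
  bounds of a sort, and only directional comparisons (center loss vs
  softmax-only, recall sweeps, similarity-band effects) transfer.
- Per-class thresholds need several validation samples per class to be
  meaningful (see above).
- Single-subject, single-session reasoning: no electrode-shift or
  cross-subject modelling.
- The stack depth `T = 53` exceeds the 48 windows a 5 s repetition
  provides, so default-protocol images always carry 5 padded rows.
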