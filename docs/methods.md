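# Methods

`mieeg` implements a five-stage decoding pipeline for two-class (left vs right
hand) motor-imagery EEG: multiscale-PCA denoising, continuous-wavelet-transform
scalogram images, a focal-loss-trained convolutional feature extractor, an
arithmetic-optimization metaheuristic for hyperparameter tuning, and an ID3
decision tree as the final classifier, reported through standard
confusion-matrix metrics.  This note records the models, the parameters that
matter, the numerical choices, and the known limitations.

## Synthetic MI-EEG generator

The generator emulates a 3-electrode (C3, Cz, C4) cued motor-imagery session:
by default 128 Hz sampling, 9 s trials, balanced left/right labels.  Each
trial contains a mu (10 Hz) and a beta (20 Hz) oscillation generated as
*common sources* — one random phase per trial, mixed into the channels with
fixed gains (1.0, 0.7, 1.0) — so that channels are linearly correlated, the
statistical structure that volume conduction gives real scalp EEG and that
cross-channel PCA denoising relies on.  Event-related desynchronization (ERD)
is modelled as a multiplicative amplitude attenuation of depth `erd_depth`
(default 0.5) applied to the channel contralateral to the imagined hand
(C4 for left, C3 for right) inside the imagery window (default 3–7 s), with
0.25 s raised-cosine ramps.  Trial-to-trial amplitude varies uniformly by
±20%.  Additive noise is 1/f^β (β = 1) noise, independent per channel,
scaled so the full-band SNR inside the imagery window equals `snr_db`
(default 5 dB, a realistic band-limited scalp-EEG figure).  The noiseless
template is retained on the returned trial set as a denoising oracle.

What the generator does *not* emulate: ocular/muscular artifacts,
non-stationary background spectra, inter-subject variability, electrode
drift, or more than two classes.  Tests passing on this generator show the
pipeline recovers a contralateral band-power contrast embedded in 1/f noise;
they do not certify performance on real recordings.

## MSPCA denoising

Each channel of a trial is decomposed with a multilevel DWT (default `db4`,
4 levels, symmetric extension).  Per subband, the coefficients of all
channels form a samples × channels matrix; columns are mean-centered, PCA is
fitted via the sample covariance (n−1 denominator), and the coefficients are
re-projected through the leading principal components before inverse
transformation.  Component retention defaults to the Kaiser rule (keep
eigenvalues strictly above their mean, floor of one); `fixed:A` and
`variance:p` rules are available.  Retaining all components reproduces the
input to 1e−8 (full-retention identity), which the tests exploit.

Two measured properties worth knowing:

* **Band-edge leakage.**  Daubechies-4 filters are not sharp: a 10 Hz tone at
  128 Hz puts only ~74–80% of its energy into the nominal 8–16 Hz subband.
  The energy-bookkeeping test uses `db8`, which concentrates ≥80%.  The
  default stays `db4` (the conventional EEG choice); the wavelet is
  configurable.
* **Signal suppression at high SNR.**  With 3 channels the Kaiser rule
  typically retains a single component.  When the discriminative signal is a
  deep attenuation of *one* channel (ERD ≥ ~0.9) and noise is low, that
  deviation is mostly orthogonal to the first principal component and the
  reconstruction suppresses it — denoising then removes class information.
  At the default conditions (ERD 0.6, 5 dB) the contrast survives and
  denoising helps; in near-noiseless regimes denoising should be disabled or
  the retention rule loosened.

The spectral normalization ambiguity (mean-centering vs z-scoring) is
resolved as centering only; z-scoring is exposed as a flag.

## Scalogram images

Trials are mapped to H × W × C images by per-channel CWT with a complex
Morlet wavelet (ω₀ = 6), scale s = fs·(ω₀/2π)/f, on a log-spaced grid of 64
frequencies covering 4–40 Hz (mu + beta), coefficient magnitudes bilinearly
resampled to the target size (default 224 × 224; the desk-scale experiments
use 32 × 32) and min–max normalized to [0, 1] per channel.  C3/Cz/C4 map to
the three image channels.  Per-channel normalization removes absolute
amplitude differences *between* channels; the class signal survives as the
within-channel temporal contrast between the imagery window and the rest of
the trial.  A constant channel (zero dynamic range) yields an all-zero plane
with a warning rather than NaNs.

## Feature network

A residual convolutional backbone with a feature-pyramid network (FPN) and
two small heads, implemented in numpy with hand-written backprop (im2col
convolutions; gradients verified against central differences to ~1e−10
absolute).  The default `tiny` backbone has a stem plus three basic residual
blocks (16/32/64 channels, stride-2 stages, batch norm, leaky-ReLU slope
0.01); depths 18/34 (basic) and 50/101 (bottleneck) are buildable with the
standard stage layouts.  The FPN merges the top three stages with lateral
1×1 convolutions and nearest-neighbour upsampling; a 3×3 convolution smooths
the finest merge, which is globally average-pooled and fed to a feature head
(default width 256 — the vector handed to the decision tree) and a 1-logit
classification head.  Detection machinery (anchors, box regression) is
deliberately absent: the architecture is used purely for classification and
feature extraction.

Training minimizes mean binary focal loss, FL(p_t) = −α_t(1−p_t)^γ log p_t
(natural log, probabilities clipped at 1e−7; defaults α = 0.25, γ = 2), with
momentum SGD (lr 0.05, momentum 0.9, batch 16).  Stability measures, all
deterministic: global gradient-norm clipping at 5; if an epoch produces a
non-finite loss the epoch is rolled back and the step size halved; after the
epoch loop the classification bias is recentered at the midpoint of the
per-class training-logit means (on hard tasks the raw bias wanders under
minibatch noise by more than the logit separation, so threshold-at-zero
accuracy would otherwise be uninformative even when the learned direction is
good).  α = 0.25 follows the detection literature; for balanced data α = 0.5
is the neutral choice and both are inside the tuner's search box.

## Arithmetic optimization algorithm

Population metaheuristic over a box, with the accelerated-function gate
MOA(t) = min + t(max−min)/Mt (defaults 0.2–0.9) choosing per dimension
between exploration and exploitation when compared with a uniform draw, and
the step magnitude MOP(t) = 1 − t^(1/α)/Mt^(1/α) (α = 5).  Exploration uses
division/multiplication around the best solution, exploitation
subtraction/addition, each scaled by ((UB−LB)·μ + LB) with μ = 0.5; positions
are clipped to the box and replacement is greedy, making the best-so-far
trace monotone.  ε = 2.2e−16 guards the division.

A structural property to be aware of: on a symmetric box [−b, b] the term
((UB−LB)·μ + LB) is exactly zero for μ = 0.5, so exploration proposes the
origin and exploitation proposes the incumbent — the search degenerates to
initialization plus origin-probing.  This is faithful to the published
update rules; practical search spaces (learning rates, epochs — all
nonnegative) are asymmetric and unaffected.  Hyperparameter tuning minimizes
1 − validation accuracy over learning rate (log10 scale), focal γ, focal α
and epoch count, with failures penalized at fitness 1 and a full evaluation
log retained.

## ID3 classification

Continuous CNN features are bridged to nominal attributes by per-feature
equal-frequency binning (default 10 bins; training quantiles, open outer
bins, constant features collapse to one bin with a warning).  The tree
splits on maximal information gain (base-2 entropy), ties toward the lowest
attribute index, majority labels with ties toward the lowest class, no
attribute reuse along a path, no pruning; `max_depth` and `min_samples` are
the regularizers.  Zero-gain splits are permitted — XOR-structured data
requires them.  Unseen attribute values at prediction fall back to the
node's majority label.

## Evaluation protocol

Confusion matrices are 2 × 2 with rows = true (left, right); metrics take
left as the positive class; kappa is standard Cohen's kappa from marginal
products.  Display values are percentages rounded half-up to two decimals;
raw fractions are retained.  An experiment runs n independent iterations
(default 5), each with freshly generated trials and a fresh 50/50 stratified
train/test split under a counter-derived seed; the Average row is the
arithmetic mean of per-iteration metrics.  When tuning is enabled it runs
once, in the first iteration, and the tuned values are reused — re-tuning
per iteration would multiply cost without changing the protocol's meaning.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at
60 trials/class, 32 × 32 scalograms (32 frequencies), the `tiny` backbone and
30 epochs — sizes at which the whole suite completes in minutes on one CPU
core while leaving the measured contrasts far from threshold (held-out
accuracy 0.95–1.0 at ERD 0.6 vs ~0.5 for the ERD-0 control).

## Known limitations

* No GPU path and no ImageNet-style pretraining; the deep backbones (50/101)
  are buildable and correct but impractical to train in numpy.
* EDF support: reading goes through `mne`; writing uses a minimal built-in
  EDF+C writer (16-bit, one record per trial, annotation channel for
  labels).  GDF is not supported.
* The ID3 stage ignores feature interactions beyond axis-aligned splits on
  binned values; with few training trials, deep trees overfit — hence the
  shallow defaults.
* Two classes only; artifact simulation and multi-class extensions are out
  of scope.
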