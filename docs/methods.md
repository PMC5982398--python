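# Methods

This note documents the models, numerical conventions and design choices in
emofusion, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic experiments do and do not show.

## Labels

Self-assessed valence and arousal (1–9) are thresholded at (5, 5): "high"
means strictly greater than 5, so a rating exactly at the threshold maps to
"low".  This tie rule keeps the 2-class labels exact marginals of the
4-class quadrants (HV = HAHV ∪ LAHV, HA = HAHV ∪ HALV), which the tests
assert on the exhaustive integer grid.  Seeded k-means (k-means++-style
initialization, Lloyd's iterations to convergence) is provided purely as a
diagnostic that the rating cloud's centroid mean sits near (5, 5); labeling
never depends on the clustering, so labels are deterministic.  k-means is
implemented in-package because the contract requires exact reproducibility
from a seeded initialization; an independent library implementation serves
as a cross-check in the tests.

## Wavelet spectrograms

Each electrode trace is convolved with complex Morlet wavelets (Gaussian
envelope, truncated at ±3.5 σ) at 42 centre frequencies linearly spaced
over 4.0–45 Hz — the band-pass of the DEAP preprocessed release; 42 bins
over a 41 Hz span is ≈1 Hz resolution, which is why linear spacing is the
default.  The cycle count rises linearly from 3 at 4 Hz to 8 at 45 Hz,
the usual EEG compromise between temporal resolution at low frequencies and
spectral resolution at high ones.  Each wavelet is scaled by 2/Σ(envelope)
so a unit sinusoid at the centre frequency yields magnitude ≈1.

The magnitude is reduced to exactly 200 time frames by partitioning the
samples into 200 contiguous near-equal bins (38–39 samples each for a 60 s
trial) and averaging within bins — averaging rather than subsampling so
transients are not aliased away.  The output is therefore always a 42 × 200
non-negative image, independent of trial length.  Convolution runs in the
frequency domain with one shared FFT per channel; dataset-scale transforms
use single precision (float32 roundoff, far below any physiological
difference; images are z-scored afterwards anyway), while the single-channel
API keeps double precision and is tested against direct `np.convolve` to
1e-10.

Before entering the network every spectrogram is z-scored over all its
cells (constant images map to zeros).  A dB-power output scale is available
but not default: the per-image normalization makes the overall scale choice
immaterial to training.

## GSR short-time zero-crossing rate

Skin conductance is strictly positive, so crossings are counted on a
detrended trace.  The default detrend subtracts a moving average whose
width equals one analysis window (1 s): this isolates the fast phasic
fluctuations from the slowly drifting tonic level — the conventional
tonic/phasic decomposition for electrodermal activity — and keeps the
crossing rate approximately linear in the phasic event rate.  Plain mean
removal is available but saturates once responses overlap, because the
tonic level itself wanders through the global mean; first differencing is
also provided.

The STZCR of a window is the weighted count of sign changes between
adjacent samples inside the window, divided by the window length N
(values in [0, (N−1)/N] for the rectangular window).  `sign(0) = 0`, so a
transition through an exact zero contributes half a crossing on each flank;
perturbing exact zeros by ±1e-12 changes only those samples' crossings.
Windows default to 1 s, non-overlapping — 60 features per 60 s trial.

The gate keeps windows whose rate strictly exceeds the trial mean
T = mean(STZCR) and zeroes the rest.  Supra-threshold values pass through
unchanged (preserving amplitude information); an alternative mode replaces
them with the vector maximum.  Strictness is enforced up to a 1e-12
relative tolerance on the mean, so an all-equal vector gates to all zeros
despite floating-point rounding.

At the fusion layer the model receives the gated vector multiplied by the
window length — per-window crossing *counts* rather than rates.  This is a
pure units choice: it makes the GSR inputs O(1), commensurate with the
z-scored spectrogram activations, so the first fully connected layer sees
both modalities at comparable scale.

## The fusion network

The reference architecture is four convolution layers with 3 × 2 filters
(3 along frequency, 2 along time), stride 1 along frequency and 2 along
time, no padding; batch normalization then ReLU after every convolution
except the last; a 2 × 2 max pool; flattening; concatenation of the trial's
GSR feature vector (replicated across the 32 electrode rows of a batch);
seven fully connected ReLU layers; softmax head with 2 or 4 units.  The
taller filter side spans frequency because the image's vertical axis
carries the spectral structure; striding along time is what keeps all four
layers and the pool shape-valid on 42 × 200 (frequency 42→40→38→36→34,
time 200→100→50→25→12, pool → 17 × 6; striding 2 along frequency would
collapse that axis before the fourth layer).

Channel counts default to (32, 64, 128, 128) and FC widths to
(1024, 512, 256, 128, 64, 32, n_classes); both are configuration, and a
`reduced` constructor with the same topology but narrow layers
((4, 8, 8, 8) filters, (64, 32, 24, 16, 12, 8) hidden widths) is used for
the synthetic experiments and examples, where the planted structure does not
need large capacity and single-CPU runtimes matter.  Layer-count validation
is strict only for the reference architecture; reduced depths (e.g. the
2-conv + 2-FC model used for gradient checking) are first-class.

Batch normalization follows the standard formulation: batch statistics and
an exponential running average (momentum 0.9, ε = 1e-5) in training mode;
running statistics with the learned γ, β at inference.  Pooling is max
pooling.  No dropout or L2 regularization is applied — batch normalization
is the only regularizer, and early stopping the only capacity control.

Everything, including the backward pass (im2col convolution gradients,
batch-norm backward, pool argmax routing, softmax + cross-entropy), is
plain numpy.  The test suite checks analytic gradients against central
finite differences (h = 1e-5) with tolerance
|∇ₐ − ∇ₙ| ≤ 1e-4·max(|∇ₐ|, |∇ₙ|) + 1e-7; the absolute floor exists because
conv biases that feed a batch-norm layer have an exactly-zero true gradient
(the mean subtraction cancels them), where a pure relative criterion is
ill-defined.

## Training and evaluation

The loss is L(p, q) = −Σ p ln q with q clamped at 1e-12; the optimizer is
plain SGD, default learning rate 1e-3 (the synthetic experiments use 3e-2,
which plain SGD needs on these narrow models).  One batch is one trial: 32
electrode spectrograms sharing the trial's GSR vector and label.
Validation loss (mean per-row cross-entropy over the validation trials) is
measured every `eval_interval` iterations; the parameter snapshot at the
minimum is returned, and training halts once `early_stop_patience`
iterations pass without improvement.  Two runs with the same seed are
identical to the last bit of the loss curve.

Hold-out evaluation uses a per-class proportional (stratified) 9:1:1
train/validation/test split of trials.  Leave-one-video-out trains one
model per stimulus on the other videos (carving a stratified tenth of the
training trials for early stopping) and reports the mean fold accuracy;
a per-(video, subject) variant exists.  Every split is checked
programmatically for (subject, video) overlap between train and test.
Trial-level predictions average the 32 electrode probability rows and take
the argmax (ties to the lowest class index); electrode-level accuracy is
reported alongside.

## Synthetic data

The generator emulates the DEAP preprocessed layout: per subject, 40 trials
× 40 channels × 7680 samples at 128 Hz, 32 EEG rows in Geneva order, GSR at
row 36, plus (valence, arousal, dominance, liking) ratings.  Per-trial
random streams are keyed by (seed, subject, video), so datasets are bitwise
reproducible and subjects can be generated independently.

Each trial carries a latent quadrant class.  Classes are assigned per
subject by a seeded shuffle that hits the configured class proportions
exactly (a balanced design, so class priors do not drift with sample size).
Latent valence/arousal are drawn uniformly from [6, 8.5] ("high") or
[1.5, 4] ("low") — margins around the (5, 5) threshold so that noiseless
ratings recover the planted class exactly; observed ratings add Gaussian
noise (default σ = 0.5), clipped to [1, 9].

EEG rows are 1/f background (RMS 10 µV) plus band-limited alpha (8–13 Hz,
RMS 4 µV) and beta (14–30 Hz, RMS 5 µV) oscillations.  Latent affect x
enters amplitudes as factors (1 + effect)^((x−5)/2).  Arousal scales beta
power scalp-wide at half that log-depth, with the frontal channels
AF3/AF4/F3/F4 at full depth — arousal-linked beta changes are widespread
with frontal prominence, and a generator confining them to four electrodes
would make trial-level aggregation (28 uninformative rows outvoting 4
informative ones) insensitive to any EEG effect.  Valence scales
right-frontal (AF4/F4) alpha, producing the classic frontal alpha
asymmetry.  The GSR row is a tonic level (4 a.u.) with slow drift plus
Poisson phasic responses (rise 0.7 s, decay 3 s, amplitude ≈0.4 a.u.) whose
rate is 0.1 Hz scaled by (1 + gsr_effect)^((arousal−5)/2).  Conventional
depths used throughout: 0 (null), 0.5 (moderate), 2.0 (large).

What the generator does **not** emulate: subject-specific rating biases,
volume conduction and channel correlation structure, artifacts (the DEAP
release is already cleaned), non-stationary band power, or DEAP's empirical
rating distribution.  Passing tests therefore demonstrate that the pipeline
recovers structure of this planted form — band-power and phasic-rate
modulations — not that it attains any particular accuracy on real DEAP
data, whose effect sizes are unknown and certainly smaller.

## Experiment sizes in the validation protocol

The acceptance tests and `scripts/acceptance.py` run: geometry on a single
60 s channel; bookkeeping on the full 32 × 40 layout (1280 trials, 40 960
spectrograms, streamed one subject at a time); STZCR oracles on 100 random
traces; gradient checks on a 2-conv + 2-FC model with ~80 sampled
parameters; early stopping on 60 trials at moderate effect (1000-iteration
cap); and discrimination on 200 trials (5 subjects × 40 videos) with the
reduced model, learning rate 3e-2, 1200-iteration cap at large effect and a
600-iteration cap for the null arm — the null needs no convergence, only a
fair test pass.  These sizes keep the whole protocol within tens of minutes
on one CPU while leaving every check at full signal fidelity (60 s, 128 Hz,
42 × 200 images).

## Known limitations

* Plain SGD on the full-width reference architecture converges slowly; the
  synthetic experiments use the reduced widths.  The optimizer is kept
  deliberately minimal (no momentum/Adam) to match the stated update rule.
* Batch-norm inference uses running averages accumulated with momentum 0.9;
  very short runs therefore evaluate with statistics still close to the
  first batches.
* The trial-level aggregation (mean of electrode probabilities) lets a
  confidently wrong majority of electrode rows override a correct minority;
  with few informative electrodes this caps trial accuracy at roughly the
  accuracy of the shared (GSR) information.  This is a property of the
  aggregation rule, preserved by design.
* `derive_threshold` is diagnostic; per-subject or per-split threshold
  adaptation is deliberately out of scope.
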