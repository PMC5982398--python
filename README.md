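# emofusion

Multimodal emotion classification from physiological signals: a complete,
tested re-implementation of an EEG + GSR fusion convolutional-network
pipeline, exercised end to end on synthetic DEAP-shaped data.

## The problem

Affective computing systems try to recognize a person's emotional state.
Facial expressions are easy to fake; central- and peripheral-nervous-system
signals are not.  The DEAP protocol records 32-channel EEG plus peripheral
channels (including galvanic skin response, GSR) while 32 subjects watch 40
one-minute music videos, and collects self-assessed **valence** and
**arousal** ratings (1–9) per trial.  Under the circumplex model of affect
the (valence, arousal) plane splits at (5, 5) into four emotion quadrants —
HAHV, HALV, LALV, LAHV — which serve as classification targets, alongside
the 2-class marginals [HV, LV] and [HA, LA].

This package implements the full pipeline:

1. **Labels** — k-means on the rating cloud justifies the (5, 5) threshold;
   labels are one-hot vectors under the 2- or 4-class scheme
   (high ⇔ strictly greater than 5).
2. **EEG features** — each electrode's 60 s trace becomes a 42 × 200
   time-frequency image: a complex-Morlet continuous wavelet transform at 42
   linearly spaced centre frequencies over 4.0–45 Hz, magnitude bin-averaged
   to 200 frames, then z-scored per image.
3. **GSR features** — the short-time zero-crossing rate (STZCR) of the
   detrended conductance trace,

   `STZCR[m] = (1/N) Σₙ |sign(s(n)) − sign(s(n−1))|/2 · w(n)`,

   over 1 s windows, gated at the trial mean `T = Σ STZCR / N_windows`
   (windows below T are zeroed).
4. **Fusion CNN** — four convolution layers with non-square 3 × 2 filters
   (3 along frequency, 2 along time), stride (1, 2), no padding, batch
   normalization + ReLU after every convolution except the last, a 2 × 2 max
   pool, then flattening, concatenation with the trial's GSR feature vector,
   and seven fully connected layers ending in a softmax over 2 or 4 classes.
   On a 42 × 200 input the conv stack maps 42×200 → 40×100 → 38×50 → 36×25 →
   34×12 → (pool) 17×6.
5. **Training / evaluation** — softmax cross-entropy minimized by plain SGD
   (`W ← W − γ ∂L/∂W`), one trial (32 electrode spectrograms) per batch,
   early stopping at the validation-loss minimum; evaluated by stratified
   9:1:1 hold-out and by leave-one-video-out cross-validation, with
   trial-level predictions obtained by averaging the 32 electrode
   probability rows.

The network — convolution, batch norm, pooling, dense layers and the entire
backward pass — is written directly in numpy, and its gradients are verified
against central finite differences in the test suite.

The real DEAP dataset is access-controlled, so the package ships a
first-class **synthetic generator** that reproduces the DEAP layout
(40 trials × 40 channels × 60 s at 128 Hz per subject) and plants a latent
emotion quadrant per trial: arousal modulates scalp-wide beta power (frontal
channels strongest) and the phasic GSR response rate; valence modulates
frontal alpha asymmetry; ratings are noisy copies of the latent affect.
Effect sizes are configurable down to zero (null data).

## Worked example

`examples/04_train_fusion_model.py` simulates 40 short trials with a strong
planted arousal effect, trains a reduced-width fusion network and evaluates
a stratified hold-out split:

```
40 trials; each = 32 z-scored 42x200 spectrograms + 8 gated STZCR features
stopped at iteration 300; best validation loss at iteration 275
  iter  225: train loss 0.031  val loss 0.085
  iter  250: train loss 0.027  val loss 0.093
  iter  275: train loss 0.006  val loss 0.078
  iter  300: train loss 0.030  val loss 0.107
hold-out trial accuracy: 1.000 on 4 trials (electrode-level 0.984)
```

The accuracy is trial-level: a test trial is correct when the argmax of its
32 averaged electrode probability rows matches the true class.  The other
examples cover simulation + labeling, the wavelet transform, the STZCR
features, and leave-one-video-out evaluation.

A command-line interface chains the stages on disk with manifests and a
single global seed:

```bash
emofusion --config run.yaml --out run/ simulate
emofusion --config run.yaml --out run/ preprocess
emofusion --config run.yaml --out run/ label
emofusion --config run.yaml --out run/ train
emofusion --config run.yaml --out run/ evaluate
```

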