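# Methods

`emgpr` implements an offline pattern-recognition pipeline for myoelectric
prosthesis control: multi-channel surface-EMG recordings are windowed,
reduced to classic time-domain features, and classified into individual and
simultaneous hand/wrist movements by one of five model/trainer combinations.
This note records the models, the numerical choices, what the synthetic
generator does and does not emulate, and the known limitations.

## Signal treatment

A recording session holds a `[time x channels x movements]` tensor with the
repetitions of each movement concatenated along time (default protocol:
8 bipolar channels, 2 kHz, 3 repetitions of 3 s per movement). Each
repetition is processed independently:

1. **Trim.** The first and last `trim_fraction` (default 15 %) of each
   repetition are removed, keeping only the isotonic part of the
   contraction. Boundaries are floored: a 1000-sample repetition keeps
   samples 150–849.
2. **Window.** Fixed windows of 200 ms slide in 50 ms increments over the
   trimmed repetition; windows use half-open sample intervals
   `[start, start + w)` and never span repetition boundaries. A contiguous
   segment of `L` samples yields `floor((L − w)/i) + 1` windows. At the
   default protocol this gives 39 windows per repetition and **117 windows
   per movement**. (Descriptions of this protocol sometimes quote 121
   windows per movement; that number is not reproducible from the stated
   arithmetic — per-repetition trimming gives 117, trimming the
   concatenated 9 s recording gives 123 — so the window count here is
   always derived from the formula, never hard-coded.)
3. **Features.** Per window and channel: mean absolute value (MAV),
   waveform length (WL), zero crossings (ZC) and slope sign changes (SSC).
   ZC counts sign changes between consecutive samples whose amplitude step
   exceeds a deadband threshold; SSC counts interior samples whose slope
   changes sign with both adjacent steps above the threshold. Both
   thresholds default to 0 and are configurable (hardware front-ends often
   use small deadbands). Eight channels give the standard 32-dimensional
   feature vector.
4. **Normalization.** Either z-score (column mean 0, sample SD 1) or
   "midrange 0, range 2" (training column min → −1, max → +1). Parameters
   are fitted on the **training partition only** and applied unchanged to
   the test partition; fitting them on all data would leak test-set
   statistics into training. Constant columns get scale 1 and a logged
   warning.

## Movement coding

With k degrees of freedom (DoF) — default three: hand open/close,
flexion/extension, pronation/supination, agonist listed first — a movement
label is a state vector in {−1, 0, +1}^k, giving 3^k = 27 classes: 6
individual movements, 20 simultaneous combinations and rest. The canonical
class index is the mixed-radix number with digit `state + 1`, first DoF most
significant.

Three target encodings are used:

* **single** — one unit per label (27 outputs), one-hot, decoded by argmax
  with lowest-index tie-break;
* **multiple** — one unit per individual movement (6 outputs); a unit is
  active when its output exceeds 0.5; if both units of a DoF fire, the
  larger output wins (ties to the agonist); no active unit decodes to rest.
  A prediction is counted correct only when the full decoded state vector
  matches the truth — no partial credit;
* **per-DoF** — k blocks of four units (agonist, antagonist, other
  movement, rest), used by per-DoF ensembles of linear models. When
  training, a window whose DoF is active is labelled agonist/antagonist for
  that DoF regardless of co-active DoF; windows active only elsewhere train
  the "other" class. Decoding maps "other" and "rest" to an inactive DoF,
  so the per-DoF scheme cannot represent co-activation it has mapped to
  "other" — an inherent lossiness of the scheme, visible in its round-trip
  behaviour.

## Classifiers

* **LDA** — classic pooled-covariance linear discriminant with empirical
  priors. The pooled covariance is ridge-regularized by
  `1e-8 · trace(S)/p` on the diagonal to survive degenerate fixtures. A
  single LDA handles the 27-class single-output problem; the multiple
  output type uses the per-DoF ensemble (one 4-class LDA per DoF), since a
  discriminant cannot emit unit combinations.
* **GLM** — a linear layer with bias and softmax (one-hot targets) or
  logistic (binary targets) outputs, trained either by **IRLS** — damped
  Newton/Fisher scoring with the exact multinomial or Bernoulli Hessian and
  a step-halving safeguard, so the training cross-entropy is non-increasing
  by construction — or by **scaled conjugate gradient**. Both objectives
  are convex; with a small weight decay the optimum is unique, which the
  tests use as a cross-trainer oracle (agreement within 1e-4).
* **MLP** — feed-forward network with one or two logistic hidden layers
  (default one layer of 32 units) and softmax or logistic outputs, trained
  full-batch by plain **gradient descent** (backpropagation, learning rate
  0.1 scaled by 1/n, momentum 0) or by **scaled conjugate gradient**. The
  error function is the cross-entropy matched to the output function, so
  the output delta is `y − t` in both cases. Weight initialization is
  Gaussian scaled by `1/sqrt(fan_in + 1)` and fully reproducible from the
  seed.
* **SCG** — Møller's scaled conjugate gradient: conjugate directions with a
  Levenberg–Marquardt-style scale λ adapted from the comparison parameter
  (actual vs predicted error decrease), curvature estimated by a one-sided
  finite difference of the gradient; no line search. Constants follow the
  published algorithm (σ₀ = 1e-4, initial λ = 1e-6) and are configurable.
  Accepted steps never increase the error.

All iterative trainers stop at `max_iterations` (default 200) or when both
the error decrease and the parameter step fall below their tolerances.
Gradient-descent hyperparameters are declared defaults, not derived values;
the 1/n scaling of the summed-cross-entropy gradient makes the default
learning rate roughly sample-size independent.

## Evaluation protocol

Each evaluation repetition draws a fresh stratified split — a fixed number
of training and disjoint test windows per movement (defaults 72/49;
protocols with fewer than 121 windows per movement use a correspondingly
smaller test count, e.g. 72/45 at the default synthetic protocol) —
fits normalization on the training partition, trains the model, and records
accuracy = correct / total classifications. Mean accuracy (Acc) and sample
SD are taken over repetitions (default 100). Method comparisons share one
split sequence (common random numbers) and pair accuracies by repetition
index, so paired differences reflect the method rather than the split.

The **Wilcoxon signed-rank test** (two-sided, α = 0.05) compares paired
accuracy vectors. Zero differences are discarded; tied absolute differences
receive average ranks. For ≤ 25 non-zero pairs the p-value comes from the
exact null distribution of W⁺ (sign-assignment enumeration computed by
convolution; average ranks are half-integers, so doubled ranks make the
distribution an exact integer polynomial). Larger samples use the normal
approximation with tie correction and continuity correction. An all-zero
difference vector returns p = 1 with a no-evidence flag.

The **hidden-unit sweep** trains `nets_per_hu` networks (default 10) per
candidate hidden-layer size, each on its own split (shared across sizes),
and selects the smallest size whose accuracies are not significantly worse
than those of the best-scoring size. The sweep's stopping phrase "smallest
number of units beyond which no significant improvement is available" is
ambiguous between successive and best-reference comparisons; the
best-reference reading is implemented because the successive reading can
stop at spurious local plateaus.

## Synthetic EMG generator

For time-domain feature classification the relevant structure of surface
EMG is its per-channel envelope, not its fine waveform. The generator
therefore models each channel of each movement as band-limited Gaussian
noise (white noise through a zero-phase 4th-order Butterworth band-pass,
default 20–450 Hz, renormalized to unit variance) scaled by

    amplitude = baseline · sqrt(1 + activation · snr)

so `snr` is the excess power of a fully active channel over baseline, and
`snr = 0` makes all 27 movements statistically identical. Class structure
comes from a 6 × 8 activation matrix in which each individual movement
dominates 2–3 electrodes with partial overlap and agonist/antagonist pairs
differ in support; simultaneous movements combine their constituents' rows
by elementwise `max` (co-contraction saturates; `sum`, clipped at 1, is
available).

What the generator does **not** emulate: motor-unit firing statistics,
signal nonstationarity within a contraction, electrode shift, sweat,
fatigue, crosstalk correlation between channels, and between-subject
variability. Passing tests therefore demonstrate that the pipeline's
machinery (features → training → decoding → statistics) behaves correctly
and that the optimizer comparison holds on well-posed separable problems;
they do not predict absolute accuracies on clinical recordings.

### Window-split optimism

With only 3 repetitions per movement, overlapping windows drawn from the
same repetition share realization-specific noise features. Random
window-level splits therefore let a classifier partially memorize
realizations: at `snr = 0`, where movements are statistically identical,
the within-session protocol still scores well above 1/27. This is a
property of the protocol, not a bug — the same optimism affects real
recordings evaluated with window-level splits. Consequently the
chance-level check trains on one `snr = 0` session and classifies a freshly
generated one (accuracy is then exactly chance by independence), while the
SNR-monotonicity and high-SNR checks retain the standard within-session
protocol.

## Problem sizes used in tests and the acceptance script

The test suite runs the pipeline on scaled-down sessions (1 kHz, 1.5 s
repetitions → 54 windows/movement, 36/18 splits) chosen so the suite stays
fast while preserving the signal structure; the acceptance script uses the
full default protocol (2 kHz, 3 × 3 s → 117 windows/movement, 72/45
splits), 20 seeds for the optimizer comparison and 5 repetitions for the
method table.

## Known limitations

* The per-DoF "other" class conflates all foreign movements; richer
  schemes (per-DoF 3-state classifiers with explicit co-activation
  handling) are out of scope.
* IRLS builds the exact dense multinomial Hessian
  (`(p+1)·K` square); fine at 32 features × 27 classes, but quadratic
  memory in both.
* Only offline evaluation is provided: no proportional control, no online
  adaptation, no electrode-robustness simulation.
* Training-time figures are wall-clock and hardware-dependent; they are
  reported for orientation and never asserted.
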