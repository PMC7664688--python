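# Methods

## Scope and data model

The package implements a subject-wise EEG classification study over question
trials: a subject reads a scenario for 30 s while 21 channels of the extended
10–20 montage (FP1…O2) are recorded at 500 Hz, then answers yes/no.  Two
binary tasks are evaluated per subject: *intent* (yes vs. no answers within
insider-threat questions) and *scenario type* (insider-threat vs. everyday-
conflict questions).  No recordings of this kind are publicly available, so
the study is driven end-to-end by a synthetic generator with known ground
truth; all statistical guarantees quoted below are therefore statements about
the pipeline's behavior on data with controlled structure, not about real
scalp EEG.

## Synthetic EEG generator

Each channel of a question trial is a sum of

* 1/f background noise (spectral exponent 1, 6 µV RMS),
* band-limited Gaussian oscillations in theta (4–8 Hz, 2.5 µV), alpha
  (8–13 Hz, 4 µV) and beta (13–25 Hz, 1.5 µV), with per-subject log-amplitude
  offsets drawn N(0, 0.2),
* a flat broadband component (1.5 µV) carrying the entropy-family features,

with half of each component's variance shared across channels so that scalp-
realistic inter-channel correlation (~0.5) exists for the bad-channel
detector.  Class effects act multiplicatively on band amplitudes:

* `intent_effect` shifts log(beta power / alpha power) by its value for
  yes-answers within insider questions (an alertness signature: alpha down,
  beta up);
* `scenario_effect` applies the same band shift to insider questions and
  scales the broadband component by `exp(effect/2)`, moving the entropy and
  complexity features between scenario types.

Zero effects make the classes exchangeable by construction (verified by a
two-sample KS test on band-power ratios).  The effect is constant over the
30 s trial; a time-varying (ramping) profile is left as a configuration hook.
Artifacts are injected separately: a line-frequency sinusoid (50 Hz default,
the mains frequency where such studies are typically run; configurable),
sub-hertz drift, blink-like transients confined to FP1/FPz/FP2, and a
dead-channel probability.  Answer labels default to the empirical rates of
the study design the generator emulates (96/242 yes for insider, 150/248 for
conflict questions) and a 2% per-question no-response dropout; the chance-
level and effect-response experiments below use balanced 0.5 rates instead so
that "chance" is well defined.

What the generator does **not** emulate: non-stationarity over a session,
topographically structured sources, eye/muscle artifacts beyond the blink
template, volume-conduction mixing beyond a uniform shared component, and
any psychological realism.  Passing tests demonstrate that the pipeline is
correct and leakage-free and that its statistical machinery behaves as
designed — not that real malicious intent is detectable at these accuracies.

Seed policy: one master seed; per-subject baselines, per-question signal and
artifact streams, and per-fold selection/tuning streams are derived as
`SeedSequence([master, stage, subject, question/fold])`, so any subset of a
run can be regenerated in isolation.  Derived integer seeds stay below 2^31.

## Preprocessing

Fixed order: polyphase resample to 250 Hz; zero-phase 4th-order Butterworth
1 Hz high-pass; zero-phase IIR notch (1 Hz bandwidth) at the line frequency
and its first harmonic; bad-channel detection — flat line (variance <
10⁻¹⁰ µV²) or maximum absolute correlation with every other channel < 0.4 —
followed by inverse-squared-distance interpolation on unit-sphere electrode
positions; average re-reference over all 21 channels.  A recording with more
than half its channels flagged is rejected with an explicit error.  Every
step is appended to a log carried by the cleaned recording.  The interactive
artifact-subspace-reconstruction and ICA stages used on real laboratory data
are out of scope; the bad-channel stage plus an optional amplitude-threshold
epoch rejection (off by default) stand in for them, and the log makes the
substitution visible.

Epoching: full 2 s windows at a 1 s step starting at 0 (a 30 s question gives
29 epochs — the "1 s moving average" is read as a sliding start, the only
reading consistent with that count); a recording shorter than 2 s but at
least 1 s long is emitted whole; shorter recordings yield nothing.  Tail
windows between 1 and 2 s inside full-length recordings are *not* emitted,
since that would give 30 epochs from 30 s.

## Features (65 per channel per epoch)

* **Time domain (9)** — mean, mean square, median, peak-to-peak, skewness and
  kurtosis (bias-uncorrected moments, Pearson kurtosis), Hjorth activity
  (variance), mobility (sqrt(var(Δx)/var(x))), complexity
  (mobility(Δx)/mobility(x)).  For a sampled sinusoid of frequency f,
  mobility is 2·sin(πf/fs), which the tests check on a frequency grid.
* **Wavelet (24)** — 5-level db4 decomposition; per subband D1…D5, A5:
  relative energy, within-subband Shannon entropy of coefficient-energy
  fractions, maximum squared coefficient, variance of squared coefficients.
  The epoch is zero-padded to the next multiple of 2⁵ and decomposed in
  periodization mode, making the filter bank orthonormal: subband energies
  sum to signal energy at machine precision and relative energies to exactly
  1.  (Symmetric padding was considered and rejected because boundary
  redundancy breaks energy conservation; zero-padding adds a negligible edge
  discontinuity at these epoch lengths.)  An independent circular-convolution
  filter bank serves as the test oracle.
* **Spectral (28)** — single Hann-windowed periodogram per epoch (0.5 Hz
  resolution at 2 s; Welch averaging has no room at this length); per band
  delta 1–4, theta 4–8, alpha 8–13, beta 13–25, high beta 25–30, gamma
  30–40, high gamma 40–50 Hz (half-open [low, high), last band closed):
  absolute power (sum of in-band periodogram values), relative power over the
  seven bands, max power, peak frequency.
* **Nonlinear (4)** — approximate and sample entropy with m = 2,
  r = 0.2·SD(x) (conventional defaults; configurable), Chebyshev distance,
  computed by an incremental running-max distance matrix and verified against
  literal O(n²) template counting; sample entropy uses a bounded convention
  (B = 0 → 0; A = 0 capped at one match, returning log B).  Permutation
  entropy of order 3, delay 1, normalized by log 3! — stable at 500-sample
  epochs.  Correlation dimension by Grassberger–Procaccia: delay = first
  non-positive autocorrelation lag (capped at 10), embedding dimensions 2–8
  over a common start-index set (subsampled to ≤256 vectors), slope of
  log C(r) vs log r over radii spanning the 10th–50th percentile of pairwise
  distances, median slope across dimensions.

Constant/degenerate inputs return 0 for the affected features and set a
`degenerate` flag in the feature table rather than raising.  Normalization is
plain z-scoring with per-column mean/SD *fitted on training-fold rows only*
(zero-variance columns map to 0); normalizing across all subjects and trials
globally would leak held-out statistics into training, so the global variant
is deliberately not offered.

## Feature selection (training folds only)

Both selectors are built on random forests.  Because scikit-learn exposes no
out-of-bag permutation importance and permutation importance evaluated on
training rows is degenerate for an interpolating forest, the package fits its
own bagged ensemble of sqrt-feature decision trees and measures per-tree
out-of-bag accuracy drop under single-column permutation; Gini (impurity)
importance remains available as a fast option.

* **Boruta-style wrapper** — each iteration appends a shuffled shadow copy of
  every active column, fits the ensemble, and scores a hit for real columns
  whose importance z-score exceeds the best shadow's; hit counts are tested
  two-sided against Binomial(k, 1/2) with Bonferroni correction over the
  initial column count (α = 0.01), classifying columns as confirmed or
  rejected (rejected columns leave the design matrix); the loop stops early
  when nothing is undecided.  Columns still undecided at the iteration cap
  are *tentative* and are included in the downstream feature set (inclusive
  policy — avoids empty selections on small folds).
* **varSelRF-style backward elimination** — an initial forest ranks features
  once by unscaled mean decrease in OOB accuracy; the worst 20% are dropped
  per step down to a 2-column floor, the OOB error of each candidate set is
  recorded, and the smallest set within one standard error
  (√(e(1−e)/n)) of the minimum error is returned.

Defaults (iteration cap 30 and 50 trees for the wrapper; 200-tree forests
for the elimination) are desk-scale choices for per-fold use on a single
CPU; the R originals default to forests one to two orders of magnitude
larger, and the tree counts are exposed in the configuration for users who
want them.  On the planted benchmark (5 columns mean-shifted by 1.5 SD among
50 iid noise columns, n = 300) both selectors recover all informative columns
in ≥90% of seeded runs, the wrapper confirms no noise column in ≥90%, and
with labels independent of the features its confirmed set is empty.  Note
the wrapper is an *all-relevant* method evaluated in-sample: a noise column
whose chance correlation with the labels is strong enough to generalize
across bootstrap splits of the same finite dataset is, for this purpose,
relevant — OOB-based importance keeps such confirmations rare but cannot
eliminate them.

## Cross-validation, voting, and summaries

Leave-one-question-out per subject: the intent task cross-validates over the
subject's insider questions only (9 training questions per fold at the full
design), the scenario task over all questions (19 per fold).  Folds whose
training side would contain a single class are skipped with a warning and
excluded from the subject's accuracy denominator.  Per fold the scaler is
fitted, the selector run, and the classifier tuned on training rows only;
an audit trail records the exact row sets and a test re-derives their
disjointness from the held-out question.

Classifier grids: kNN k ∈ {1,3,5,7,9}; RBF-SVM C ∈ 10^{−1..3},
γ ∈ 10^{−4..0}; Gaussian NB untuned; MLP with one hidden layer of width
{5,10,20}, 300 iterations, seeded initialization.  Tuning uses question-
grouped 3-fold internal validation (epochs of one question never straddle
tuning folds); ties break to the first grid entry.

A question is predicted by majority vote over its epochs; the question score
is the positive-epoch fraction, so the vote equals thresholding the score at
0.5, with ties going to the negative class (no/conflict) — verified
exhaustively for every vote pattern at 1–29 epochs.  ROC curves sweep the
observed question scores and AUC is trapezoidal.  Summary tables report the
mean per-subject accuracy (%) for every selector × classifier cell; channel-
subset runs (frontopolar FP1/FPz/FP2; mid-frontal F3/Fz/F4) restrict the
feature space to the subset's 3 × 65 columns and are otherwise identical.

### A caveat on chance-level behavior

Leave-one-question-out validation has a known small-sample artifact: holding
out a question shifts the training majority toward the opposite class, so at
zero effect size majority-following classifiers are biased *below* the
majority-class rate ("anti-learning"), and majority voting over epochs
amplifies the bias.  The effect shrinks with the number of questions and is
immaterial at strong effect sizes, but at desk scale (≤10 questions per
subject) individual cells can sit a few points below chance.  The chance-
level calibration test pools 10 synthetic subjects with 8 insider questions
each and checks every selector × classifier cell against the 95% binomial
band around the realized majority rate; users evaluating tiny designs should
expect the artifact and not read below-chance cells as bugs.

## Problem sizes used in tests and the acceptance script

Full-scale runs (25 subjects × 20 × 30 s × 21 channels) are supported but
slow on one CPU (feature extraction is ~7 s per 30 s question, dominated by
the entropy features).  The shipped tests and `scripts/acceptance.py`
therefore run the complete pipeline at reduced scale as the package's own
evaluation design: strong-effect studies use 2–3 subjects × 10 questions of
30 s on 3 frontal channels (preserving the 29-epoch majority vote, which is
what drives question-level accuracy); calibration and effect-response
studies use 3–10 subjects with 5–10 s questions on 2–4 channels; the
selector benchmark uses the planted-feature design above.  At these sizes the
strong-effect intent study reaches ~97% question accuracy (AUC 1.0) and the
zero-effect control stays at 50%.

## Known limitations

* EDF output is not provided (recordings interchange as plain float matrices
  with JSON sidecars); EDF input is read through `mne` when installed.
* The generator's effects are spatially uniform, so channel-subset analyses
  measure only the cost of fewer feature columns, not topographic
  specificity.
* The correlation-dimension estimator subsamples pairwise distances for
  tractability and is a feature, not a certified dimension estimate.
* Boruta's level control is in-sample by nature (see above).
* No pooled cross-subject modelling is offered; the design is deliberately
  subject-wise.
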