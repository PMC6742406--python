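# Methods

`mweeg` implements an individual-level mind-wandering (MW) detection
analysis for probe-based lecture EEG: a listener's 16-channel recording is
conditioned, artifact-handled, cut into labelled pre-probe epochs, and
classified per canonical frequency band with common spatial patterns (CSP)
features and a nonlinear SVM, with chance level calibrated by label
permutation. A synthetic forward model generates study-scale sessions with
known ground truth so every stage has a parameter-recovery test.

## Signal model of the synthetic generator

A session is `x(t) = A s(t) + b(t) + n(t)`:

* `s(t)` — band-limited Gaussian sources (white noise passed through FIR
  band filters), two per canonical band by default. Band-limited noise
  rather than sinusoids keeps per-epoch covariances full-rank, which CSP
  needs; a pure tone would make them nearly singular.
* `A` — smooth signed scalp topographies (Gaussian bumps at random sites on
  the 10-20 layout), redrawn until well-conditioned.
* Class effect: inside the 10 s window preceding each probe whose simulated
  response is MW, designated sources are amplitude-scaled by
  `sqrt(class_effect)` (power ratio `class_effect`), with 0.2 s cosine
  ramps to avoid switching transients. Restricting the effect to the
  pre-probe window keeps the labels exactly aligned with what the pipeline
  extracts.
* `b(t)` — blink artifacts: half-sine bursts of 200-400 ms at Poisson
  times, projected through a frontal-dominant topography. The scalar burst
  time course is returned so tests can verify exact recoverability.
* `n(t)` — white sensor noise.

Defaults emulate the study conditions the pipeline targets: 16 channels at
250 Hz (the sampling rate is not dictated by the design; 250 Hz satisfies
Nyquist for the 30 Hz analysis ceiling with margin), 13 usable probes,
240 s probe spacing, P(MW) = 0.35, P(unsure) = 0.04, one alpha-band source
with a 2x power effect, blinks at 10/min and 120 µV, 5 µV sensor noise.
Cohorts can be `individualized` (each subject gets an independently drawn
effect band and topography — the regime in which detection patterns do not
transfer across subjects) or shared (one topography for all — the positive
control in which leave-one-subject-out transfer works).

What the generator does **not** model: volume-conducted head geometry
(no BEM lead field), EMG or line noise, non-stationary background rhythms,
and within-class heterogeneity of MW episodes. Passing tests therefore show
that the pipeline recovers planted linear band-power effects at realistic
SNR — not that real lecture EEG carries such effects.

## Conditioning

1. **Bad channels** — a channel is removed when the robust z-score
   (median/MAD across channels) of its log-variance exceeds 5. The rule is
   deliberately conservative; on realistic synthetic sessions it removes
   zero to two channels.
2. **Average re-reference.**
3. **Exponential running standardization** with smoothness `alpha = 0.001`:
   `mu_t = (1-a) mu_{t-1} + a x_t`, `v_t = (1-a) v_{t-1} + a (x_t-mu_t)^2`,
   output `(x_t-mu_t)/sqrt(max(v_t, 1e-4))`. The mean is updated *before*
   the output is formed. Initialization: `mu_0` = first sample, `v_0` =
   variance of the first 10 s (fallback 1). Both recursions are evaluated
   as first-order IIR filters.
4. **1-30 Hz bandpass** — even-length (Type II) linear-phase FIR, Hamming
   window, order auto-selected from the narrower transition band (1 Hz at
   the low edge, 5 Hz at the high edge, ~3.3·fs/Δf taps), applied
   forward-backward so epoch timing is not delayed relative to probe
   onsets. Zero-phase application squares the magnitude response; passband
   ripple is negligible for the Hamming design.

A consequence worth knowing: with `alpha = 0.001` at 250 Hz the variance
tracker has a ~4 s time constant, which is *shorter* than the 10 s
pre-probe window. Block-modulated power effects are therefore partially
compressed by standardization, and because all bands share one per-channel
running sigma, part of a narrow-band effect is redistributed into the other
bands (a band whose own power is flat acquires a negative apparent effect).
This is intrinsic to the published conditioning recipe, halves the
post-conditioning contrast of a planted effect, and means the
best-detecting band need not be the band carrying the generative effect —
an instructive parallel to the per-participant best-band variability the
method reports on real data.

## Artifact handling

Two stages, in a fixed order (epoch screening before ICA, because large
transients disrupt source separation):

1. **Peak-to-peak epoch rejection.** The recording is cut into 1 s epochs;
   a single global threshold is selected by cross-validated reconstruction
   error (for each candidate, the mean of retained training epochs is
   compared by RMSE to the pointwise median of held-out epochs; the
   arg-min wins, ties to the most permissive). This is the simplest
   published form of data-driven threshold selection; no channel-wise
   repair or interpolation is attempted.
2. **ICA.** Extended infomax is fitted on the surviving epochs after PCA
   whitening; rank deficiency caps the component count. Long recordings
   are subsampled (whole epochs, seeded) to at most 50 000 time points
   before fitting — for 16 channels this is far beyond what infomax needs,
   and fitting on full hour-long sessions costs minutes without changing
   the result. Components whose source skewness exceeds ±2.50 or whose
   *excess* kurtosis exceeds ±3.00 (strict inequalities) are rejected and
   the signal is re-mixed from the remainder. Excess (Fisher) kurtosis is
   the only convention under which a symmetric ±3 threshold is coherent.
   Rejection is fully automatic; there is no visual-confirmation step.

The **artifacts-present** analysis variant runs the identical pipeline with
stage 2 bypassed (stage 1 still applies); nothing else changes.

## Epoching and labelling

The 10 s before each probe — half-open interval `(onset-10 s, onset]`,
sample index `floor(t·fs)` — is cut into five 2 s epochs sharing the
probe's id and response label. "Unsure" probes are ignored; probes with
less than 10 s of history are skipped with a warning. The learned
peak-to-peak threshold is then re-applied to the pre-probe epochs
(per-2 s-window rejection, not whole-probe rejection).

## Band power and statistics

Welch estimates (1 s Hann segments, 50 % overlap) are integrated per band
with the closed-open convention `[lo, hi+1)` on the frequency grid, so the
four canonical bands (theta 4-7, alpha 8-12, beta1 13-18, beta2 19-30 Hz)
tile 4-31 Hz without double-counting. ANOVAs run on **log** power (band
powers are right-skewed; a config switch restores absolute power).

Two families of 2 (state) x 4 (band) repeated-measures ANOVAs are fitted
on cell means (one value per unit x state x band — the aggregation forced
by the reported df structure): per channel with participants as units, and
per participant with channels as units. The univariate decomposition uses
a separate error term per effect (state tested against state x unit,
interaction against the three-way residual), giving dfs `(1, n-1)` and
`(3, 3(n-1))`. No sphericity correction is applied by default — the state
factor has two levels and needs none; the interaction test is the plain
univariate form. Effect sizes are partial eta squared
`SS_eff/(SS_eff+SS_err)`, equivalently `F·df1/(F·df1+df2)` from reported
statistics. Holm-Bonferroni correction is applied per factor family across
the parallel models. Post-hoc paired t-tests per band report uncorrected
p-values; zero-variance differences are handled exactly (all-zero → t=0,
p=1; constant shift → ±inf, p=0).

## CSP and classification

With trace-normalized class covariances (per-epoch covariances divided by
their trace before averaging, so high-amplitude epochs do not dominate),
filters solve `C_mw w = λ (C_mw + C_not) w`. The three largest-λ and three
smallest-λ eigenvectors form the six filters; patterns (the scalp maps)
are the corresponding columns of the pseudo-inverse of the full filter
matrix. Filter rows are unit-normalized with compensating pattern scaling;
signs are fixed so each filter's max-|weight| coefficient is positive;
λ-ties break by input channel order (stable sort). Shrinkage toward scaled
identity is off by default with an automatic fallback to γ=0.05 when the
composite covariance is ill-conditioned. Features are log normalized
powers `log(v_i / Σ v_j)` of the six time-domain projections — scale-free
by construction. Band-specific epochs are obtained by filtering the
*continuous* record per band before extraction (short-epoch filtering
suffers edge effects); per-band filters widen their -6 dB cutoffs by half
a transition width so the integrated band sits in the flat passband.

Classification is an RBF-kernel SVM, `C = 1`, kernel width from the median
heuristic on training features, no class weighting (consistent with the
method's tendency to under-predict the minority MW class). Intra-subject
evaluation is 5-fold CV grouped at the probe level (all five epochs of a
probe share a fold; one label-stratified partition per subject, shared
across bands). The CSP model and SVM are fitted on training folds only.
The best band is the one maximizing mean F1, ties broken in canonical band
order. Inter-subject evaluation is leave-one-subject-out on one band, with
training subjects sorted internally so results are invariant to cohort
order.

## Chance calibration

Per subject and band, the full CSP+SVM CV is re-run on label permutations
(shuffled at the *probe* level, preserving within-probe dependence — the
pipeline's main reproducibility-sensitive choice; fold partitions are
redrawn per iteration) and the mean-over-folds F1 recorded; the 95 %
chance band is the empirical 2.5/97.5 percentile interval. The default is
100 iterations (a flag restores 500). True-label CV F1 values are compared
to the null samples by a Welch two-sample t-test. On uninformative
features the SVM drifts to degenerate all-one-class solutions, so the
chance F1 distribution concentrates between the coin-flip value and the
always-positive value `2p/(1+p)` for MW fraction `p` — e.g. ~0.52 at
p = 0.35 — rather than at the coin-flip value alone.

## Metrics

MW is the positive class. Accuracy is reported in percent; precision,
recall and F1 (harmonic mean) with zero-denominator cases defined as 0.
`predicted MW rate` is the fraction of MW predictions pooled over test
folds; `observed MW rate` is the MW fraction of the processed epochs.
Cross-subject summaries: Pearson r between observed and predicted rates,
Spearman ρ between per-subject epoch counts and F1.

## Problem sizes used in tests and the acceptance script

Unit tests use sessions of 2-8 probes at 15-30 s spacing. The acceptance
script uses 13-20 probes at 20 s spacing — the study's per-subject epoch
counts (65-100 pre-probe epochs) with shorter idle stretches between
probes, which leaves every probe-locked quantity unchanged — and
100-iteration permutation nulls. The "strong effect" positive-control
condition is `class_effect = 6`; given the ~2x compression by the
standardization stage this corresponds to a clearly separable
post-conditioning effect, whereas the default 2x is a realistic moderate
one. The calibration check excludes the rare replicate whose simulated
subject never reports MW (no detection task exists for such a subject).

## Known limitations

* Patterns are compared to planted topographies only up to sign and a
  common-average projection (the reference removes the mean).
* The permutation null inherits the discreteness of small probe counts;
  CIs from 13-probe subjects are coarse.
* No streaming/online inference; no cross-session transfer of CSP models;
  no hyperparameter search beyond the documented defaults.
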