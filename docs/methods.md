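# Methods

`dichotic` re-implements, as a tested pipeline on synthetic data with known
ground truth, the single-trial analysis chain used to study two neural
"attentional filter" mechanisms in dichotic (dual-talker) listening:
lateralization of 8–12 Hz alpha power and the differential neural tracking
of attended versus ignored speech, together with the statistical machinery
that links both measures to listening behaviour. This note describes the
generative model, every analysis stage and its assumptions, the design
choices made where the procedure was genuinely open, and what the passing
tests do and do not establish about real data.

## The simulated experiment

Each simulated subject performs a 2×2 cued dichotic-listening task:
a spatial cue (informative → selective attention; uninformative → divided
attention) crossed with a semantic cue (specific vs. general), 60 trials
per cell by default (240 per subject), probed ear balanced within cells.
Two five-word "sentences" are presented, one per ear; the subject is probed
on the final word of one sentence.

**Stimuli.** A sentence is a train of five two-syllable word pulses: a
150 ms Hann-shaped primary pulse (amplitude jittered in 0.85–1.15) plus a
weaker secondary pulse (100 ms; 25–45% of the primary amplitude) at a
160–240 ms offset. Word-onset gaps are drawn quasi-regularly from
350–550 ms and rescaled so the sentence spans a duration drawn uniformly
from 2183–2963 ms. The two-syllable substructure matters: it makes the two
streams of a pair locally distinguishable even where word onsets coincide,
as envelopes of different natural words are. The pair is aligned at
final-word onset (the final word's extent is fixed so every pair fits the
presentation window), which leaves sentence onsets asynchronous by an
amount drawn uniformly from 0–580 ms, either stream leading with equal
probability. Stimuli are represented directly as non-negative onset
envelopes at 125 Hz; no audio is synthesized.

**Source signals.** Epochs span −0.5 to 6.5 s around cue onset at 250 Hz,
with sentences inside the 3.5–6.5 s window, for 5 parcels per hemisphere
(an "auditory region of interest"). Each parcel carries:

1. *Envelope encoding*: the convolution of a temporal response kernel
   (default: a smooth N1/P2-like biphasic kernel over 0–350 ms lags) with
   `gain_attended × attended envelope + gain_ignored × ignored envelope`
   (defaults 1.0 / 0.3), scaled 1.0× in the hemisphere contralateral and
   0.5× ipsilateral to each ear's input. The attended gain is jittered
   per trial by a latent attention state (SD 0.2) that also feeds the
   behavioural model. Divided-attention trials use the mean of the two
   gains for both streams: without an informative cue there is, on
   average, no differential tracking to plant.
2. *Alpha*: a 10 Hz sinusoid (random phase per parcel) whose
   ipsilateral/contralateral power ratio relative to the attended ear is
   1.5 under an informative cue and 1.0 otherwise, constant across the
   epoch. Within-trial alpha dynamics are deliberately not emulated; the
   constant ratio suffices for index-recovery testing.
3. *Noise*: pink (1/f) plus 20% white noise, scaled so that the SD of the
   attended envelope drive over the sentence divides the noise SD by
   `snr_envelope` (default 2 — not stated by any source; chosen once as a
   regime where single-trial indices are noisy but group effects are
   clear).

**Behaviour.** Accuracy is Bernoulli with a logistic linear predictor:
intercept 2.1 plus deviation-coded cue, probed-ear, age and hearing (PTA)
effects with planted log-odds `log 3.5` (spatial cue), `log 1.1`
(semantic), `log 1.25` (ear), `log 0.80` (age/SD), `log 0.75` (PTA/SD), a
trial-level tracking-state effect `log 1.06`, and subject (SD 0.7) and
item (SD 0.3) random intercepts. Response speed (1/RT) is Gaussian on a
z-scale with planted standardized effects (0.57 spatial cue, 0.20
semantic, 0.08 tracking trait, 0.08 ear, −0.15 age, −0.05 PTA), variance
components chosen so the total variance is ~1, then mapped to RT via
`speed = 0.62 + 0.17·z`. Errors split 2:1 into spatial stream confusions
vs. random errors; a configured fraction of trials (2%) times out at the
4 s response deadline.

Everything is a pure function of the configuration and its seed; the
dataset is stored as one HDF5 file (epochs, envelopes, truth) plus a CSV
trial table, written without HDF5 timestamps so identical runs are
byte-identical.

## Alpha-power lateralization

Per subject: Morlet wavelet power (6 cycles) at 8, 9, 10, 11, 12 Hz on the
250 Hz epochs; Box-Cox variance stabilization `(x^p − 1)/p` with `p = 0.5`;
whole-trial normalization (per parcel × frequency, subtract the mean over
trials and time); average over frequencies and over the parcels of each
hemisphere; then the robust lateralization index

    ALI(t) = (σ(P_ipsi) − σ(P_contra)) / (σ(P_ipsi) + σ(P_contra)),

with σ the inverse-logit, hemispheres labelled ipsi/contra by the probed
ear. Applying the inverse-logit *after* ROI averaging (rather than per
parcel) is a choice the source procedure leaves open; it is isolated in
one function. Samples within half the longest wavelet's support (375 ms at
8 Hz) of the epoch edges are treated as missing. Summaries per trial: the
mean over the sentence window (3.5–6.5 s) and the mean over the final 35%
of the percent-warped sentence.

Frequency resolution (integer steps), unweighted ROI parcel means, and the
rectified-first-difference onset envelope (20 ms smoothing before
differencing) are likewise standard-convention choices, each behind its
own function.

## Envelope decoding and neural tracking

Backward models reconstruct the onset envelope from time-lagged parcel
responses, ŝ(t) = Σ_n Σ_τ g(τ, n) r(t + τ, n), with lags covering −100 to
+500 ms (samples −13…62 at 125 Hz; 76 lags — the lag grid floors both
half-sample bounds, keeping integer bounds inclusive). Weights are the
closed-form ridge solution `g = (RᵀR + λ m I)⁻¹ Rᵀ s`, where `m` is the
mean of the trace of RᵀR; design columns and targets are mean-centered per
training set (the model has no intercept term). Epochs are low-passed at
8 Hz (zero-phase FIR) and decimated to 125 Hz before decoding — the
slow-fluctuation band conventionally used for speech tracking; the cutoff
is configurable.

Attended and ignored decoders are trained separately for attend-left and
attend-right selective trials (zero-padding 600 ms between concatenated
trials). One global ridge parameter is selected on the grid
λ = 10⁻⁵…10¹⁰ by cross-validated mean sliding-window correlation, with
mean squared error breaking ties (the two criteria the procedure names,
combined lexicographically). Every selective trial is reconstructed leave-
one-out within its attend side; divided trials are decoded with the full
decoders of the probed side (probed-left ↔ attend-left models).
Reconstruction accuracy is the Pearson correlation in a centred 248 ms
(31-sample) window stepped by one sample; zero-variance windows are
missing, never zero. The tracking index
`(r_att − r_ign)/(r_att + r_ign)` is computed per sample, missing where
the denominator magnitude falls below 10⁻⁶, and stored unclipped (it is
unbounded when a correlation is negative). Backward weights are made
interpretable by the covariance transformation
`A = Cov(R) g / Var(ŝ)`.

## Temporal alignment and cross-correlation

Because sentences differ in length, per-trial index time courses are
mapped onto 100 bins of 1% sentence increments (bin means), then smoothed
with a centred 3-bin rectangular window evaluated at every bin — the
reading of the "3% window, 1% overlap" convention that preserves the
100-bin axis; edge bins use available neighbours. Final-word summaries
average bins 66–100. Group time courses are subject means first, then the
grand mean with between-subject SEM.

The grand-average tracking and ALI time courses are related by a
normalized cross-correlation over ±50 bins (full-series SDs × overlap
length in the denominator; positive lag = first series leads). Chance
levels come from 5000 surrogates that independently permute the bin order
of each series; the 2.5th/97.5th percentile per lag forms the band.
Whole-bin order permutation is the plainest reading of "independently
permuted time courses"; trial- and subject-level permutation units are
exposed as options. Bin lags convert to milliseconds via the mean sentence
duration (lag × duration/100) — a conversion the source procedure
presupposes but does not state.

## Behaviour and mixed-effects models

Timeout trials are excluded from accuracy; speed = 1/RT uses correct
trials only. Error proportions (stream confusions vs. random errors) are
compared per subject by a paired t test on logits adjusted as
`(k + 0.5)/(n + 1)` to keep zero counts finite.

Neural measures enter the models twice: a between-subject (trait)
regressor — the subject mean, z-scored across subjects — and a
within-subject (state) regressor — the trial deviation from the subject
mean, z-scored globally (z-scoring is global rather than per subject; both
use the n−1 denominator, computed after exclusions). Categorical
predictors are deviation-coded ±0.5 so coefficients are full-range
effects; continuous covariates are z-scored. Accuracy uses a
binomial-logit mixed model, speed a Gaussian mixed model on z-scored
speed; both carry subject and item random intercepts, with random slopes
adopted only when a likelihood-ratio test on nested ML fits favours them.
Wald tests (z, and t-as-z for Gaussian models) are corrected by
Benjamini–Hochberg FDR at q = 5% within each model.

Estimation is delegated to lme4 through an `Rscript` subprocess — the
standard Laplace/ML estimator for crossed random effects; Python-side
mixed-model implementations either lack crossed-intercept GLMMs or proved
orders of magnitude slower at the 50 × 240 scale the recovery tests use.
Model formulas are configuration data (lme4 syntax), so brain–behaviour,
brain–brain and control models are all expressible without code changes.

## Numerical and degenerate-input conventions

- Sliding windows touching series bounds, and all-NaN warp bins, are
  missing and excluded from summaries (with logged counts).
- `select_lambda` on pure noise is defined and terminates (NaN fold scores
  are dropped).
- A subject with fewer than two selective trials on a side is skipped with
  a warning.
- The robust ALI is mathematically inside (−1, 1); logistic underflow at
  extreme inputs can round a float result onto ±1.
- The pipeline expands one master seed into fixed per-stage substreams, so
  re-running one stage never perturbs another's randomness.

## What the synthetic data do and do not show

The generator plants linear, stationary envelope encoding, a constant
sinusoidal alpha asymmetry, and behaviour from the same model family the
analysis fits. Passing tests therefore demonstrate that the pipeline
recovers what it is designed to measure — planted spectral ratios exactly,
kernels and gains through the decoding chain, planted odds ratios and
standardized betas with nominal confidence coverage, planted delays on the
percent-time axis — not that the measures behave this way in real EEG,
where encoding is nonlinear and nonstationary, alpha dynamics are rich,
and envelopes are natural speech.

One property of the noise-free regime deserves emphasis: with measurement
noise off, the parcel signals are an exactly invertible linear mixture of
the two envelopes, so *both* streams reconstruct near-perfectly regardless
of their gains and the tracking index has no positive expectation. A
positive index requires a noise floor, which penalizes the weak-gain
stream's reconstruction more. This is visible in the test suite: the
noise-free decoder-recovery check of index positivity fails by design of
the physics (the fraction of positive trials sits near chance), while
under the default noisy conditions the index is clearly positive on
average. The noise-free regime remains the right one for weight and
kernel recovery.

## Problem sizes

Tests and the acceptance script run at deliberately modest scale chosen as
adequate for the properties under test: single-subject datasets of
120–240 trials for signal-chain checks, 10–20 replicates of 50 × 240
trials for mixed-model recovery and type-I error, 500-permutation
surrogate bands over 50 replicates, and a 2-subject end-to-end pipeline
run for determinism.
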