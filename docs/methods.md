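# Methods

This note documents the models, conventions and design choices behind
`brainheart`, in the spirit of a statistical methods appendix.

## Index derivation

**Minute grid.** All indices live on a 0-based 1-minute grid from monitoring
onset, half-open bins [m, m+1), at most 72 h (4,320 min). Minute values of
pressure signals are trapezoidal time integrals of the waveform over the
minute divided by the covered span; the sample on the next minute boundary
closes the integral, which makes constants exact and leaves an O(1/fs²)
error for band-limited signals, so 100 Hz and 200 Hz recordings agree to
well below 0.01 mmHg. A minute whose fraction of non-finite samples exceeds
25% is missing. Missingness is an explicit boolean mask end to end; the only
place missing values are imputed (as 0, "no correlation") is the model-input
boundary of the CNN.

**PRx.** ABP and ICP are averaged over 10-s bins to isolate slow waves; the
pressure reactivity index is the Pearson correlation of the 30 most recent
bin pairs (a 5-min window) updated every 10 s. The minute value averages the
six window updates ending inside that minute — a declared aggregation
choice. A window with zero variance in either channel is undefined
(missing), never 0. A window needs at least 50% valid pairs.

**Beat detection.** Systolic peaks are local ABP maxima above an adaptive
prominence threshold (30% of the 5–95 percentile spread) with a 250-ms
refractory period. Interbeat intervals (IBI) outside 250–2,000 ms are
flagged implausible. Pulse-interval variability from the arterial line
stands in for ECG R-R variability.

**BRS (xBRS).** Beat-wise systolic pressure and IBI are sampled onto a 1-s
grid using the *nearest beat* (not interpolation: interpolation correlates
neighbouring grid samples and mis-calibrates the significance test below).
For every 10-s segment, the IBI segment is correlated with the SBP segment
at candidate delays 0–5 s; the delay with the highest correlation wins and
its regression slope (ms/mmHg) is recorded if the correlation is positive
and significant. Because the best of six delays is selected, the per-delay
threshold is Šidák-adjusted so the family-wise false-acceptance rate under
an independence null is the nominal α = 0.01; the test suite verifies the
realised null rate by simulation. The physiological gain is reported as a
positive slope (higher systolic pressure lengthens the interval); segments
whose best delay has a negative correlation are rejected. Minute value =
mean of accepted segment slopes.

**LF/HF.** Per 5-min window (right-aligned, hence causal; stepped by
1 min), the Lomb–Scargle periodogram of the unevenly sampled IBI series is
integrated over 0.04–0.15 Hz (LF) and 0.15–0.40 Hz (HF) on a 0.002-Hz grid.
Windows with fewer than half the expected beats are missing, as are windows
whose HF power falls below a 1e-12 stability floor (the ratio is reported as
missing, never infinite). On evenly sampled input the Lomb–Scargle
periodogram equals the classical periodogram to relative 1e-6 (tested).
The 5-min/1-min windowing is a convention choice, not a claim about any
particular clinical configuration.

## WTLCC matrices

Given two aligned minute series, the analysis window of N minutes is split
into K contiguous, non-overlapping sub-windows of w = N/K minutes (N must be
divisible by K; w ≥ 3). Entry (k, j) is the Pearson correlation between I₁
on sub-window k and I₂ shifted by `lag = j − J/2` minutes; J = 240 by
default, so lags span −120…+119 min. Conventions:

* **Lag sign.** Positive lag means I₁ leads I₂ (I₂ is read later). Swapping
  the pair negates the lag once the window follows the lag:
  `build(I2,I1,s)[k, J/2−l] = build(I1,I2,s−l)[k, J/2+l]` exactly; a naive
  column mirror holds only statistically, because the sub-window stays
  pinned to I₁.
* **Edges.** Lagged samples come from the full panel beyond the window when
  available; otherwise the pair is missing (no zero padding). An entry needs
  at least `min_valid_frac` (default 0.8) of w valid pairs.
* **Normalisation.** Entries are full Pearson correlations (mean-removed,
  variance-normalised), hence bounded in [−1, 1]; zero-variance sub-windows
  yield missing rows.
* **Paper-mode grids.** `WTLCCParams(paper_mode=True)` restricts N to
  {360, 720, 1080} min, S to {15, 30, 60, 90} min, K to {15, 30, 60} and
  J = 240 — the published hyperparameter sets for this method family.

Matrices are dropped (with a logged reason) when more than half their
entries are missing; a panel shorter than N yields no matrices.

## Matrix scorer (CNN) and patient aggregation

The scorer is a small channels-last convolutional network implemented in
numpy: conv(3×3, same) → ReLU → max-pool(2×2) blocks, a dense embedding
layer with ReLU, dropout, and a sigmoid head, trained with Adam on
class-weighted binary cross-entropy. Everything is deterministic given the
config seed.

* **Head: flatten, not global average pooling.** GAP is translation
  invariant along the lag axis, and the discriminative feature of lagged
  coupling is precisely the *position* of the correlation ridge; with GAP
  the planted-lag experiment plateaus near AUC 0.7, with flatten it reaches
  1.0. GAP remains available (`pooling="gap"`).
* **Patient aggregation.** A patient's score is the unweighted mean of all
  their matrix scores; the label is unfavourable iff the mean strictly
  exceeds 0.5 (a score of exactly 0.5 is favourable). The patient embedding
  is the mean of per-matrix embeddings from the penultimate layer.
* **Splits.** Train/validation splits operate on patient ids only
  (stratified by outcome), so no patient contributes matrices to both
  sides.
* **Restarts.** Small networks occasionally collapse to the constant
  solution (dead ReLUs; the scores of every input coincide). Training is
  restarted up to twice with re-derived seeds when the score spread on
  *training* matrices falls below 1e-3 — healthy fits spread well above
  this even on uninformative inputs, so only genuinely dead networks
  restart, and no validation information enters the decision.

**Hyperparameter search.** A sequential model-based optimizer over the
discrete space of signal pairs × WTLCC geometry × learning rate. Startup
trials cycle every dimension through a shuffled order of its choices
(quasi-random coverage, so each signal pair is visited before modelling
starts); afterwards candidates are proposed Tree-structured-Parzen style:
trials are split into the best γ = 0.3 fraction and the rest, each
dimension gets add-one-smoothed categorical densities g and b, and the
candidate with the best Π g/b among 24 draws from g is evaluated. The
objective is validation patient-level AUC.

## Tabular comparison

XGBoost (binary logistic, depth 3, 200 rounds, learning rate 0.1, fixed
seed) on one row per patient: either the 72-h means of the five indices or
the patient embedding, plus the CRASH covariates (age, GCS, pupils encoded
ordinally 0/1/2 as bilateral/unilateral/nonreactive, extracranial injury
0/1). Patients missing a covariate are dropped, not imputed, with a logged
reason. Two numerical choices matter on cohorts of tens of patients:
splits use the exact greedy method (histogram binning derives candidate
thresholds from training quantiles only and can place *every* validation
row in a single leaf when the training classes separate with a wide gap),
and early stopping on the tiny validation set is off by default.

## Evaluation

GOS 4–5 and GOS-E 5–8 are favourable; GOS 1–3 and GOS-E ≤ 4 unfavourable.
AUC is the rank statistic with ties averaged; F1 is computed for the
unfavourable (alarm) class; the confusion matrix applies the strict 0.5
threshold. Cohort comparisons report median (Q1–Q3) per class with
Shapiro–Wilk normality recorded, two-sided Mann–Whitney U (exact when both
groups have ≤ 8 patients, asymptotic otherwise), and chi-squared for
categorical variables with Fisher's exact test when any expected cell is
below 5; α = 0.05, no multiplicity correction.

## Synthetic generator

The generator is the validation instrument: every emitted quantity has a
known ground truth.

**Waveform fidelity** (≥ 50 Hz, used for index validation on ≤ 2-h
snippets). The ABP channel is a beat train: beat n carries a stereotyped
pulse — raised-cosine upstroke peaking a fixed 0.12 s after beat onset,
then exponential decay (τ = 0.25 s) — scaled so the systolic peak equals
that beat's SBP and the beat's time average equals the slowly wandering
mean pressure. The peak sits at a fixed *time*, not a fixed fraction of the
interval; a fractional peak would high-pass filter the detected IBI
sequence and bias pulse-derived HRV (≈ +18% on the LF/HF ratio at 75 bpm).
The IBI recursion realises the baroreflex:

    IBI_n = IBI₀ + gain·(SBP_{n−d} − SBP₀) + LF(t) + HF(t) + ε_n

with the delay d in beats matching `baro_delay`, LF/HF sinusoidal
modulations at 0.10/0.25 Hz whose powers are `lf_power`/`hf_power` (ms²),
and white noise of SD `ibi_sd`. SBP oscillates at the same two frequencies
(Mayer and respiratory bands) and follows a slow mean. The ICP channel is
`icp_base` plus B-wave-band slow waves (0.3–3 cycles/min, a sum of 4
random-phase sinusoids normalised to unit variance — chosen over filtered
noise for analytic controllability; component frequencies are drawn
stratified, one per equal log-frequency stratum, so every realisation
covers the band rather than occasionally collapsing to a near-monochromatic
wave whose periodic autocorrelation would make lags ambiguous) plus a small cardiac pulse; the slow
wave is correlated with the slow ABP mean at the polarity and magnitude of
the planted pressure-reactivity target. The LF amplitude envelope is
multiplied by `1 + strength·0.5·s(t − lag)`, planting the ICP→ANS coupling.

**Minute fidelity** (cohort-scale experiments; 72 h at 200 Hz across a
cohort would be pointless for what it tests). The 1-min panel is emitted
directly with the same statistical structure: ICP = base + slow waves drawn
from the 0.3–0.5 cycles/min sub-band (the 1-min grid's Nyquist is
0.5 cycles/min, faster components would alias); CPP = wandering mean ABP −
ICP; BRS ≈ gain; PRx ≈ planted sign × coupling; LF/HF = power ratio ×
`(1 + strength·0.5·s(t − lag))` with multiplicative log-normal noise. The
modulation is *linear* here rather than the squared envelope→power relation
of the waveform path: squaring adds harmonic content above the minute-grid
Nyquist that aliases into spurious correlation-ridge peaks, and the purpose
of this fidelity level is a clean, analytically known planted lag.

**Cohorts.** Per-patient physiology is a class template with relative
jitter (default ±10%) on the continuous fields; the designed class signal
(coupling lag/strength, reactivity sign, baroreflex delay) is copied
exactly. CRASH-style metadata is sampled from severe-TBI-like marginals
(age ≈ N(45, 16) clipped to 18–85, GCS uniform 3–12, pupils 76/14/10%,
extracranial injury 45%) and carries no class signal. Byte-identical
reproducibility given the cohort seed.

**What the generator does not emulate.** Plateau waves, paroxysmal
sympathetic hyperactivity episodes, craniectomy effects, drug titration,
artefacts and gaps beyond simple invalid-sample masking, ECG morphology,
and any nonlinearity of the true ICP–ANS relationship: the lagged-envelope
coupling is one plausible planted structure, not a physiological claim.
Passing the recovery experiments therefore shows the *pipeline* measures
what it claims to measure under known conditions — not that real TBI
monitoring carries this much signal.

## Validation experiment sizes

The bundled experiments are sized for a single CPU: the planted-signal
cohort uses 40 minute-fidelity patients with WTLCC geometry N = 360,
S = 120, K = 15 (34 matrices of 15×240 per patient) and a two-block CNN;
lag-recovery and oracle checks use the full published geometry
(N = 1080, S = 90, K = 60); waveform-level index validation uses 30-min
snippets at 100–125 Hz. The search experiment runs 10 seeded repeats of a
budget-12 search over six signal pairs. In that cohort the mean-ABP wander
is given a dominant amplitude (12 mmHg vs 3 mmHg of ICP slow wave) so that
CPP — which by definition contains −ICP — does not inherit a usable copy of
the planted ICP–LF/HF coupling.

## Known limitations

* The beat simulator's pulse morphology is stereotyped; beat detection
  performance on real arterial lines (dicrotic notches, damping, artefacts)
  is untested here.
* PRx/BRS/LF-HF windowing constants follow common conventions; clinical
  deployments tune them, and the recovery tolerances quoted in the tests
  hold for the simulator's conditions.
* The numpy CNN targets small matrices and cohorts; it makes no attempt at
  GPU-scale performance.
* With ~14 validation patients, patient-level AUC has a sampling SD of
  roughly 0.15 under the null — single-split results on cohorts of this
  size should be read accordingly (the tests therefore use planted effects
  far from the decision boundaries).
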