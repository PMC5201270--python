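# Methods

This note documents the models behind `ecgrepol`, the choices made where
the design was genuinely open, and what the synthetic data can and cannot
establish.

## The estimand and the analysis chain

The scientific question is whether a drug's ECG effect profile reflects
selective hERG potassium-channel block or multichannel block (hERG plus an
inward current, here the late sodium current).  The readout is the
placebo-corrected change from baseline (ΔΔ) in eight repolarization
biomarkers: QTc, J-Tpeakc, Tpeak–Tend, T-wave flatness, T-wave asymmetry,
ERD30%, LRD30% and T-wave amplitude.  The analysis chain is

synthesize/ingest 10-s ECGs → median-beat delineation → morphology →
heart-rate correction → change-from-baseline and ΔΔ mixed model →
concentration–response and mitigation tests → ROC and decision-rule
classification.

## Synthetic trial generator

The generator emulates a five-period randomized crossover in 21 healthy
subjects (8 female), each receiving every arm {placebo, dofetilide,
moxifloxacin, mexiletine+dofetilide, lidocaine+dofetilide} in a cyclic
Latin-square sequence, with three 10-s replicate ECGs per time-point and a
pre-dose baseline per period.

**Pharmacokinetics.** One-compartment, first-order absorption, superposed
over three daily doses at 0, 5.5 and 11 h (ka = 0.8/h, ke = 0.22/h) so the
population curve peaks ≈ 12.7 h after the first dose; scales are set to the
published mean peak concentrations (dofetilide 1.8, mexiletine 1426,
lidocaine 2261 ng/mL).  Moxifloxacin gets a single morning dose (ka =
1.5/h, ke = 0.15/h, Cmax 3000 ng/mL ≈ 1.7 h) so its effects peak at the
morning/afternoon time-points used for it downstream.  `ka = ke` is
rejected rather than special-cased.

**Drug effects.** Effects are linear in concentration and additive across
co-administered drugs.  The population targets at each drug's reference
(peak) concentration are the published placebo-corrected changes:
dofetilide +45.2 ms QTc, +29.1 ms J-Tpeakc, +0.11 flatness, −87.9 µV
amplitude (etc.); the late sodium blockers are increments solved so the
combination arms land on their published values (+17.3/+17.9 ms QTc,
+1.1/+4.1 ms J-Tpeakc).  Moxifloxacin, whose effect table is not published,
is the dofetilide signature scaled to +12 ms QTc, consistent with its
reported 10–14 ms QTc prolongation at therapeutic exposure.  Inter-subject
variability: lognormal mean-one sensitivity multipliers per drug
(σ = 0.30, set so ΔΔ confidence-interval widths approximate the published
ones) and lognormal concentration factors (σ = 0.15).  No pharmacodynamic
synergy is modelled.

**Waveform model.** A beat is a biphasic QRS (three raised-cosine lobes
spanning `qrs_duration_ms`, R amplitude 1100 µV) and a T wave built from
two half-bell limbs of widths `sigma_asc_ms` / `sigma_desc_ms`, each mixed
with a 1.6× wider "heavy shoulder" component weighted by `t_tail_weight`.
This minimal parameterization gives independent dials for ERD/LRD (limb
widths), amplitude, and flatness (shoulder weight).  Ground truth: T-peak
is the shape maximum; T-end follows the *tangent rule* evaluated on the
continuous descending limb (steepest tangent extended to baseline), so the
generator declares exactly the quantity the delineator measures.  QRS
onset/offset truth is the 0.5%-of-R-amplitude support edge.  Recordings
concatenate beats with lognormal RR jitter, add 40-Hz-low-passed noise, and
quantize at 2.5 µV — emulating clinical Holter-extracted 10-s ECGs at
500 Hz.  Three pseudo-orthogonal leads project a fixed unit-norm dipole, so
the vector-magnitude lead recovers the template exactly.

Baseline beat calibration: `sigma_asc = 32.2 ms` reproduces ERD30% ≈ 50 ms;
`sigma_desc = 24 ms`, `tail_weight = 0.06` give a plausible terminal T and
flatness ≈ 0.47; J-Tpeak is then solved so truth QT matches a 397 ms QTc at
the population RR of 0.988 s.  Two published baseline values are *not*
reproduced at the waveform level: LRD30% (≈38 vs 31 ms) and Tpeak–Tend
(≈49 vs 82 ms).  They cannot both hold for a tangent-rule T-end on a
unimodal descending limb with the 30%-of-peak convention — the tangent
intersection always lies closer to the peak, relative to the 30% crossing,
than those two numbers imply.  We prioritized QTc and ERD.  Consequently
waveform-level drug calibration matches the interval targets (J-Tpeak and
QT changes to < 0.5 ms, with Tpeak–Tend the additivity remainder ≈ 16 ms)
while morphology changes are directional rather than magnitude-calibrated.

**Biomarker-level generator.** Trial-scale statistical studies (interval
coverage, ROC ordering over ≥ 100 trials) would gain nothing from waveform
synthesis, so a second path draws each biomarker directly on the corrected
scale — subject baseline ~ Normal(published mean, published SD), plus
period effects, plus the linear concentration effects — and maps to the raw
scale through `raw = corrected · RR^α` with per-replicate measurement
scatter (QT 6 ms, J-Tpeak 7 ms, Tpeak–Tend 5 ms, flatness 0.035, asymmetry
0.06, ERD 6 ms, LRD 4.5 ms, amplitude 40 µV per 10-s ECG).  Each biomarker
is generated marginally: the published change table is not interval-additive
(ΔΔQTc ≠ ΔΔJ-Tpeakc + ΔΔTpeak–Tend after rate-correction factors), so a
jointly additive generator could not match every printed value; marginal
generation matches them all, at the cost of per-row interval additivity,
which is enforced only for waveform-derived measurements.

**What passing tests do and do not show.**  The generator produces
stationary, unimodal, single-morphology beats with drug effects exactly
linear in concentration and noise that is Gaussian after band-limiting.
Real ECGs have T-U fusion, notched and biphasic T waves, respiration and
electrode artifacts, hysteresis between RR and repolarization, and
non-linear exposure–response.  Passing the suite shows the *pipeline
mathematics* is right (estimators match oracles, corrections remove the
rate dependence they model, the classifier ordering follows from the
calibrated effect geometry); it does not validate the delineator or the
thresholds against clinical recordings.

## Delineation

The analysis lead is the per-sample L2 norm across leads ("vector
magnitude").  Recordings are polyphase-resampled to 1 kHz.  R peaks come
from smoothed slope energy (squared derivative integrated over 80 ms) with
a 200-ms refractory window — thresholding the raw envelope instead would
double-trigger on tall T waves.  The median beat takes the per-sample
median of R-aligned windows (−300 ms, +min(650 ms, 0.75·RR)); beats whose
neighboring RR deviates > 20% from the median RR are excluded, and at least
three usable beats are required.

Fiducials on the median beat: QRS onset/offset are the edges of the
contiguous region (gaps ≤ 24 ms bridged) where |dV/dt| exceeds 5% of its
QRS maximum, with sub-sample interpolation; the isoelectric baseline is the
median of the 60→10 ms window before onset; T-peak is the argmax of a
31-ms Savitzky-Golay-smoothed T search window with parabolic refinement
over ±15 ms; T-end is the tangent method — a line fitted over ±14 ms around
the steepest descending point, intersected with the baseline (a 5%-of-peak
threshold method is available via `tend_method="threshold"`).  T waves
below 30 µV are reported unmeasurable rather than guessed.  Window and
threshold defaults were tuned on the generator's noiseless beats and fixed;
at 20 dB SNR the median absolute single-beat error is ≈ 2 ms for both
T-peak and T-end, comfortably inside the 4/6-ms acceptance bounds.

Replicate ECGs within a time-point are aggregated by the median of their
biomarker values — consistent with the median-beat philosophy; the mean is
a one-line change if ever needed.

## Morphology definitions (documented surrogates)

The proprietary measurement software behind the published flatness and
asymmetry values is not specified, so concrete surrogates preserving the
biomarkers' *ordering behaviour* are used and exposed in config:

* flatness `F = 1 − κ^(−1/2)` with κ the kurtosis of the rectified,
  area-normalized T wave treated as a density (Gaussian profile → 0.423,
  inside the published healthy band 0.43 ± 0.05; heavier shoulders → larger
  F; within the generator F grows monotonically with `t_tail_weight` up to
  ≈ 0.22, which is why that is the admissible tail-weight cap);
* asymmetry `A = Σ|w(p+u) − w(p−u)| / Σ(w(p+u) + w(p−u))` over the
  symmetric overlap around the peak of the peak-normalized wave;
* ERD/LRD at level L: time from the last pre-peak (first post-peak)
  linear-interpolated crossing of `L × peak` to the peak.  "30%" is read as
  a threshold at 30% *of* peak amplitude; the level is a parameter, so the
  30%-below-peak convention is `level=0.70`;
* amplitude: the vector-magnitude value at T-peak;
* ventricular gradient: norm of the per-lead time integrals over
  QRS-onset→T-end (computed, excluded from classification).

## Heart-rate correction

`QTc = QT/RR^(1/3)` (Fridericia); other rate-dependent biomarkers use
`value/RR^α` with α = 0.50 (flatness), 0.96 (T-vector amplitude), 1.17
(ventricular gradient).  J-Tpeak uses α = 0.58, a value inherited from the
corrected interval's measurement lineage rather than fitted here; it is a
config entry precisely because it is a convention.  T-wave amplitude and
"maximum T-vector magnitude" are treated as the same quantity.

`fit_alpha` estimates α by `log(value) = subject-intercept + α·log(RR)`
with a random subject intercept (statsmodels MixedLM; an absorbed-fixed-
effects OLS fallback is exact on noiseless data and used when the mixed fit
degenerates), and tests a sex×log(RR) interaction at 0.05; only when
significant does the returned correction carry sex-specific exponents.  The
recovery benchmark draws baseline RR with lognormal spread σ≈0.29 (0.28
within subject, 0.08 between), i.e. a full ambulatory day spanning roughly
35–105 bpm: a population exponent is only identifiable from 63 rows with 5%
measurement noise if baseline sampling covers a wide physiologic RR range,
and that is precisely how population corrections are derived in practice.

## Exposure–response

ΔΔ: change from the period-specific pre-dose baseline, modelled as
`change ~ sequence + period + time + treatment + treatment×time` with a
subject random intercept (REML).  The reported contrast x(arm, t) −
x(placebo, t) cancels sequence and period terms, so it is invariant to
their coding; under a balanced design it equals the cell-means contrast
exactly, which the tests assert to 1e-9.  Noiseless inputs short-circuit to
the OLS fixed-effects path (REML is degenerate at zero residual variance).
Intervals are Wald ±1.96·SE from the fixed-effect covariance.

Concentration–response: `change ~ concentration` with correlated random
intercept and slope per subject; when the mixed fit fails the two-stage
estimator (mean of per-subject least-squares fits) is used, which the
balanced-design oracle requires anyway.  Signature curves evaluate the
model at 0.25/0.50/0.75/1.00 of the population Cmax with delta-method CIs
(simulation-based CIs would also be defensible; delta-method was chosen for
determinism and because the model is linear).  Mitigation: paired t-test of
observed combination responses vs the value predicted from the single-drug
model at each subject's measured concentration; Cohen's d uses paired
differences with left-closed label bands (|d| = 0.5 → "medium").

## Classification

Positive class: multichannel block.  Rows are subject-level time-matched
placebo-corrected changes pooled over afternoon/evening time-points for the
three-dose arms and morning/afternoon for moxifloxacin.  Logistic scores
come from an explicit IRLS (so the separation contract — warning with
capped iterations, never a crash — is under our control); AUC is the
Mann–Whitney rank statistic with ties counting one half; CIs are
2000-replicate stratified bootstrap percentiles; model comparison uses
DeLong's placement-value test.  The operating point reported is the one
maximizing sensitivity + specificity.

The fixed rule ships the published thresholds: ΔΔJ-Tpeakc > 9 ms → hERG;
else ΔΔQTc ≤ 29 ms → multichannel; else inconclusive (boundaries inclusive
toward the lower branch).  The learner is deliberately *not* a full C4.5:
depth ≤ 2, binary splits at observed-value midpoints maximizing gain ratio
with two C4.5 guards (candidates need at least the average positive
information gain, and each side at least 5% of the training rows —
without these the gain ratio reliably picks near-empty pathological
splits), majority leaves, an "inconclusive" label when leaf purity < 0.55
(near-ties only, approximating J48's majority labelling while keeping a
third class), and seeded stratified 10-fold CV.  Inconclusive predictions
count as errors by default (`exclude_inconclusive` recomputes on conclusive
rows); under that convention CV accuracies on realistically noisy synthetic
trials are moderate — an honest property of 21-subject data, not a defect
of the fixed rule, whose published thresholds are the canonical artifact.

## Reproducibility and problem sizes

Every stochastic stage draws from a root `SeedSequence` split per stage; a
pipeline run is byte-identical given (config, seed), and the manifest
records a hash of the scientific configuration (paths excluded).  The test
suite uses reduced problem sizes chosen to keep each statistical check
well-powered at desk scale: 500 simulations for exponent recovery, 200
trials for interval coverage, 1000 replicates for null uniformity, 100
calibrated trials for the biomarker-ranking properties, and 200 noisy beats
for delineation accuracy.

## Known limitations

* Single T-wave morphology: no notched/biphasic T disambiguation, no P-wave
  or PR analysis, no arrhythmia.
* Waveform-level morphology magnitudes (flatness, LRD, Tpeak–Tend absolute
  levels) are not calibrated to the published table; interval changes are.
* Population (not individualized) rate correction; no QT/RR hysteresis.
* Linear exposure–response only; no Emax or effect-compartment models.
* The learned tree is a two-feature threshold learner, not a complete C4.5
  with pruning and subtree raising.
* Waveform input is delimited text (+ JSON sidecar) only.
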