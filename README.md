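# ecgrepol

ECG repolarization biomarkers for detecting drug-induced late sodium
current block.

Drugs that block the hERG potassium channel prolong the heart-rate-corrected
QT interval (QTc) and are associated with torsade de pointes.  Drugs that
*also* block inward currents — in particular the late sodium current — can
prolong QTc while carrying low torsade risk, because the inward-current
block counteracts the early-repolarization effects of hERG block.  The
early repolarization subinterval J-Tpeakc (J point to T-wave peak,
heart-rate corrected) shortens under late sodium current block even while
QTc stays prolonged, which makes the pair (ΔΔJ-Tpeakc, ΔΔQTc) a practical
ECG readout of a drug's ion-channel profile.

`ecgrepol` implements the full analysis pipeline for this question and a
calibrated synthetic crossover trial to exercise it end to end:

1. **`synth`** — a five-period randomized crossover in 21 healthy subjects
   (8 female): a selective hERG blocker (dofetilide, moxifloxacin) given
   alone or combined with a late sodium-current blocker (mexiletine,
   lidocaine).  Waveform level: 10-s multi-lead ECGs at 500 Hz / 2.5 µV
   resolution built from a parametric beat model (biphasic QRS, two-half-bell
   T wave with a heavy-shoulder term) with per-beat ground-truth fiducials.
   Biomarker level: per-recording biomarker tables for trial-scale
   statistics.  Drug effects are linear in plasma concentration (one-
   compartment PK, three daily doses, Cmax ≈ 12.5–13 h after the first
   dose) and calibrated so the population placebo-corrected changes at Cmax
   match published clinical values (dofetilide ≈ +45 ms QTc / +29 ms
   J-Tpeakc; the combinations ≈ +17–18 ms QTc with J-Tpeakc pulled back to
   ≈ +1–4 ms).
2. **`delineate`** — resampling to 1 kHz, slope-energy R detection, a
   per-sample median beat, and fiducials on the vector-magnitude lead:
   derivative-threshold QRS onset/offset, parabolic-refined T peak, and
   tangent-method T end, so `QT = QRS + J-Tpeak + Tpeak-Tend` holds exactly.
3. **`morphology`** — T-wave flatness (kurtosis-based, `F = 1 − κ^(−1/2)`),
   mirror-difference asymmetry, amplitude, early/late repolarization
   durations at 30% of peak (ERD30%/LRD30%), and the ventricular gradient.
4. **`ratecorrect`** — Fridericia for QT (`QTc = QT/RR^(1/3)`) and the
   exponential model `biomarker_c = biomarker/RR^α` (α = 0.50 flatness,
   0.96 T-vector amplitude, 1.17 ventricular gradient, 0.58 J-Tpeak), plus
   estimation of α from baseline data with a sex-difference test.
5. **`exposure`** — placebo-corrected change from baseline (ΔΔ) via a
   crossover mixed model (sequence, period, time, treatment, treatment×time
   fixed effects; subject random intercept), per-subject random
   intercept+slope concentration-response models, ECG "signature" curves at
   25% increments of Cmax, paired-t mitigation tests and Cohen's d.
6. **`classify`** — logistic-regression ROC analysis (Mann–Whitney AUC,
   2000-replicate stratified bootstrap CIs, DeLong's paired test), the fixed
   decision rule (ΔΔJ-Tpeakc > 9 ms → hERG; else ΔΔQTc ≤ 29 ms →
   multichannel; else inconclusive), and a depth-2 gain-ratio threshold
   learner with stratified 10-fold CV.

## Worked example

```python
import numpy as np
from ecgrepol import synth, ratecorrect as rc, exposure as ex, classify as cl
from ecgrepol.pipeline import _classification_table

design = synth.TrialDesign(seed=7)          # 21 subjects, 5 arms, 3 replicates
table = synth.simulate_biomarker_trial(design)
corrected = rc.correct_table(table)
changes = ex.changes_from_baseline(corrected, ["qtc_ms", "jtpeakc_ms"])

for biomarker in ("qtc_ms", "jtpeakc_ms"):
    for est in ex.delta_delta(changes, biomarker):
        if est.timepoint == 13.0 and est.arm in ("dofetilide", "mexiletine+dofetilide"):
            print(f"ddelta {biomarker:11s} {est.arm:22s} "
                  f"{est.estimate:6.1f} [{est.ci95_low:.1f}, {est.ci95_high:.1f}]")

feats = _classification_table(corrected)
labels = feats["label"].to_numpy()
for name, cols in (("J-Tpeakc", ["jtpeakc_ms"]), ("QTc", ["qtc_ms"])):
    m = cl.logistic_fit(feats[cols].to_numpy(), labels, tuple(cols))
    r = cl.roc_auc(m.predict_proba(feats[cols].to_numpy()), labels)
    print(f"AUC({name:8s}) = {r.auc:.2f}")
print("tree_classify(29.1, 45.2) ->", cl.tree_classify(29.1, 45.2))
print("tree_classify(1.1, 17.3)  ->", cl.tree_classify(1.1, 17.3))
```

prints (seed 7):

```
ddelta qtc_ms      dofetilide               35.9 [31.0, 40.9]
ddelta qtc_ms      mexiletine+dofetilide    12.7 [7.7, 17.6]
ddelta jtpeakc_ms  dofetilide               22.3 [17.7, 26.8]
ddelta jtpeakc_ms  mexiletine+dofetilide    -0.4 [-5.0, 4.1]
AUC(J-Tpeakc) = 0.81
AUC(QTc     ) = 0.66
tree_classify(29.1, 45.2) -> hERG
tree_classify(1.1, 17.3)  -> multichannel
```

Reading this: in one simulated trial the hERG blocker alone prolongs both
QTc (+36 ms) and J-Tpeakc (+22 ms); adding the late sodium-current blocker
leaves residual QTc prolongation (+13 ms) but abolishes the J-Tpeakc change
(−0.4 ms).  Pooled subject-level rows separate the two mechanisms better on
J-Tpeakc (AUC 0.81) than on QTc (AUC 0.66), and the fixed two-threshold
rule classifies the population-mean change pairs accordingly.  Estimates
fluctuate from trial to trial exactly as a 21-subject study does — rerun
with another seed to see it.

The same analysis runs end to end from raw synthetic waveforms through
delineation:

```sh
ecgrepol run-all --seed 1 --out-dir out/           # full waveform pipeline
ecgrepol tree-apply --ddjtpeakc 4.1 --ddqtc 17.9   # -> multichannel
```

`run-all` persists every intermediate (biomarker, corrected, change and ΔΔ
tables; classification results; a manifest with a config hash) and is
byte-identical across reruns with the same seed.

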