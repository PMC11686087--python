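# pwavekit

Measurement and analysis of P-wave parameters on 12-lead ECGs, for studies
that relate atrial electrical remodelling to catheter-ablation outcomes in
paroxysmal atrial fibrillation.

The P wave is the ECG deflection of atrial depolarization. After pulmonary
vein isolation (PVI), changes in P-wave parameters can reflect residual or
iatrogenic conduction abnormality and predict recurrence. `pwavekit`
implements the full measurement chain and the accompanying cohort
statistics:

* **Delineation** — per beat and per lead, the P-wave peak is the largest
  baseline excursion at least 15 ms wide; the onset is found by the chord
  ("trapezium"/knee) rule on the segment from the T-wave end to the P
  peak, refined to the first point of rise above the isoelectric line; the
  offset is the return to within 5% of the P amplitude of baseline, with a
  deep opposite-polarity terminal lobe (the biphasic P in V1) extending
  the wave. Twenty consecutive beats are averaged.
* **Parameters** — per patient-stage:
  - PWDc = PWD + 1.75 × (HR − 60) (Hodges heart-rate correction, ms),
  - PWA = max |amplitude| from the isoelectric line across leads (mV),
  - PWDisp = max − min PWD across leads (ms),
  - PTFV1 = −|terminal negative amplitude in V1 (mm)| × duration (s),
    in mm·s at the standard 0.1 mV/mm calibration.
* **Cohort statistics** — paired pre/post tests (t or Wilcoxon by a
  Shapiro–Wilk gate), failure-vs-success change comparison, Cox
  proportional-hazards with the univariable-screen rule (univariable
  p < 0.05 admits a covariate to the single multivariable model),
  intraobserver variability, and post hoc two-sample power.
* **Synthetic data** — a 12-lead ECG generator with analytically known
  fiducials (half-sine P/QRS/T pulses, biphasic V1, noise, baseline
  wander, 16-bit quantisation) and a cohort generator with
  group-conditional pre/post parameter distributions and an exponential
  proportional-hazards event process, so every stage is testable without
  patient data.

## Worked example

```python
from pwavekit import (SynthEcgSpec, generate_ecg, preprocess,
                      compute_parameter_set, CohortAnalysis,
                      SynthCohortSpec, generate_cohort)

# one synthetic patient-stage ECG, measured end to end
record, truth = generate_ecg(SynthEcgSpec(duration_s=23.0, seed=1))
ps = compute_parameter_set(preprocess(record))
print(f"PWDc={ps.pwdc_ms:.1f} ms  PWA={ps.pwa_mv:.3f} mV  "
      f"PWDisp={ps.pwdisp_ms:.1f} ms  PTFV1={ps.ptfv1_mm_s:.3f} mm.s")
# PWDc=136.8 ms  PWA=0.171 mV  PWDisp=26.6 ms  PTFV1=-0.026 mm.s

# a study-sized cohort (130 successful / 50 failed ablations)
cohort = generate_cohort(SynthCohortSpec(seed=1))
res = CohortAnalysis.from_dataframe(
    cohort, covariates=["pwdc_change_z", "pwa_change_z", "age_years"]
).fit()
print(res.summary())
```

The measured PWDc is the across-lead maximum P duration corrected to a
60 bpm reference; PWDisp reflects the generator's built-in cross-lead
duration spread; the negative PTFV1 is the terminal force of the biphasic
V1 P wave. In the cohort analysis, the failure arm shows a mean PWDc
increase near +7 ms (its generating distributions move from 139 to
146 ms), the success arm is flat, and the standardized PWDc/PWA changes
carry hazard ratios near e^0.9 ≈ 2.5 and e^0.5 ≈ 1.6 in the
multivariable Cox model, while null covariates are screened out.

A command-line interface wraps the same stages:

```bash
pwave simulate --out ecg.csv --seed 1 --duration 23
pwave parameters ecg.csv --out params.csv
pwave simulate --kind cohort --out cohort.csv --seed 1
pwave analyze cohort.csv --out cox.csv
pwave run --out runs/demo --seed 1
```

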