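# Methods

This note documents the models, rules, and numerical choices behind
`pwavekit`, and what the synthetic-data validation does and does not
establish about real ECGs.

## Signal model of the synthetic ECG

Each beat is the sum of three analytic pulses on a zero baseline:

* a **QRS** half-sine, 50 ms wide, centred on the R peak (amplitude
  pattern across leads scaled by `qrs_amplitude_mv`, default 1.0 mV;
  negative in aVR and V1);
* a **T wave** half-sine from 130 to 260 ms after the R peak
  (`t_amplitude_mv`, default 0.30 mV);
* a **P wave** ending 90 ms before the *next* R peak. A monophasic P is a
  single half-sine of the configured duration and signed amplitude
  (inverted in aVR). The V1 P is biphasic: a positive half-sine followed
  by a negative one whose share of the total duration is
  `biphasic_fraction` (default 0.4) and whose depth is
  `negative_amplitude_mv` (default 0.05 mV — ~0.5 mm, which puts the
  default terminal force near the classical 0.03 mm·s abnormality
  threshold).

The half-sine was chosen over flatter unimodal templates (raised cosine,
truncated Gaussian) because its non-zero flank slope makes the analytic
onset/offset well-defined at the sample level: the chord knee and the
baseline-return crossing both sit within ~1 sample of the support edge,
so ground truth is unambiguous. Ground-truth fiducials are computed
analytically (first sample at/after the wave's departure from baseline,
last sample at/before its return) and are exact to half a sample.

Defaults for the stochastic components: white noise SD 0.01 mV, baseline
wander 0.05 mV at 0.3 Hz, and quantisation to the 16-bit step of a 10 mV
input range. Per-lead P amplitudes follow a fixed physiological pattern
(largest in II, inverted in aVR), and per-lead P durations carry a fixed
offset pattern with a 32 ms spread so that dispersion is non-degenerate —
on the scale of the 31–38 ms dispersion values the measurement targets.
Heart rate is constant within a record; respiratory RR modulation,
ectopy, and AF episodes themselves are out of scope. Timing constants
(QRS width, T window, PQ gap) are fixed rather than rate-adaptive, which
is adequate for 50–110 bpm.

**What passing tests show / do not show.** Recovery of parameters from
these records validates the geometry of the delineation rules and the
arithmetic of the parameter definitions against known truth. It does not
certify accuracy on real ECGs, whose P waves have rounder feet, variable
morphology, and muscle-artifact noise; on such data the manual-override
table exists for a reason.

## Pre-processing

A mains notch (default 50 Hz, Q = 30) followed by a 4th-order Butterworth
band-pass at 1–50 Hz, both applied forward-backward (`filtfilt`) so the
chain is zero-phase and fiducial latencies are unbiased. The 1 Hz
high-pass necessarily removes each wave's DC content, leaving a shallow
(~5% of amplitude) symmetric undershoot around every deflection and a
slow sag near the large QRS; the delineation stage is designed around
this (below). On noise-free sharp-flanked synthetic waves the full
filtered chain widens the measured PWD by roughly 1–2 samples at 500 Hz;
the delineator alone, on unfiltered noise-free records, is accurate to
within 2 ms across 80–160 ms durations and 50–110 bpm.

## Delineation rules

Each RR interval of each lead is processed independently:

1. **R peaks**: dominant absolute excursions from the median level with a
   200 ms refractory period.
2. **T-wave end**: tangent method — the steepest point of the T terminal
   limb, extrapolated to the isoelectric level. The T-peak search is
   capped at 0.42 RR after the R peak so the next P wave never enters the
   T window at high rates.
3. **Per-beat isoelectric line**: a straight line through two anchor
   medians, one just after the T end (TP segment, 8–28 ms) and one just
   before the QRS (PR segment, 55–85 ms before R). The beat is measured
   on the detrended signal. A linear per-beat baseline tracks both slow
   wander and the residual filter sag; the chord onset rule is invariant
   to any linear detrend, so this only affects thresholds and
   amplitudes.
4. **P peak**: the largest |deviation| whose width (at half prominence)
   is ≥ 15 ms, which rejects narrow noise spikes regardless of height.
5. **P onset**: the knee of the chord — the sample with maximal
   perpendicular distance to the straight line joining the signal at the
   chord anchor and at the P peak, ties toward the earlier sample. The
   literal minimal-distance reading is available
   (`chord_min_distance_literal`) but is degenerate in principle (the
   chord's own endpoints have distance zero), so the knee variant is the
   default. The anchor is the T end, pulled forward to at most 120 ms
   before the peak (`max_onset_chord_ms`): atrial depolarization bounds
   the onset-to-peak interval, and anchoring a chord several hundred ms
   away on a slow-rate diastole makes the knee sensitive to ~0.01 mV
   baseline ripple. The knee is then refined to the first point of rise
   above the isoelectric line, which lifts it out of the shallow
   undershoot dip the band-pass leaves just before the wave.
6. **P offset**: first sample after the peak where the deviation toward
   the peak's polarity falls below 5% of the P amplitude
   (`offset_threshold_frac`) and stays there ≥ 10 ms. A subsequent
   opposite-polarity lobe deeper than 25% of the amplitude
   (`terminal_phase_frac`) is a true terminal phase — the biphasic V1
   P — and moves the offset to that lobe's own baseline return; shallower
   opposite excursions are filter undershoot and do not extend the wave.
   If the signal never settles before the QRS onset the offset is clamped
   there and the beat flagged. Threshold decisions use a centred 10 ms
   moving average for noise robustness; a mirrored-chord variant exists.
   The 5% threshold (rather than, say, 10%) keeps the crossing within
   ~1 sample of the analytic support edge for smooth unimodal waves.
7. **Negative phase (V1)**: longest below-baseline run between the P peak
   and offset; its duration and trough feed the terminal force.
8. **Averaging**: the first run of 20 consecutive measurable beats per
   lead; heart rate is 60 000 / mean RR (ms) of the averaged beats.
   Unmeasurable beats break runs; fewer than 20 consecutive measurable
   beats is an error naming the lead and shortfall. Manual adjustment is
   supported as an override table of fiducial indices, not a GUI.

## Parameters

* **PWDc** (ms): per-patient PWD is the across-lead maximum (the P-max
  convention that pairs with dispersion; a mean rule is available), then
  Hodges-corrected, PWDc = PWD + 1.75 × (HR − 60). The correction is
  linear by construction: identity at 60 bpm, strictly increasing in
  rate.
* **PWA** (mV): maximum absolute deviation of the P peak from the
  isoelectric line across leads. Reported in record units; clinical
  display conventions that report an order of magnitude larger are a
  scale choice, not a different quantity.
* **PWDisp** (ms): max − min PWD across measurable leads (≥ 2 required).
* **PTFV1** (mm·s, ≤ 0): −(|terminal negative amplitude| at 0.1 mV/mm) ×
  (terminal duration in s), zero for a monophasic positive V1 P. The unit
  scale is configurable; only sign and ordering are comparable across
  display conventions.

## Synthetic cohorts and the statistics stage

Each patient belongs to a *designed* group (success or failure) that
fixes the group-conditional normal distributions of the four parameters
pre and post ablation (defaults: PWDc 132→132 vs 139→146 ms; PWA
1.6→1.8 vs 1.6→2.0 mV; PWDisp 31→32 vs 36→38 ms; PTFV1 −3.4→−4.6 vs
−3.4→−5.4 mm·s, SD 1.0 where no spread is reported). Pre and post draws
correlate at 0.8 within patient while keeping the stated marginals, so
within-group changes have realistic repeated-measures structure.

Recurrence is an exponential proportional-hazards process on the
standardized PWDc and PWA changes (default log-HRs 0.9 and 0.5, the
logs of multivariable hazard ratios 2.5 and 1.7). The clock starts at
the end of the 3-month blanking window — countable recurrence hazard is
zero during blanking, exactly mirroring a failure definition that
ignores blanking-period events — and censoring is administrative at 12
months. Because the Cox baseline hazard is unrestricted, this delayed
clock keeps the covariate effects exactly proportional, so
coefficient-recovery tests are well-posed. The default baseline hazard,
0.027 events/month, makes the expected event fraction equal 50/180, the
study-sized failure share; with the default design the realized event
count averages ≈ 50 of 180. Baseline covariates (age, sex,
hypertension, diabetes, BMI, LVEF, indexed LA volume, ablation modality)
are drawn from study-scale distributions and carry no hazard effect, so
they double as screen-calibration nulls.

Statistical rules: Shapiro–Wilk at α = 0.05 gates t-tests vs rank tests;
the between-arm difference is reported as failure − success; the Cox
univariable screen admits covariates at p < 0.05 (configurable) to one
multivariable model; ties use Efron's method (appropriate for coarse
visit-binned event times); degenerate paired comparisons (all changes
identical) are flagged rather than tested. Intraobserver variability is
the mean ± SD of absolute pass-to-pass differences with percent relative
to the grand mean magnitude. Post hoc power uses the noncentral-t
two-sample formulation.

## Problem sizes used in validation

The validation suite uses 22-second records (≥ 21 beats at 60 bpm, the
shortest record that supports a 20-beat average), a 3 × 3 recovery grid
over {100, 120, 140} ms × {60, 75, 90} bpm, 100 synthetic beats for the
onset-oracle comparison, 1000 replicates for test calibration, and 100
study-sized cohorts for Cox coverage. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances.

## Known limitations

* The delineator assumes sinus rhythm with one P per RR interval; it has
  no arrhythmia handling.
* Fixed beat-timing constants are tuned to 50–110 bpm; far outside that
  range the T window and PQ gap assumptions degrade.
* The chord onset rule's literal "minimum distance" reading and the
  exact chord anchors are under-determined in the measurement tradition
  it follows; both variants are implemented and the default is the only
  non-degenerate one.
* PTFV1 magnitudes depend on a display-unit convention; cross-study
  comparisons should rely on sign and ordering.
* The cohort generator's designed group and realized outcome coincide
  only on average; analyses of group change use the designed label, event
  analyses use the realized process.
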