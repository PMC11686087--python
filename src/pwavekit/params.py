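"""P-wave parameters: heart-rate-corrected duration, amplitude, dispersion,
and terminal force in V1.

Conventions
-----------
* PWD is corrected to 60 bpm by the Hodges linear rule,
  ``PWDc = PWD + 1.75 * (HR - 60)`` (same form as its QT use).
* The per-patient PWD and PWA scalars are by default the maximum across
  measurable leads (the P-max convention that pairs naturally with
  dispersion); a mean rule is available.
* PWDisp is max - min PWD across measurable leads.
* PTFV1 is the product of the absolute amplitude (in mm at the standard
  ECG gain of 0.1 mV/mm) and duration (in s) of the terminal negative
  phase of the P wave in V1, reported negative by convention; a monophasic
  positive P in V1 gives 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .delineate import (
    DelineationConfig,
    LeadMeasurement,
    average_measurements,
    delineate_record,
)
from .ecg import ECGRecord

#: Hodges heart-rate correction slope, ms per bpm away from 60.
HODGES_SLOPE_MS_PER_BPM = 1.75
#: Standard ECG calibration: 1 mm of paper = 0.1 mV.
MM_PER_MV = 10.0


@dataclass(frozen=True)
class ParameterSet:
    """One patient-stage summary of the four P-wave parameters."""

    pwdc_ms: float
    pwa_mv: float
    pwdisp_ms: float
    ptfv1_mm_s: float
    heart_rate_bpm: float
    stage: str = "pre"
    leads_used: int = 12


def correct_pwd_hodges(pwd_ms: float, heart_rate_bpm: float) -> float:
    """Correct a P-wave duration to a 60 bpm reference heart rate."""
    if pwd_ms <= 0:
        raise ValueError("pwd_ms must be > 0")
    if not (20 < heart_rate_bpm < 250):
        raise ValueError(f"non-physiological heart rate: {heart_rate_bpm} bpm")
    return pwd_ms + HODGES_SLOPE_MS_PER_BPM * (heart_rate_bpm - 60.0)


def summarize_pwd(pwd_by_lead: Mapping[str, float], rule: str = "max") -> float:
    """Collapse per-lead PWDs to the per-patient scalar (P-max by default)."""
    vals = [v for v in pwd_by_lead.values() if np.isfinite(v)]
    if not vals:
        raise ValueError("no measurable leads")
    if rule == "max":
        return float(max(vals))
    if rule == "mean":
        return float(np.mean(vals))
    raise ValueError(f"unknown PWD summary rule: {rule!r}")


def compute_pwa(pwa_by_lead: Mapping[str, float], rule: str = "max_abs") -> float:
    """Per-patient P amplitude: largest absolute excursion across leads (mV)."""
    vals = [v for v in pwa_by_lead.values() if np.isfinite(v)]
    if not vals:
        raise ValueError("no measurable leads")
    if rule == "max_abs":
        return float(max(abs(v) for v in vals))
    if rule == "mean_abs":
        return float(np.mean([abs(v) for v in vals]))
    raise ValueError(f"unknown PWA rule: {rule!r}")


def compute_pwdisp(pwd_by_lead: Mapping[str, float]) -> float:
    """P-wave dispersion: max minus min PWD across measurable leads (ms)."""
    vals = [v for v in pwd_by_lead.values() if np.isfinite(v)]
    if len(vals) < 2:
        raise ValueError("dispersion needs at least 2 measurable leads")
    return float(max(vals) - min(vals))


def compute_ptfv1(
    neg_peak_mv: float, neg_duration_ms: float, scale: float = 1.0
) -> float:
    """Terminal force in V1 (mm*s, signed negative).

    ``neg_peak_mv`` is the signed trough of the terminal negative phase
    (<= 0); ``neg_duration_ms`` its duration. Zero when there is no
    negative phase.
    """
    if neg_duration_ms < 0:
        raise ValueError("neg_duration_ms must be >= 0")
    if neg_duration_ms == 0 or neg_peak_mv >= 0:
        return 0.0
    amp_mm = abs(neg_peak_mv) * MM_PER_MV
    return -amp_mm * (neg_duration_ms / 1000.0) * scale


def compute_parameter_set(
    record: ECGRecord,
    config: DelineationConfig | None = None,
    stage: str = "pre",
    pwd_rule: str = "max",
    pwa_rule: str = "max_abs",
    ptfv1_scale: float = 1.0,
    measurements: Mapping[str, LeadMeasurement] | None = None,
) -> ParameterSet:
    """Run delineation + averaging on a record and assemble the parameters.

    ``measurements`` may be supplied to skip the delineation (e.g. after a
    manual-override pass). Heart rate for the Hodges correction is the
    mean over leads of the averaged-beat heart rate.
    """
    config = config or DelineationConfig()
    if measurements is None:
        beats = delineate_record(record, config)
        measurements = average_measurements(
            beats, config.n_beats, record.sampling_rate_hz
        )
    if len(measurements) < 2:
        raise ValueError("need at least 2 measurable leads")
    pwd_by_lead = {l: m.pwd_ms for l, m in measurements.items()}
    pwa_by_lead = {l: m.pwa_mv for l, m in measurements.items()}
    hr = float(np.mean([m.heart_rate_bpm for m in measurements.values()]))
    pwd = summarize_pwd(pwd_by_lead, pwd_rule)
    if "V1" not in measurements:
        raise ValueError("lead V1 is required for the terminal force")
    v1 = measurements["V1"]
    return ParameterSet(
        pwdc_ms=correct_pwd_hodges(pwd, hr),
        pwa_mv=compute_pwa(pwa_by_lead, pwa_rule),
        pwdisp_ms=compute_pwdisp(pwd_by_lead),
        ptfv1_mm_s=compute_ptfv1(v1.neg_peak_mv, v1.neg_duration_ms, ptfv1_scale),
        heart_rate_bpm=hr,
        stage=stage,
        leads_used=len(measurements),
    )
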