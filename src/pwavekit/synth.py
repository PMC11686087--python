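"""Synthetic 12-lead ECGs with known fiducials, and synthetic ablation cohorts.

The ECG generator builds each beat from three analytic pulses — a narrow QRS
complex, a T wave, and a P wave placed ahead of the following QRS — so that
the exact sample support of every P wave is known and can serve as ground
truth for the delineation stage. The cohort generator draws pre/post
parameter sets from group-conditional normal distributions and event times
from an exponential proportional-hazards law, so that the statistics stage
can be validated against known truth.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
spec with the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ecg import ECGRecord, STANDARD_LEADS

# ---------------------------------------------------------------------------
# Beat geometry (ms, relative to the R peak of each beat)
# ---------------------------------------------------------------------------
QRS_WIDTH_MS = 50.0          # half-sine QRS, centred on the R peak
T_START_MS = 130.0           # T wave begins this long after the R peak
T_DURATION_MS = 130.0        # T wave support
PQ_GAP_MS = 90.0             # P wave ends this long before the next R peak
#: Margin required between the end of one beat's T wave and the next P onset.
T_TO_P_MARGIN_MS = 5.0

#: Fixed physiological amplitude pattern per lead (multiplies the base
#: amplitude). Cross-lead variation keeps PWA and PWDisp non-degenerate.
P_AMPLITUDE_PATTERN: dict[str, float] = {
    "I": 0.70, "II": 1.00, "III": 0.50, "aVR": -0.90, "aVL": 0.35,
    "aVF": 0.80, "V1": 0.60, "V2": 0.90, "V3": 0.85, "V4": 0.75,
    "V5": 0.65, "V6": 0.55,
}
QRS_AMPLITUDE_PATTERN: dict[str, float] = {
    "I": 0.80, "II": 1.00, "III": 0.60, "aVR": -0.90, "aVL": 0.40,
    "aVF": 0.90, "V1": -0.70, "V2": 0.90, "V3": 1.10, "V4": 1.20,
    "V5": 1.00, "V6": 0.80,
}
T_AMPLITUDE_PATTERN: dict[str, float] = {
    "I": 0.80, "II": 1.00, "III": 0.40, "aVR": -0.80, "aVL": 0.30,
    "aVF": 0.70, "V1": 0.30, "V2": 0.90, "V3": 1.00, "V4": 0.90,
    "V5": 0.80, "V6": 0.60,
}
#: Fixed per-lead P-duration offsets (ms) around the base duration. The
#: spread (max - min = 32 ms) is on the scale of the dispersion values the
#: measurement targets, so PWDisp is non-degenerate by default.
P_DURATION_OFFSET_PATTERN_MS: dict[str, float] = {
    "I": 0.0, "II": 12.0, "III": -12.0, "aVR": -6.0, "aVL": -18.0,
    "aVF": 6.0, "V1": -10.0, "V2": 8.0, "V3": 14.0, "V4": 2.0,
    "V5": -4.0, "V6": -14.0,
}

#: 16-bit quantisation step for a 10 mV input range.
ADC_LSB_MV = 10.0 / 65536.0


@dataclass(frozen=True)
class LeadPWaveSpec:
    """P-wave shape for one lead.

    A monophasic P is a half-sine lobe of the given duration and peak
    amplitude (signed; negative gives an inverted P as in aVR). A biphasic P
    (``biphasic_fraction > 0``, V1 only) is a positive half-sine lobe
    followed by a negative one; the fraction gives the share of the total
    duration occupied by the negative (terminal) phase.
    """

    duration_ms: float = 120.0
    amplitude_mv: float = 0.15
    biphasic_fraction: float = 0.0
    negative_amplitude_mv: float = 0.05

    def validate(self, lead: str) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"{lead}: duration_ms must be > 0")
        if not (0.0 <= self.biphasic_fraction < 1.0):
            raise ValueError(f"{lead}: biphasic_fraction must be in [0, 1)")
        if self.biphasic_fraction > 0 and lead != "V1":
            raise ValueError(
                f"{lead}: biphasic_fraction is only supported on V1"
            )
        if self.negative_amplitude_mv < 0:
            raise ValueError(f"{lead}: negative_amplitude_mv must be >= 0")


def default_p_specs(
    duration_ms: float = 120.0,
    amplitude_mv: float = 0.15,
    duration_spread: float = 1.0,
    v1_biphasic_fraction: float = 0.4,
    v1_negative_amplitude_mv: float = 0.05,
) -> dict[str, LeadPWaveSpec]:
    """Build the per-lead P specs from the fixed physiological patterns.

    ``duration_spread`` scales the per-lead duration offsets; 0 gives a
    uniform duration in every lead (useful for controlled recovery tests).
    """
    specs = {}
    for lead in STANDARD_LEADS:
        d = duration_ms + duration_spread * P_DURATION_OFFSET_PATTERN_MS[lead]
        a = amplitude_mv * P_AMPLITUDE_PATTERN[lead]
        if lead == "V1":
            specs[lead] = LeadPWaveSpec(
                duration_ms=d,
                amplitude_mv=abs(a),
                biphasic_fraction=v1_biphasic_fraction,
                negative_amplitude_mv=v1_negative_amplitude_mv,
            )
        else:
            specs[lead] = LeadPWaveSpec(duration_ms=d, amplitude_mv=a)
    return specs


@dataclass
class SynthEcgSpec:
    """Specification of one synthetic 12-lead ECG."""

    heart_rate_bpm: float = 60.0
    duration_s: float = 30.0
    sampling_rate_hz: float = 500.0
    p_waves: Mapping[str, LeadPWaveSpec] = field(default_factory=default_p_specs)
    qrs_amplitude_mv: float = 1.0
    t_amplitude_mv: float = 0.30
    noise_sd_mv: float = 0.01
    baseline_wander_amplitude_mv: float = 0.05
    baseline_wander_freq_hz: float = 0.30
    quantize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (20 < self.heart_rate_bpm < 250):
            raise ValueError("heart_rate_bpm must lie in (20, 250)")
        if self.sampling_rate_hz < 250:
            raise ValueError("sampling_rate_hz must be >= 250")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")
        if self.baseline_wander_amplitude_mv < 0:
            raise ValueError("baseline_wander_amplitude_mv must be >= 0")
        if set(self.p_waves) != set(STANDARD_LEADS):
            raise ValueError("p_waves must specify exactly the 12 standard leads")
        rr_ms = 60000.0 / self.heart_rate_bpm
        budget = rr_ms - PQ_GAP_MS - (T_START_MS + T_DURATION_MS) - T_TO_P_MARGIN_MS
        for lead, p in self.p_waves.items():
            p.validate(lead)
            if p.duration_ms > budget:
                raise ValueError(
                    f"p_waves[{lead}].duration_ms={p.duration_ms:g} does not fit "
                    f"the PR interval implied by {self.heart_rate_bpm:g} bpm "
                    f"(max {budget:g} ms)"
                )


def _half_sine(t: np.ndarray, t0: float, duration_s: float, amp: float) -> np.ndarray:
    """Half-sine lobe supported on the open interval (t0, t0 + duration)."""
    phase = (t - t0) / duration_s
    y = np.zeros_like(t)
    m = (phase > 0.0) & (phase < 1.0)
    y[m] = amp * np.sin(np.pi * phase[m])
    return y


def _p_wave(t: np.ndarray, t_end: float, spec: LeadPWaveSpec) -> np.ndarray:
    """P pulse ending at ``t_end`` seconds; biphasic if the spec says so."""
    d = spec.duration_ms / 1000.0
    t0 = t_end - d
    if spec.biphasic_fraction <= 0:
        return _half_sine(t, t0, d, spec.amplitude_mv)
    d_neg = d * spec.biphasic_fraction
    d_pos = d - d_neg
    pos = _half_sine(t, t0, d_pos, spec.amplitude_mv)
    neg = _half_sine(t, t0 + d_pos, d_neg, -spec.negative_amplitude_mv)
    return pos + neg


def generate_ecg(spec: SynthEcgSpec) -> tuple[ECGRecord, pd.DataFrame]:
    """Generate one 12-lead ECG and the ground-truth fiducials of every P wave.

    Returns
    -------
    record
        The synthetic :class:`~pwavekit.ecg.ECGRecord` (noise, baseline
        wander and 16-bit quantisation applied).
    truth
        One row per (lead, beat) with the analytic fiducials, in samples:
        ``prev_r_index``/``r_index`` bracket the RR interval containing the
        P wave, ``t_end_index`` is the last supported sample of the previous
        T wave, ``p_onset_index``/``p_peak_index``/``p_offset_index`` are the
        first supported, maximal, and last supported samples of the clean P
        template, and ``neg_start_index``/``neg_end_index`` bound the
        negative phase (-1 when monophasic). ``beat`` indexes the R peak
        that follows the P wave.
    """
    spec.validate()
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    rr = 60.0 / spec.heart_rate_bpm

    # R peak times: first beat at 0.5 s, last one fully inside the record.
    r_times = []
    k = 0
    while True:
        rt = 0.5 + k * rr
        if rt + QRS_WIDTH_MS / 2000.0 >= spec.duration_s:
            break
        r_times.append(rt)
        k += 1
    if len(r_times) < 2:
        raise ValueError("duration_s too short for two beats at this heart rate")
    r_times = np.asarray(r_times)
    r_indices = np.round(r_times * fs).astype(int)

    rng = np.random.default_rng(spec.seed)
    data = np.zeros((len(STANDARD_LEADS), n))
    rows = []
    for li, lead in enumerate(STANDARD_LEADS):
        clean = np.zeros(n)
        qrs_amp = spec.qrs_amplitude_mv * QRS_AMPLITUDE_PATTERN[lead]
        t_amp = spec.t_amplitude_mv * T_AMPLITUDE_PATTERN[lead]
        p_spec = spec.p_waves[lead]
        t_end_time: dict[int, float] = {}
        for bi, rt in enumerate(r_times):
            clean += _half_sine(t, rt - QRS_WIDTH_MS / 2000.0, QRS_WIDTH_MS / 1000.0, qrs_amp)
            t_start = rt + T_START_MS / 1000.0
            t_end = t_start + T_DURATION_MS / 1000.0
            if t_end < spec.duration_s:
                clean += _half_sine(t, t_start, T_DURATION_MS / 1000.0, t_amp)
                t_end_time[bi] = t_end
        # Analytic fiducials: onset is the first sample at/after the wave's
        # departure from baseline, offset the last sample at/before its
        # return; both are within half a sample of the continuous truth.
        for bi in range(1, len(r_times)):
            if bi - 1 not in t_end_time:
                continue
            p_end = r_times[bi] - PQ_GAP_MS / 1000.0
            d = p_spec.duration_ms / 1000.0
            p_start = p_end - d
            clean += _p_wave(t, p_end, p_spec)
            onset = int(np.ceil(p_start * fs - 1e-9))
            offset = int(np.floor(p_end * fs + 1e-9))
            if onset < 0 or offset >= n:
                continue
            if p_spec.biphasic_fraction > 0:
                d_neg = d * p_spec.biphasic_fraction
                peak = int(round((p_start + (d - d_neg) / 2.0) * fs))
                neg_start = int(np.ceil((p_end - d_neg) * fs - 1e-9))
                neg_end = offset
            else:
                peak = int(round((p_start + d / 2.0) * fs))
                neg_start = neg_end = -1
            rows.append(
                dict(
                    lead=lead,
                    beat=bi,
                    prev_r_index=int(r_indices[bi - 1]),
                    r_index=int(r_indices[bi]),
                    t_end_index=int(np.floor(t_end_time[bi - 1] * fs + 1e-9)),
                    p_onset_index=onset,
                    p_peak_index=peak,
                    p_offset_index=offset,
                    neg_start_index=neg_start,
                    neg_end_index=neg_end,
                )
            )
        sig = clean.copy()
        if spec.baseline_wander_amplitude_mv > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig += spec.baseline_wander_amplitude_mv * np.sin(
                2 * np.pi * spec.baseline_wander_freq_hz * t + phase
            )
        else:
            rng.uniform(0, 2 * np.pi)  # keep the stream aligned across settings
        if spec.noise_sd_mv > 0:
            sig += rng.normal(0.0, spec.noise_sd_mv, n)
        if spec.quantize:
            sig = np.round(sig / ADC_LSB_MV) * ADC_LSB_MV
        data[li] = sig

    record = ECGRecord(STANDARD_LEADS, fs, data, source_id=f"synth(seed={spec.seed})")
    truth = pd.DataFrame(rows)
    return record, truth


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

#: (pre_mean, pre_sd, post_mean, post_sd) per parameter per designed group.
#: PWDc/PWA/PWDisp defaults follow the study-size group summaries
#: (success n=130, failure n=50); the PTFV1 spread is a plausible choice on
#: the same display scale since only the group means are reported.
DEFAULT_PARAM_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "pwdc_ms": {
        "success": (132.0, 12.0, 132.0, 11.0),
        "failure": (139.0, 10.0, 146.0, 9.0),
    },
    "pwa_mv": {
        "success": (1.6, 0.03, 1.8, 0.04),
        "failure": (1.6, 0.04, 2.0, 0.10),
    },
    "pwdisp_ms": {
        "success": (31.0, 0.5, 32.0, 0.5),
        "failure": (36.0, 0.8, 38.0, 0.8),
    },
    "ptfv1_mm_s": {
        "success": (-3.4, 1.0, -4.6, 1.0),
        "failure": (-3.4, 1.0, -5.4, 1.0),
    },
}

#: Null baseline covariates: name -> ("normal", mean, sd) or ("bernoulli", p).
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age_years": ("normal", 60.0, 10.0),
    "male": ("bernoulli", 0.71),
    "hypertension": ("bernoulli", 0.36),
    "diabetes": ("bernoulli", 0.11),
    "bmi": ("normal", 22.2, 3.1),
    "lvef_percent": ("normal", 51.0, 8.0),
    "la_volume_index": ("normal", 30.2, 3.0),
    "rf_ablation": ("bernoulli", 0.30),
}


@dataclass
class SynthCohortSpec:
    """Specification of one synthetic pre/post ablation cohort.

    The designed group (which parameter distribution a patient is drawn
    from) is fixed by ``n_success``/``n_failure``; the realized outcome is
    the event process. Countable recurrence hazard starts at the end of the
    blanking window — the clock of the exponential event-time law begins at
    ``blanking_months`` — so no counted event can fall inside blanking and
    the covariate effects stay exactly proportional-hazards.
    """

    n_success: int = 130
    n_failure: int = 50
    param_distributions: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: DEFAULT_PARAM_DISTRIBUTIONS
    )
    covariates: Mapping[str, tuple] = field(default_factory=lambda: DEFAULT_COVARIATES)
    log_hr_pwdc_change: float = 0.9
    log_hr_pwa_change: float = 0.5
    baseline_hazard_per_month: float = 0.027
    horizon_months: float = 12.0
    blanking_months: float = 3.0
    pre_post_correlation: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_success < 2 or self.n_failure < 2:
            raise ValueError("n_success and n_failure must both be >= 2")
        if not (self.horizon_months > self.blanking_months >= 0):
            raise ValueError("need horizon_months > blanking_months >= 0")
        lam = self.baseline_hazard_per_month
        if not np.isfinite(lam) or lam <= 0:
            raise ValueError("baseline_hazard_per_month must be finite and > 0")
        if not np.isfinite(self.log_hr_pwdc_change) or not np.isfinite(self.log_hr_pwa_change):
            raise ValueError("log-hazard coefficients must be finite")
        if not (-1.0 <= self.pre_post_correlation <= 1.0):
            raise ValueError("pre_post_correlation must lie in [-1, 1]")
        for param, groups in self.param_distributions.items():
            for grp, (m1, s1, m2, s2) in groups.items():
                if s1 < 0 or s2 < 0:
                    raise ValueError(f"{param}/{grp}: SDs must be >= 0")


def generate_cohort(spec: SynthCohortSpec | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy patient table.

    One row per patient with designed ``group``, baseline covariates,
    ``<param>_pre``/``<param>_post``/``<param>_change`` columns for each
    configured parameter, standardized change scores ``pwdc_change_z`` and
    ``pwa_change_z`` (the hazard covariates), and the realized
    ``event``/``time_months``/``outcome`` triplet.
    """
    spec = spec or SynthCohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_success + spec.n_failure
    groups = np.array(["success"] * spec.n_success + ["failure"] * spec.n_failure)

    df = pd.DataFrame(
        {
            "id": [f"P{i + 1:04d}" for i in range(n)],
            "group": groups,
        }
    )
    for name, dist in spec.covariates.items():
        if dist[0] == "normal":
            df[name] = rng.normal(dist[1], dist[2], n)
        elif dist[0] == "bernoulli":
            df[name] = (rng.random(n) < dist[1]).astype(int)
        else:
            raise ValueError(f"unknown covariate distribution: {dist[0]!r}")

    r = spec.pre_post_correlation
    for param, by_group in spec.param_distributions.items():
        pre = np.empty(n)
        post = np.empty(n)
        for grp in ("success", "failure"):
            m1, s1, m2, s2 = by_group[grp]
            mask = groups == grp
            k = int(mask.sum())
            z_pre = rng.standard_normal(k)
            z_ind = rng.standard_normal(k)
            pre[mask] = m1 + s1 * z_pre
            # post correlates with pre but keeps the stated marginal moments
            post[mask] = m2 + s2 * (r * z_pre + np.sqrt(1.0 - r * r) * z_ind)
        df[f"{param}_pre"] = pre
        df[f"{param}_post"] = post
        df[f"{param}_change"] = post - pre

    for param, zname in (("pwdc_ms", "pwdc_change_z"), ("pwa_mv", "pwa_change_z")):
        ch = df[f"{param}_change"].to_numpy()
        sd = ch.std(ddof=1)
        df[zname] = (ch - ch.mean()) / sd if sd > 0 else 0.0

    log_hazard = (
        np.log(spec.baseline_hazard_per_month)
        + spec.log_hr_pwdc_change * df["pwdc_change_z"].to_numpy()
        + spec.log_hr_pwa_change * df["pwa_change_z"].to_numpy()
    )
    lam = np.exp(log_hazard)
    if not np.all(np.isfinite(lam)):
        raise ValueError("degenerate hazard: non-finite rates")
    t_event = spec.blanking_months + rng.exponential(1.0 / lam)
    event = t_event <= spec.horizon_months
    df["event"] = event.astype(int)
    df["time_months"] = np.where(event, t_event, spec.horizon_months)
    df["outcome"] = np.where(event, "failure", "success")
    return df
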