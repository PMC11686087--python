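"""Beat detection and P-wave delineation on filtered 12-lead ECGs.

Each RR interval is delineated independently per lead. The search window
for the P wave runs from the end of the preceding T wave to just before the
next QRS complex. Within it:

* the P peak is the largest absolute excursion from the isoelectric
  baseline whose width exceeds a minimum (default 15 ms), which rejects
  narrow noise spikes;
* the P onset is located by the chord (trapezium/"knee") rule on the
  segment from the T-wave end to the P peak: the sample with the greatest
  perpendicular distance to the straight chord joining those two points.
  A literal minimum-distance variant is available behind
  ``onset_rule="chord_min_distance_literal"``;
* the P offset is the first post-peak sample where the signal has returned
  to within a small fraction of the P amplitude of baseline and stays there
  (``baseline_return``), or a mirrored chord rule toward the QRS onset.

Per-beat measurements are averaged over the first run of twenty
consecutive measurable beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .ecg import ECGRecord

#: Minimum plausible QRS excursion (mV); below this a lead is treated as flat.
_MIN_QRS_MV = 0.1


@dataclass(frozen=True)
class DelineationConfig:
    """Tunable rules of the delineation stage (defaults are the study rules)."""

    min_p_width_ms: float = 15.0
    n_beats: int = 20
    onset_rule: str = "chord_max_distance"          # or "chord_min_distance_literal"
    offset_rule: str = "baseline_return"            # or "mirrored_chord"
    baseline_estimator: str = "tp_segment_median"   # or "pr_segment_mean"
    #: baseline-return threshold, as a fraction of the P amplitude
    offset_threshold_frac: float = 0.05
    #: the signal must stay inside the threshold band this long
    offset_hold_ms: float = 10.0
    #: opposite lobes deeper than this fraction of the P amplitude count as
    #: a true terminal phase (biphasic P) rather than filter undershoot
    terminal_phase_frac: float = 0.25
    #: onset chord anchor is at most this far before the P peak
    max_onset_chord_ms: float = 120.0
    #: assumed QRS onset, ms before the R peak (bounds the P search window)
    qrs_onset_before_r_ms: float = 50.0
    refractory_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.min_p_width_ms <= 0:
            raise ValueError("min_p_width_ms must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.onset_rule not in ("chord_max_distance", "chord_min_distance_literal"):
            raise ValueError(f"unknown onset_rule: {self.onset_rule!r}")
        if self.offset_rule not in ("baseline_return", "mirrored_chord"):
            raise ValueError(f"unknown offset_rule: {self.offset_rule!r}")
        if self.baseline_estimator not in ("tp_segment_median", "pr_segment_mean"):
            raise ValueError(f"unknown baseline_estimator: {self.baseline_estimator!r}")


def detect_beats(
    record: ECGRecord, refractory_ms: float = 200.0
) -> dict[str, np.ndarray]:
    """Detect R peaks on every lead.

    QRS complexes are found as the dominant absolute excursions from the
    median level, at least ``refractory_ms`` apart. Raises if a lead is
    flat or carries fewer than two beats.
    """
    fs = record.sampling_rate_hz
    dist = max(1, int(round(refractory_ms / 1000.0 * fs)))
    out = {}
    for lead in record.lead_names:
        x = record.lead(lead)
        dev = np.abs(x - np.median(x))
        top = float(dev.max())
        if top < _MIN_QRS_MV:
            raise ValueError(f"lead {lead}: no QRS-sized activity (flat signal?)")
        peaks, _ = sps.find_peaks(dev, height=0.6 * top, distance=dist)
        if len(peaks) < 2:
            raise ValueError(f"lead {lead}: fewer than 2 beats detected")
        out[lead] = peaks
    return out


def estimate_baseline(x: np.ndarray, start: int, end: int, estimator: str = "median") -> float:
    """Isoelectric level of one window, by median (robust) or mean."""
    if end <= start:
        raise ValueError("empty baseline window")
    seg = np.asarray(x[start:end], dtype=float)
    if seg.size == 0:
        raise ValueError("empty baseline window")
    return float(np.median(seg) if estimator == "median" else np.mean(seg))


def detect_t_end(
    x: np.ndarray,
    fs: float,
    r_index: int,
    next_r_index: int,
    baseline: float,
) -> int | None:
    """T-wave end by the tangent method.

    The T peak is the largest absolute excursion in a window after the
    QRS; the tangent at the steepest point of the terminal slope is
    extrapolated to the baseline and its crossing taken as the T end.
    """
    rr = next_r_index - r_index
    w0 = r_index + int(round(0.080 * fs))
    # the T peak lies within the QT interval (~0.42 RR); capping the search
    # there keeps the next P wave out of the T window at high heart rates
    w1 = min(next_r_index - int(round(0.050 * fs)),
             r_index + max(int(round(0.250 * fs)), int(round(0.42 * rr))))
    if w1 - w0 < 4:
        return None
    seg = x[w0:w1] - baseline
    tp = w0 + int(np.argmax(np.abs(seg)))
    sign = 1.0 if x[tp] >= baseline else -1.0
    s0 = tp
    s1 = min(w1 + int(round(0.060 * fs)), next_r_index - 1)
    if s1 - s0 < 3:
        return None
    slope = np.gradient(x[s0:s1])
    # steepest slope back toward baseline on the terminal limb
    k = s0 + int(np.argmin(sign * slope))
    sl = slope[k - s0]
    if sl == 0 or sign * sl >= 0:
        return None
    t_end = k + (baseline - x[k]) / sl
    t_end_i = int(round(t_end))
    if t_end_i <= tp or t_end_i >= next_r_index:
        return None
    return t_end_i


def detect_p_peak(
    x: np.ndarray,
    baseline: float,
    start: int,
    end: int,
    fs: float,
    min_p_width_ms: float = 15.0,
) -> int | None:
    """Largest absolute excursion of at least the minimum width.

    Candidate peaks are local maxima of ``|x - baseline|`` within
    ``[start, end)`` whose width (at half prominence) is at least
    ``min_p_width_ms``; among candidates the tallest wins. Returns ``None``
    when no excursion of sufficient width exists (unmeasurable beat).
    """
    if end - start < 3:
        return None
    dev = np.abs(x[start:end] - baseline)
    wmin = min_p_width_ms / 1000.0 * fs
    peaks, props = sps.find_peaks(dev, width=(wmin, None), rel_height=0.5)
    if len(peaks) == 0:
        return None
    best = peaks[int(np.argmax(dev[peaks]))]
    return start + int(best)


def _chord_distances(x: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Perpendicular distances of samples i0+1..i1-1 to the chord (i0, i1).

    Coordinates are (sample index, mV); distances are in that mixed plane,
    which is fine because only the arg-extreme is used.
    """
    idx = np.arange(i0 + 1, i1)
    dx = float(i1 - i0)
    dy = float(x[i1] - x[i0])
    norm = np.hypot(dx, dy)
    return np.abs(dy * (idx - i0) - dx * (x[idx] - x[i0])) / norm


def detect_p_onset(
    x: np.ndarray,
    t_end_index: int,
    p_peak_index: int,
    rule: str = "chord_max_distance",
    max_chord_span: int | None = None,
    baseline: float | None = None,
) -> int | None:
    """P onset between the T end and the P peak by the chord rule.

    ``chord_max_distance`` (default) returns the sample farthest from the
    straight chord joining the signal at the chord anchor and at the P
    peak — the geometric knee. ``chord_min_distance_literal`` returns the
    interior sample closest to the chord. Ties break toward the earlier
    sample. Returns ``None`` when the segment is degenerate (the signal
    coincides with the chord).

    The chord anchor is the T-wave end, optionally pulled forward to at
    most ``max_chord_span`` samples before the peak: atrial depolarization
    bounds how far before its peak the P can start, and anchoring the
    chord hundreds of ms away on a long diastole makes the knee sensitive
    to residual baseline ripple.

    When ``baseline`` is given, the knee is refined to the first point of
    rise above the isoelectric line: if the knee sample still lies on the
    far side of the baseline from the peak (e.g. in the shallow dip the
    band-pass leaves just before the wave), the onset advances to the
    first sample that has crossed the baseline toward the peak.
    """
    anchor = t_end_index
    if max_chord_span is not None:
        anchor = max(anchor, p_peak_index - max_chord_span)
    if p_peak_index - anchor < 2:
        return None
    d = _chord_distances(x, anchor, p_peak_index)
    if float(d.max()) < 1e-9:
        return None  # straight segment: every sample lies on the chord
    if rule == "chord_max_distance":
        k = int(np.argmax(d))
    elif rule == "chord_min_distance_literal":
        k = int(np.argmin(d))
    else:
        raise ValueError(f"unknown onset rule: {rule!r}")
    onset = anchor + 1 + k
    if baseline is not None and rule == "chord_max_distance":
        sgn = 1.0 if x[p_peak_index] >= baseline else -1.0
        while onset < p_peak_index and sgn * (x[onset] - baseline) <= 0:
            onset += 1
    return onset


def _first_settled(below: np.ndarray, start: int, hold_n: int) -> int | None:
    """First index >= start where ``below`` holds for hold_n samples or to the end."""
    run = np.zeros(below.size + 1, dtype=int)
    for i in range(below.size - 1, -1, -1):
        run[i] = run[i + 1] + 1 if below[i] else 0
    for i in range(start, below.size):
        if below[i] and (run[i] >= hold_n or i + run[i] >= below.size):
            return i
    return None


def detect_p_offset(
    x: np.ndarray,
    baseline: float,
    p_peak_index: int,
    window_end: int,
    fs: float,
    rule: str = "baseline_return",
    threshold_frac: float = 0.05,
    hold_ms: float = 10.0,
    terminal_phase_frac: float = 0.25,
    smooth_ms: float = 10.0,
) -> tuple[int | None, bool]:
    """P offset after the peak; returns ``(index, clamped)``.

    ``baseline_return``: first sample after the peak where the deviation
    toward the peak's polarity has fallen below ``threshold_frac`` of the
    P amplitude and stays there for ``hold_ms`` (or to the window end). If
    the wave then swings into an opposite-polarity lobe deeper than
    ``terminal_phase_frac`` of the amplitude — a true terminal phase, as
    in the biphasic V1 P — the offset is moved to that lobe's own return
    to baseline. Shallow opposite excursions (filter undershoot) do not
    extend the wave. When the signal never settles before the QRS onset
    the offset is clamped to the window end and flagged.

    ``mirrored_chord`` applies the onset chord rule between the peak and
    the window end. Threshold decisions use a centred moving average of
    ``smooth_ms`` to be robust to noise; indices refer to the raw signal.
    """
    if window_end - p_peak_index < 2:
        return None, False
    if rule == "mirrored_chord":
        d = _chord_distances(x, p_peak_index, window_end)
        if float(d.max()) < 1e-9:
            return None, False
        return p_peak_index + 1 + int(np.argmax(d)), False
    if rule != "baseline_return":
        raise ValueError(f"unknown offset rule: {rule!r}")
    amp = abs(x[p_peak_index] - baseline)
    if amp == 0:
        return None, False
    sgn = 1.0 if x[p_peak_index] >= baseline else -1.0
    seg = sgn * (np.asarray(x[p_peak_index : window_end + 1], dtype=float) - baseline)
    smooth_n = max(1, int(round(smooth_ms / 1000.0 * fs)) | 1)
    if smooth_n > 1 and seg.size > smooth_n:
        kernel = np.ones(smooth_n) / smooth_n
        proj = np.convolve(seg, kernel, mode="same")
        # the moving average would drag the peak sample down; keep edges raw
        proj[: smooth_n // 2] = seg[: smooth_n // 2]
        proj[-(smooth_n // 2):] = seg[-(smooth_n // 2):]
    else:
        proj = seg
    thr = threshold_frac * amp
    hold_n = max(1, int(round(hold_ms / 1000.0 * fs)))
    c1 = _first_settled(proj < thr, 1, hold_n)
    if c1 is None:
        return window_end, True
    # deep opposite-polarity lobe after the return: terminal phase of a
    # biphasic P -- extend the offset to its end
    tail = proj[c1:]
    if tail.size and float(tail.min()) < -terminal_phase_frac * amp:
        trough = c1 + int(np.argmin(tail))
        back = _first_settled(np.abs(proj) < thr, trough, hold_n)
        if back is None:
            return window_end, True
        return p_peak_index + back, False
    return p_peak_index + c1, False


def measure_negative_phase(
    x: np.ndarray,
    baseline: float,
    p_peak_index: int,
    p_offset_index: int,
    fs: float,
) -> tuple[float, float]:
    """Duration (ms) and signed peak (mV) of the terminal negative phase.

    Looks for the longest contiguous run of samples below baseline between
    the P peak and the P offset (the biphasic P's terminal lobe in V1).
    Returns ``(0.0, 0.0)`` for a monophasic positive P.
    """
    if p_offset_index - p_peak_index < 1:
        return 0.0, 0.0
    amp = abs(x[p_peak_index] - baseline)
    eps = max(0.02 * amp, 1e-4)
    seg = x[p_peak_index : p_offset_index + 1] - baseline
    below = seg < -eps
    if not below.any():
        return 0.0, 0.0
    # longest run of below-baseline samples
    edges = np.diff(np.concatenate(([0], below.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    j = int(np.argmax(ends - starts))
    s, e = starts[j], ends[j]
    duration_ms = (e - s + 1) / fs * 1000.0  # run plus its bounding crossings
    neg_peak = float(seg[s:e].min())
    return duration_ms, neg_peak


def delineate_record(
    record: ECGRecord,
    config: DelineationConfig | None = None,
    r_peaks: dict[str, np.ndarray] | None = None,
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Delineate every beat of every lead.

    Returns one row per (lead, beat): fiducial sample indices, baseline,
    per-beat PWD (ms), signed P amplitude (mV), negative-phase measures for
    the terminal force, and a ``measurable`` flag. ``beat`` indexes the R
    peak terminating the RR interval that contains the P wave.

    ``overrides`` supports the manual-adjustment workflow: a table with
    columns ``lead, beat, field, index`` replacing individual fiducials
    (``field`` in ``p_onset_index|p_peak_index|p_offset_index``) before the
    derived measurements are computed.
    """
    config = config or DelineationConfig()
    fs = record.sampling_rate_hz
    if r_peaks is None:
        r_peaks = detect_beats(record, config.refractory_ms)
    rows = []
    for lead in record.lead_names:
        x = record.lead(lead)
        rp = r_peaks[lead]
        for bi in range(1, len(rp)):
            row = _delineate_beat(x, fs, int(rp[bi - 1]), int(rp[bi]), bi, lead, config)
            rows.append(row)
    df = pd.DataFrame(rows)
    if overrides is not None and len(overrides):
        df = _apply_overrides(df, overrides, record, config)
    return df


def _delineate_beat(x, fs, prev_r, r, beat, lead, config) -> dict:
    row = dict(
        lead=lead, beat=beat, prev_r_index=prev_r, r_index=r,
        t_end_index=-1, p_onset_index=-1, p_peak_index=-1, p_offset_index=-1,
        baseline_mv=np.nan, pwd_ms=np.nan, pwa_mv=np.nan,
        neg_duration_ms=np.nan, neg_peak_mv=np.nan,
        measurable=False, clamped=False,
    )
    win_end = r - int(round(config.qrs_onset_before_r_ms / 1000.0 * fs))
    # PR-segment isoelectric anchor just before the QRS onset
    pr0 = r - int(round(0.085 * fs))
    pr1 = r - int(round(0.055 * fs))
    if pr1 <= pr0 or pr0 <= prev_r:
        return row
    stat = "median" if config.baseline_estimator == "tp_segment_median" else "mean"
    coarse = estimate_baseline(x, pr0, pr1, "median")
    t_end = detect_t_end(x, fs, prev_r, r, coarse)
    if t_end is None or win_end - t_end < 4:
        return row
    row["t_end_index"] = t_end
    # Per-beat isoelectric line through the TP anchor (just after the T end)
    # and the PR anchor: a straight line tracking the residual low-frequency
    # sag the 1 Hz high-pass leaves around the large QRS deflection. The
    # beat is measured on the detrended signal (baseline identically 0).
    b0 = t_end + int(round(0.008 * fs))
    b1 = min(t_end + int(round(0.028 * fs)), win_end)
    if b1 <= b0:
        return row
    tp_level = estimate_baseline(x, b0, b1, stat)
    pr_level = estimate_baseline(x, pr0, pr1, stat)
    i_tp = 0.5 * (b0 + b1 - 1)
    i_pr = 0.5 * (pr0 + pr1 - 1)
    slope = (pr_level - tp_level) / (i_pr - i_tp)
    y = x - (tp_level + slope * (np.arange(x.size) - i_tp))
    peak = detect_p_peak(y, 0.0, t_end, win_end, fs, config.min_p_width_ms)
    if peak is None:
        return row
    row["p_peak_index"] = peak
    row["baseline_mv"] = float(tp_level + slope * (peak - i_tp))
    onset = detect_p_onset(
        y, t_end, peak, config.onset_rule,
        max_chord_span=int(round(config.max_onset_chord_ms / 1000.0 * fs)),
        baseline=0.0,
    )
    if onset is None:
        return row
    row["p_onset_index"] = onset
    offset, clamped = detect_p_offset(
        y, 0.0, peak, win_end, fs,
        config.offset_rule, config.offset_threshold_frac, config.offset_hold_ms,
        config.terminal_phase_frac,
    )
    if offset is None:
        return row
    row["p_offset_index"] = offset
    row["clamped"] = clamped
    _finish_measures(row, y, fs, 0.0)
    return row


def _finish_measures(row: dict, x: np.ndarray, fs: float, baseline: float) -> None:
    onset, peak, offset = row["p_onset_index"], row["p_peak_index"], row["p_offset_index"]
    if not (onset <= peak <= offset):
        return
    row["pwd_ms"] = (offset - onset) / fs * 1000.0
    row["pwa_mv"] = float(x[peak] - baseline)
    nd, npk = measure_negative_phase(x, baseline, peak, offset, fs)
    row["neg_duration_ms"] = nd
    row["neg_peak_mv"] = npk
    row["measurable"] = True


def _apply_overrides(df, overrides, record, config) -> pd.DataFrame:
    df = df.copy()
    valid_fields = {"p_onset_index", "p_peak_index", "p_offset_index"}
    for _, ov in overrides.iterrows():
        if ov["field"] not in valid_fields:
            raise ValueError(f"cannot override field {ov['field']!r}")
        m = (df["lead"] == ov["lead"]) & (df["beat"] == ov["beat"])
        if not m.any():
            raise ValueError(f"no beat {ov['beat']} on lead {ov['lead']}")
        df.loc[m, ov["field"]] = int(ov["index"])
    fs = record.sampling_rate_hz
    for i in df.index:
        row = df.loc[i].to_dict()
        if row["p_onset_index"] < 0 or row["p_offset_index"] < 0:
            continue
        row["measurable"] = False
        _finish_measures(row, record.lead(row["lead"]), fs, row["baseline_mv"])
        for k, v in row.items():
            df.loc[i, k] = v
    return df


@dataclass(frozen=True)
class LeadMeasurement:
    """Averaged per-lead P-wave measurement over consecutive beats."""

    lead: str
    pwd_ms: float
    pwa_mv: float            # signed relative to baseline
    neg_duration_ms: float   # terminal negative phase (V1), ms
    neg_peak_mv: float       # signed (<= 0)
    heart_rate_bpm: float
    n_beats_used: int


def average_measurements(
    beats: pd.DataFrame,
    n_beats: int = 20,
    sampling_rate_hz: float | None = None,
) -> dict[str, LeadMeasurement]:
    """Average per-beat measurements over consecutive measurable beats.

    For each lead, the first run of ``n_beats`` consecutive measurable
    beats is averaged arithmetically; leads without such a run raise a
    ``ValueError`` naming the shortfall. Heart rate is derived from the
    mean RR interval of the averaged beats.
    """
    if sampling_rate_hz is None:
        raise ValueError("sampling_rate_hz is required to convert RR to heart rate")
    out: dict[str, LeadMeasurement] = {}
    shortfalls = []
    for lead, grp in beats.groupby("lead", sort=False):
        grp = grp.sort_values("beat")
        run = _first_measurable_run(grp, n_beats)
        if run is None:
            best = int(_longest_measurable_run(grp))
            shortfalls.append(f"{lead} ({best}/{n_beats} consecutive measurable beats)")
            continue
        rr = (run["r_index"] - run["prev_r_index"]).to_numpy(dtype=float)
        hr = 60.0 * sampling_rate_hz / rr.mean()
        out[lead] = LeadMeasurement(
            lead=lead,
            pwd_ms=float(run["pwd_ms"].mean()),
            pwa_mv=float(run["pwa_mv"].mean()),
            neg_duration_ms=float(run["neg_duration_ms"].mean()),
            neg_peak_mv=float(run["neg_peak_mv"].mean()),
            heart_rate_bpm=float(hr),
            n_beats_used=int(len(run)),
        )
    if shortfalls:
        raise ValueError(
            "insufficient consecutive measurable beats on: " + "; ".join(shortfalls)
        )
    return out


def _first_measurable_run(grp: pd.DataFrame, n_beats: int) -> pd.DataFrame | None:
    meas = grp["measurable"].to_numpy(dtype=bool)
    beats_idx = grp["beat"].to_numpy()
    count = 0
    for i in range(len(meas)):
        consecutive = i > 0 and beats_idx[i] == beats_idx[i - 1] + 1
        count = (count + 1 if (meas[i] and (count == 0 or consecutive)) else (1 if meas[i] else 0))
        if count >= n_beats:
            return grp.iloc[i - n_beats + 1 : i + 1]
    return None


def _longest_measurable_run(grp: pd.DataFrame) -> int:
    meas = grp["measurable"].to_numpy(dtype=bool)
    best = count = 0
    for m in meas:
        count = count + 1 if m else 0
        best = max(best, count)
    return best
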