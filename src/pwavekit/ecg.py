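"""12-lead ECG container, CSV I/O, and pre-processing filters.

The container holds the twelve standard limb and precordial leads at a
common sampling rate, in millivolts. Pre-processing follows the usual
clinical measurement chain: a mains notch filter plus a 1-50 Hz band-pass,
applied forward-backward so that fiducial-point latencies are not biased by
filter group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Canonical lead order of the standard 12-lead ECG.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


@dataclass
class ECGRecord:
    """One multichannel digital ECG.

    Parameters
    ----------
    lead_names
        Ordered lead names; must be exactly the 12 standard leads.
    sampling_rate_hz
        Common sampling rate of all leads, Hz.
    samples
        Array of shape ``(n_leads, n_samples)`` in millivolts.
    source_id
        Free-text provenance tag.
    """

    lead_names: tuple[str, ...]
    sampling_rate_hz: float
    samples: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.lead_names = tuple(self.lead_names)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.lead_names):
            raise ValueError(
                "samples must be a 2-D array with one row per lead; got shape "
                f"{self.samples.shape} for {len(self.lead_names)} leads"
            )
        missing = [l for l in STANDARD_LEADS if l not in self.lead_names]
        if missing:
            raise ValueError(f"missing leads: {', '.join(missing)}")
        extra = [l for l in self.lead_names if l not in STANDARD_LEADS]
        if extra:
            raise ValueError(f"unknown leads: {', '.join(extra)}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.shape[1] < self.sampling_rate_hz:
            raise ValueError("record must contain at least 1 s of samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (a view), in mV."""
        try:
            i = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"no such lead: {name}") from None
        return self.samples[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples.T, columns=list(self.lead_names))

    def plot(self, leads=("II", "V1"), start_s=0.0, length_s=5.0,
             fiducials=None, ax=None):
        """Plot a few leads, optionally with delineation markers.

        ``fiducials`` accepts the frame produced by
        :func:`pwavekit.delineate.delineate_record`; onsets, peaks and
        offsets of measurable beats are marked. Returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2 * len(leads)))
        fs = self.sampling_rate_hz
        i0, i1 = int(start_s * fs), int((start_s + length_s) * fs)
        t = np.arange(i0, min(i1, self.n_samples)) / fs
        offset = 0.0
        for lead in leads:
            x = self.lead(lead)[i0 : i0 + t.size]
            ax.plot(t, x + offset, lw=0.8, label=lead)
            if fiducials is not None:
                sub = fiducials[(fiducials["lead"] == lead) & fiducials["measurable"]]
                for col, marker in (("p_onset_index", "<"),
                                    ("p_peak_index", "^"),
                                    ("p_offset_index", ">")):
                    idx = sub[col].to_numpy(dtype=int)
                    idx = idx[(idx >= i0) & (idx < i0 + t.size)]
                    ax.plot(idx / fs, self.lead(lead)[idx] + offset, marker,
                            ms=5, ls="none")
            offset -= 1.5
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mV (leads offset)")
        ax.legend(loc="upper right", fontsize=8)
        return ax

    def to_csv(self, path) -> None:
        """Write the record as one column per lead, header row of lead names.

        The sampling rate is stored in a ``# sampling_rate_hz=...`` comment
        line so that the file round-trips without a side-car header.
        """
        with open(path, "w") as fh:
            fh.write(f"# sampling_rate_hz={self.sampling_rate_hz:g}\n")
            self.to_dataframe().to_csv(fh, index=False)


@dataclass(frozen=True)
class FilterConfig:
    """Pre-processing filter settings.

    ``notch_freq_hz`` defaults to 50 Hz mains; the band-pass defaults to the
    1-50 Hz measurement band. ``zero_phase`` applies each filter
    forward-backward (``filtfilt``) so the chain introduces no group delay.
    """

    notch_freq_hz: float = 50.0
    notch_q: float = 30.0
    bandpass_low_hz: float = 1.0
    bandpass_high_hz: float = 50.0
    filter_order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2.0
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz):
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if self.bandpass_high_hz >= nyq:
            raise ValueError(
                f"bandpass_high_hz={self.bandpass_high_hz} infeasible at "
                f"sampling rate {sampling_rate_hz} Hz (Nyquist {nyq} Hz)"
            )
        if not (0 < self.notch_freq_hz < nyq):
            raise ValueError("notch_freq_hz must lie inside (0, Nyquist)")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def read_record(path, format: str = "csv") -> ECGRecord:
    """Read a 12-lead ECG from disk.

    Only the package's CSV dialect is supported: one column per lead,
    header row of the standard lead names, values in mV, optional
    ``# sampling_rate_hz=`` comment line (default 500 Hz without it).
    """
    if format != "csv":
        raise ValueError(f"unsupported format: {format!r} (only 'csv' is supported)")
    fs = 500.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "sampling_rate_hz=" in first:
                fs = float(first.split("sampling_rate_hz=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [l for l in STANDARD_LEADS if l not in df.columns]
    if missing:
        raise ValueError(f"missing leads: {', '.join(missing)}")
    data = df[list(STANDARD_LEADS)].to_numpy(dtype=float).T
    return ECGRecord(STANDARD_LEADS, fs, data, source_id=str(path))


def preprocess(record: ECGRecord, config: FilterConfig | None = None) -> ECGRecord:
    """Apply the notch + band-pass measurement filters to every lead.

    Output has the same length as the input; the passband gain is ~1 and the
    notch and out-of-band components are strongly attenuated.
    """
    config = config or FilterConfig()
    config.validate(record.sampling_rate_hz)
    fs = record.sampling_rate_hz
    b_notch, a_notch = sps.iirnotch(config.notch_freq_hz, config.notch_q, fs=fs)
    # scipy's butter doubles the order for band-pass designs, so an
    # order-4 band-pass is butter(N=2, ...).
    sos_band = sps.butter(
        max(1, config.filter_order // 2),
        [config.bandpass_low_hz, config.bandpass_high_hz],
        btype="bandpass",
        output="sos",
        fs=fs,
    )
    out = np.empty_like(record.samples)
    for i, x in enumerate(record.samples):
        if config.zero_phase:
            y = sps.filtfilt(b_notch, a_notch, x)
            y = sps.sosfiltfilt(sos_band, y)
        else:
            y = sps.lfilter(b_notch, a_notch, x)
            y = sps.sosfilt(sos_band, y)
        out[i] = y
    return replace(record, samples=out)


def extract_window(record: ECGRecord, start_s: float, length_s: float = 60.0) -> ECGRecord:
    """Cut a fixed-length analysis window (default one minute) out of a record."""
    if start_s < 0 or length_s <= 0:
        raise ValueError("start_s must be >= 0 and length_s > 0")
    fs = record.sampling_rate_hz
    i0 = int(round(start_s * fs))
    n = int(round(length_s * fs))
    if i0 >= record.n_samples or i0 + n > record.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + length_s}] s out of range for a "
            f"{record.duration_s:g} s record"
        )
    return replace(record, samples=record.samples[:, i0 : i0 + n].copy())
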