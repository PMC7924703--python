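"""ECG record, R-peak and session I/O.

Supported signal inputs: ISHNE-Holter (*.ecg), EDF (*.edf), delimited
text/CSV (one column per channel, sampling frequency supplied by the
caller) and WFDB records (benchmark harness).  All readers return an
:class:`EcgRecord` with amplitudes in millivolts, channels of equal length
and a single sampling frequency.

Coordinate conventions: sample indices are 0-based; analysis windows are
half-open ``[start, start + duration)``; millisecond-to-sample conversions
round to nearest with a minimum of one sample.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .correction import Tachogram
from .detection import DetectionConfig, RPeakAnnotations
from .formats import edf as _edf
from .formats import ishne as _ishne
from .formats import wfdb as _wfdb

__all__ = [
    "EcgRecord",
    "AnalysisWindow",
    "SessionState",
    "read_record",
    "invert",
    "crop",
    "read_peaks",
    "write_results",
    "save_session",
    "load_session",
]

SESSION_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class EcgRecord:
    """Multichannel ECG: samples in mV, one sampling frequency, labels."""

    channels: np.ndarray  # (n_channels, n_samples)
    fs: float
    labels: list[str] = field(default_factory=list)
    inverted: bool = False

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.channels.shape[1] < 1:
            raise ValueError("channels must contain at least one sample")
        if not self.labels:
            self.labels = [f"Channel {i + 1}" for i in range(self.channels.shape[0])]
        if len(self.labels) != self.channels.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open analysis window [start_s, start_s + duration_s) in seconds."""

    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError("start_s must be nonnegative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def invert(record: EcgRecord) -> EcgRecord:
    """Negate every sample and toggle the inversion flag."""
    return EcgRecord(
        channels=-record.channels,
        fs=record.fs,
        labels=list(record.labels),
        inverted=not record.inverted,
    )


def crop(record: EcgRecord, window: AnalysisWindow) -> EcgRecord:
    """Restrict a record to an analysis window.

    The result holds ``round(duration_s * fs)`` samples starting at
    ``round(start_s * fs)``; a window reaching past the record raises.
    """
    start = int(round(window.start_s * record.fs))
    count = int(round(window.duration_s * record.fs))
    if start + count > record.n_samples:
        raise IndexError(
            f"analysis window [{window.start_s}, "
            f"{window.start_s + window.duration_s}) s exceeds the "
            f"{record.duration_s:g} s record"
        )
    return EcgRecord(
        channels=record.channels[:, start : start + count],
        fs=record.fs,
        labels=list(record.labels),
        inverted=record.inverted,
    )


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    by_ext = {".ecg": "ishne", ".edf": "edf", ".csv": "csv", ".txt": "txt",
              ".hea": "wfdb"}
    if ext in by_ext:
        return by_ext[ext]
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head == _ishne.MAGIC:
        return "ishne"
    if head.startswith(b"0  ") or head.rstrip() == b"0":
        return "edf"
    return "csv"


def _read_delimited(path: str, fs_override: float | None):
    if fs_override is None:
        raise ValueError("text/CSV input needs an explicit sampling frequency")
    sep = r"[,;\t ]+"
    try:
        df = pd.read_csv(path, sep=sep, engine="python", header=None)
        df = df.apply(pd.to_numeric)
        labels = None
    except ValueError:
        df = pd.read_csv(path, sep=sep, engine="python")
        labels = [str(c) for c in df.columns]
        df = df.apply(pd.to_numeric)
    return df.to_numpy(dtype=float).T, float(fs_override), labels


def read_record(
    path,
    format: str = "auto",
    fs_override: float | None = None,
    channel_selection: list[int] | None = None,
) -> EcgRecord:
    """Read an ECG file into an :class:`EcgRecord`.

    Parameters
    ----------
    path : path-like
    format : {'auto', 'ishne', 'edf', 'csv', 'txt', 'wfdb'}
        'auto' decides from the extension and magic bytes.
    fs_override : float, optional
        Sampling frequency in Hz; required for text/CSV, overrides the
        header value otherwise.
    channel_selection : list of int, optional
        Channel indices (0-based) to keep, in the given order.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    labels: list[str] | None = None
    try:
        if fmt == "ishne":
            channels, fs, header = _ishne.read(path)
            labels = [f"Lead {i + 1}" for i in range(header.n_leads)]
        elif fmt == "edf":
            channels, fs, labels = _edf.read(path, channel_selection)
            channel_selection = None  # already applied
        elif fmt in ("csv", "txt"):
            channels, fs, labels = _read_delimited(path, fs_override)
        elif fmt == "wfdb":
            channels, fs, labels = _wfdb.read_record(path)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (_ishne.IshneFormatError, _edf.EdfFormatError, _wfdb.WfdbFormatError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if fs_override is not None:
        fs = float(fs_override)
    if channel_selection is not None:
        channels = channels[channel_selection]
        if labels is not None:
            labels = [labels[i] for i in channel_selection]
    return EcgRecord(channels=channels, fs=fs, labels=labels or [])


def read_peaks(path, fs: float, unit: str = "samples") -> RPeakAnnotations:
    """Read externally produced R-peak locations.

    Two layouts are accepted: the package's own long form with columns
    ``channel, sample_index, time_s``, or a plain numeric table with one
    column per channel (shorter channels padded with blanks).  Values in
    seconds are converted to the nearest sample.  Indices come back sorted
    with duplicates removed.
    """
    if unit not in {"samples", "seconds"}:
        raise ValueError(f"unknown unit {unit!r}")
    df = pd.read_csv(path)
    cols = [str(c).strip().lower() for c in df.columns]
    if "channel" in cols and "sample_index" in cols:
        df.columns = cols
        channels = []
        for _, grp in df.groupby("channel", sort=True):
            vals = grp["sample_index"].to_numpy(dtype=float)
            channels.append(vals)
    else:
        df = pd.read_csv(path, header=None)
        try:
            df = df.apply(pd.to_numeric)
        except ValueError:
            df = pd.read_csv(path).apply(pd.to_numeric)
        channels = [df[c].dropna().to_numpy(dtype=float) for c in df.columns]
    out = []
    for vals in channels:
        if np.any(vals < 0):
            raise ValueError("negative R-peak locations are not allowed")
        if unit == "seconds":
            vals = np.round(vals * fs)
        out.append(np.unique(vals.astype(np.intp)))
    return RPeakAnnotations(channels=out, fs=float(fs))


def write_results(
    record: EcgRecord,
    peaks: RPeakAnnotations,
    tachograms: list[Tachogram] | None,
    path,
    format: str = "csv",
) -> list[str]:
    """Export detection results.

    CSV: a ``<base>_summary.csv`` plus one ``<base>_ch<k>.csv`` per channel
    (re-readable by :func:`read_peaks`).  JSON: a single document.  Each
    channel table carries R-peak sample indices, times, RR intervals (ms)
    and the mean heart rate 60000 / mean(RR).
    """
    path = os.fspath(path)
    if tachograms is None:
        tachograms = [Tachogram.from_peaks(p, record.fs) for p in peaks.channels]
    analysis_s = record.duration_s
    summary = {
        "n_channels": record.n_channels,
        "fs_hz": record.fs,
        "signal_duration_s": record.duration_s,
        "analysis_duration_s": analysis_s,
    }
    written: list[str] = []
    if format == "json":
        doc = {
            "summary": summary,
            "channels": [
                {
                    "label": record.labels[k],
                    "r_peak_samples": [int(v) for v in peaks.channels[k]],
                    "r_peak_times_s": [float(v) for v in peaks.channels[k] / record.fs],
                    "rr_ms": [float(v) for v in tachograms[k].rr_ms],
                    "nn_flags": [bool(v) for v in tachograms[k].nn_flags],
                    "mean_hr_bpm": tachograms[k].mean_hr_bpm(),
                }
                for k in range(record.n_channels)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, allow_nan=True)
        return [path]
    if format != "csv":
        raise ValueError(f"unknown export format {format!r}")
    base = path[:-4] if path.lower().endswith(".csv") else path
    spath = f"{base}_summary.csv"
    pd.DataFrame([summary]).to_csv(spath, index=False)
    written.append(spath)
    for k in range(record.n_channels):
        p = peaks.channels[k]
        df = pd.DataFrame(
            {
                "channel": np.full(len(p), k, dtype=int),
                "sample_index": p,
                "time_s": p / record.fs,
                "rr_ms": np.concatenate([[np.nan], tachograms[k].rr_ms])
                if len(p)
                else np.empty(0),
            }
        )
        df["mean_hr_bpm"] = tachograms[k].mean_hr_bpm() if len(p) > 1 else np.nan
        cpath = f"{base}_ch{k + 1}.csv"
        df.to_csv(cpath, index=False)
        written.append(cpath)
    return written


@dataclass
class SessionState:
    """Everything needed to resume an analysis: config, filters, window, peaks."""

    config: DetectionConfig = field(default_factory=DetectionConfig)
    filters: list[dict] = field(default_factory=list)
    window: AnalysisWindow | None = None
    peaks: list[list[int]] = field(default_factory=list)
    source_path: str | None = None


class SessionFormatError(ValueError):
    """Session file unreadable or from an unsupported schema version."""


def save_session(state: SessionState, path) -> None:
    doc = {
        "schema_version": SESSION_SCHEMA_VERSION,
        "config": asdict(state.config),
        "filters": state.filters,
        "window": asdict(state.window) if state.window else None,
        "peaks": [[int(i) for i in ch] for ch in state.peaks],
        "source_path": state.source_path,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_session(path) -> SessionState:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"{path}: not a valid session document ({exc})") from exc
    version = doc.get("schema_version")
    if version != SESSION_SCHEMA_VERSION:
        raise SessionFormatError(
            f"{path}: schema version {version!r}, expected {SESSION_SCHEMA_VERSION}"
        )
    window = doc.get("window")
    return SessionState(
        config=DetectionConfig(**doc["config"]),
        filters=list(doc.get("filters", [])),
        window=AnalysisWindow(**window) if window else None,
        peaks=[list(map(int, ch)) for ch in doc.get("peaks", [])],
        source_path=doc.get("source_path"),
    )
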