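"""Zero-phase Butterworth filters and Welch spectrum estimation.

The high-pass is a zero-phase second-order Butterworth, the low-pass a
zero-phase fourth-order Butterworth, and the notch an IIR notch (default
Q = 30) — all applied forward-backward so the waveform is not delayed.
The stated orders describe the underlying design; the forward-backward pass
doubles the effective order.  Filtering is meant to be applied to the
pristine original samples the caller holds, so repeated filter choices stay
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["FilterSpec", "PowerSpectrum", "apply_filter", "welch_psd"]


class ParameterError(ValueError):
    """A filter parameter is invalid for the record's sampling frequency."""


@dataclass(frozen=True)
class FilterSpec:
    """One filter: kind 'highpass' | 'lowpass' | 'notch'.

    cutoff_hz applies to high/low-pass; center_hz and q to the notch.
    order defaults to 2 (highpass) or 4 (lowpass).
    """

    kind: str
    cutoff_hz: float | None = None
    center_hz: float | None = None
    q: float = 30.0
    order: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"highpass", "lowpass", "notch"}:
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.kind == "notch":
            if self.center_hz is None or self.center_hz <= 0:
                raise ParameterError("notch filter needs a positive center_hz")
        else:
            if self.cutoff_hz is None or self.cutoff_hz <= 0:
                raise ParameterError(f"{self.kind} filter needs a positive cutoff_hz")
        if self.order is not None and self.order < 1:
            raise ParameterError("filter order must be >= 1")

    @property
    def design_order(self) -> int:
        if self.order is not None:
            return self.order
        return 2 if self.kind == "highpass" else 4


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density (mV^2/Hz)."""

    freqs_hz: np.ndarray
    density: np.ndarray
    segment_samples: int
    overlap_fraction: float


def apply_filter(record, spec: FilterSpec):
    """Zero-phase filtering of every channel; length and fs are unchanged."""
    from .io import EcgRecord  # local import to avoid a module cycle

    fs = record.fs
    nyq = fs / 2.0
    freq = spec.center_hz if spec.kind == "notch" else spec.cutoff_hz
    if freq >= nyq:
        raise ParameterError(
            f"{spec.kind} frequency {freq:g} Hz is at or above Nyquist ({nyq:g} Hz)"
        )
    if spec.kind == "notch":
        b, a = signal.iirnotch(spec.center_hz, spec.q, fs=fs)
        out = signal.filtfilt(b, a, record.channels, axis=1)
    else:
        sos = signal.butter(
            spec.design_order, freq, btype=spec.kind, fs=fs, output="sos"
        )
        out = signal.sosfiltfilt(sos, record.channels, axis=1)
    return EcgRecord(
        channels=out, fs=fs, labels=list(record.labels), inverted=record.inverted
    )


def welch_psd(
    record,
    segment_samples: int = 500,
    overlap_fraction: float = 0.6,
    channel: int = 0,
) -> PowerSpectrum:
    """Welch PSD of one channel: Hamming taper, mean-detrended segments."""
    x = np.asarray(record.channels)[channel]
    if len(x) < segment_samples:
        raise ValueError(
            f"record has {len(x)} samples, shorter than one {segment_samples}-sample "
            "segment; use a smaller segment_samples"
        )
    freqs, pxx = signal.welch(
        x,
        fs=record.fs,
        window="hamming",
        nperseg=segment_samples,
        noverlap=int(round(overlap_fraction * segment_samples)),
        detrend="constant",
        scaling="density",
    )
    return PowerSpectrum(
        freqs_hz=freqs,
        density=pxx,
        segment_samples=segment_samples,
        overlap_fraction=overlap_fraction,
    )
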