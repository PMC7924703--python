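"""Minimal European Data Format (EDF) reader and writer.

EDF stores an ASCII header (256 bytes plus 256 per signal) followed by data
records of little-endian int16 samples.  Physical values are recovered from
the per-signal calibration (physical/digital min/max); the sampling rate of
a signal is its samples-per-record divided by the record duration.  Values
are returned in millivolts, converting from the header's physical dimension
when it is a recognizable voltage unit (uV, mV, V); unknown dimensions are
taken as mV as-is.
"""

from __future__ import annotations

import numpy as np


class EdfFormatError(ValueError):
    """Malformed EDF file; the message names the offending field."""


_UNIT_TO_MV = {"uv": 1e-3, "µv": 1e-3, "mv": 1.0, "v": 1e3}


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write(
    path,
    channels: np.ndarray,
    fs: float,
    labels: list[str] | None = None,
    record_duration_s: float = 1.0,
    phys_dim: str = "mV",
) -> None:
    """Write channels (n_signals, n_samples) in mV as an EDF file.

    The tail of the signal is zero-padded up to a whole number of data
    records (EDF stores fixed-size records).
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    ns, n = channels.shape
    labels = labels or [f"ECG {i + 1}" for i in range(ns)]
    spr = int(round(fs * record_duration_s))
    if spr <= 0:
        raise EdfFormatError("record duration too short for the sampling rate")
    n_rec = int(np.ceil(n / spr))
    padded = np.zeros((ns, n_rec * spr))
    padded[:, :n] = channels

    pmin = float(min(padded.min(), -1.0))
    pmax = float(max(padded.max(), 1.0))
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin) * scale + dmin).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),  # patient
            _ascii("X", 80),  # recording
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + ns), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(f"{record_duration_s:g}", 8),
            _ascii(ns, 4),
        ]
    )
    sig = b"".join(_ascii(lb, 16) for lb in labels)
    sig += b"".join(_ascii("", 80) for _ in range(ns))
    sig += b"".join(_ascii(phys_dim, 8) for _ in range(ns))
    sig += b"".join(_ascii(f"{pmin:.6g}", 8) for _ in range(ns))
    sig += b"".join(_ascii(f"{pmax:.6g}", 8) for _ in range(ns))
    sig += b"".join(_ascii(dmin, 8) for _ in range(ns))
    sig += b"".join(_ascii(dmax, 8) for _ in range(ns))
    sig += b"".join(_ascii("", 80) for _ in range(ns))
    sig += b"".join(_ascii(spr, 8) for _ in range(ns))
    sig += b"".join(_ascii("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            for s in range(ns):
                fh.write(digital[s, r * spr : (r + 1) * spr].tobytes())


def _field(blob: bytes, offset: int, width: int) -> str:
    return blob[offset : offset + width].decode("ascii", errors="replace").strip()


def read(path, channel_selection: list[int] | None = None):
    """Read an EDF file.

    Returns ``(channels in mV, fs, labels)`` for the selected channels.
    All selected channels must share one sampling rate (no resampling).
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EdfFormatError("file truncated inside the main header")
        try:
            n_rec = int(_field(head, 236, 8))
            rec_dur = float(_field(head, 244, 8))
            ns = int(_field(head, 252, 4))
        except ValueError as exc:
            raise EdfFormatError(f"non-numeric header field: {exc}") from exc
        if ns <= 0:
            raise EdfFormatError(f"number-of-signals field is {ns}, expected > 0")
        if rec_dur <= 0:
            raise EdfFormatError(f"record-duration field is {rec_dur}, expected > 0")
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise EdfFormatError("file truncated inside the signal headers")

        def col(width: int, base: int):
            return [_field(sig, base + i * width, width) for i in range(ns)]

        off = 0
        labels = col(16, off); off += 16 * ns
        off += 80 * ns  # transducer
        dims = col(8, off); off += 8 * ns
        pmins = [float(v) for v in col(8, off)]; off += 8 * ns
        pmaxs = [float(v) for v in col(8, off)]; off += 8 * ns
        dmins = [int(float(v)) for v in col(8, off)]; off += 8 * ns
        dmaxs = [int(float(v)) for v in col(8, off)]; off += 8 * ns
        off += 80 * ns  # prefiltering
        sprs = [int(v) for v in col(8, off)]

        sel = channel_selection if channel_selection is not None else list(range(ns))
        rates = {sprs[i] / rec_dur for i in sel}
        if len(rates) > 1:
            raise EdfFormatError(
                "selected channels have different sampling rates; "
                "resampling is unsupported — select channels of one rate"
            )
        fs = rates.pop()

        rec_words = sum(sprs)
        data = np.frombuffer(fh.read(n_rec * rec_words * 2), dtype="<i2")
        if len(data) < n_rec * rec_words:
            raise EdfFormatError("data block shorter than header promises")
        data = data.reshape(n_rec, rec_words)

    starts = np.concatenate([[0], np.cumsum(sprs)])
    out = []
    out_labels = []
    for i in sel:
        raw = data[:, starts[i] : starts[i + 1]].reshape(-1).astype(float)
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (raw - dmins[i]) * gain + pmins[i]
        phys *= _UNIT_TO_MV.get(dims[i].lower(), 1.0)
        out.append(phys)
        out_labels.append(labels[i])
    return np.vstack(out), fs, out_labels
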