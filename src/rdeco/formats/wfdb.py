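"""Minimal WFDB record and annotation support (MIT/BIH benchmarking).

Reads a record header (``.hea``), the signal file in format 16 (int16 LE,
interleaved) or 212 (packed 12-bit pairs), and MIT-format annotation files.
A matching writer produces format-16 records plus annotation files so the
benchmark harness can be exercised on locally generated fixtures.  Only the
fields the detector needs are handled: lead count, sampling rate, gain and
baseline; amplitudes are converted to millivolts as (adc - baseline) / gain
with the conventional WFDB gain unit of adc units per millivolt.
"""

from __future__ import annotations

import os
import re

import numpy as np


class WfdbFormatError(ValueError):
    """Malformed WFDB header or annotation file."""


#: MIT annotation codes that denote beats (N, L, R, a, V, F, J, A, S, E, j,
#: /, Q, r, e, n, f)
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41})
NORMAL = 1
PVC = 5


def read_header(hea_path):
    """Parse a .hea file -> (record_name, n_sig, fs, n_samples, signal specs)."""
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WfdbFormatError(f"{hea_path}: empty header")
    top = lines[0].split()
    if len(top) < 2:
        raise WfdbFormatError(f"{hea_path}: record line needs name and signal count")
    name = top[0].split("/")[0]
    n_sig = int(top[1])
    fs = float(top[2].split("/")[0]) if len(top) > 2 else 250.0
    n_samples = int(top[3]) if len(top) > 3 else 0
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, 0
        if len(parts) > 2:
            m = re.match(r"([-\d.eE+]+)(?:\(([-\d]+)\))?(?:/(\S+))?", parts[2])
            if m:
                gain = float(m.group(1)) or 200.0
                if m.group(2) is not None:
                    baseline = int(m.group(2))
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if len(parts) <= 2 or m is None or m.group(2) is None:
            baseline = adc_zero
        specs.append({"file": fname, "fmt": int(fmt), "gain": gain, "baseline": baseline})
    return name, n_sig, fs, n_samples, specs


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    s1 = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    s2 = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2], out[1::2] = s1, s2
    out = np.where(out > 2047, out - 4096, out)  # sign-extend 12 bits
    return out[:n_values]


def read_record(hea_path):
    """Read a WFDB record -> (channels in mV, fs, labels)."""
    name, n_sig, fs, n_samples, specs = read_header(hea_path)
    base = os.path.dirname(os.path.abspath(hea_path))
    dat_path = os.path.join(base, specs[0]["file"])
    fmt = specs[0]["fmt"]
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif fmt == 212:
        data = _decode_212(raw, n_samples * n_sig if n_samples else (len(raw) // 3) * 2)
    else:
        raise WfdbFormatError(f"unsupported WFDB signal format {fmt}")
    n = len(data) // n_sig
    if n_samples:
        n = min(n, n_samples)
    data = data[: n * n_sig].reshape(n, n_sig).T.astype(float)
    channels = np.empty_like(data)
    for i, spec in enumerate(specs):
        channels[i] = (data[i] - spec["baseline"]) / spec["gain"]
    labels = [f"{name} ch{i + 1}" for i in range(n_sig)]
    return channels, fs, labels


def write_record(directory, name: str, channels: np.ndarray, fs: float,
                 gain: float = 200.0) -> str:
    """Write a format-16 WFDB record; returns the .hea path."""
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    n_sig, n = channels.shape
    adc = np.round(channels * gain)
    if np.any(np.abs(adc) > 32767):
        raise WfdbFormatError("amplitude overflows int16 at this gain")
    adc = adc.astype("<i2")
    dat = f"{name}.dat"
    hea_path = os.path.join(directory, f"{name}.hea")
    with open(hea_path, "w") as fh:
        fh.write(f"{name} {n_sig} {fs:g} {n}\n")
        for _ in range(n_sig):
            fh.write(f"{dat} 16 {gain:g}(0)/mV 16 0 0 0 0 ECG\n")
    with open(os.path.join(directory, dat), "wb") as fh:
        fh.write(adc.T.tobytes())
    return hea_path


def read_annotations(atr_path, beat_only: bool = True,
                     codes: frozenset = BEAT_CODES) -> np.ndarray:
    """Read MIT-format annotations -> sample indices (beats only by default)."""
    with open(atr_path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw, dtype="<u2")
    samples = []
    t = 0
    i = 0
    while i < len(words):
        word = int(words[i])
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte interval in the next two words
            if i + 2 >= len(words):
                raise WfdbFormatError("truncated SKIP annotation")
            t += (int(words[i + 1]) << 16) + int(words[i + 2])
            i += 3
            continue
        if code == 63:  # AUX: delta = byte count, padded to even
            i += 1 + (delta + 1) // 2
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN carry no time
            i += 1
            continue
        t += delta
        if (not beat_only) or code in codes:
            samples.append(t)
        i += 1
    return np.asarray(samples, dtype=np.intp)


def write_annotations(atr_path, samples, code: int = NORMAL) -> None:
    """Write beat annotations in MIT format (single annotation code)."""
    samples = np.asarray(samples, dtype=np.int64)
    if np.any(np.diff(samples) < 0):
        raise WfdbFormatError("annotation samples must be sorted")
    words: list[int] = []
    t = 0
    for s in samples:
        delta = int(s - t)
        while delta >= 1024:
            chunk = min(delta, (1 << 31) - 1)
            words.append((59 << 10))
            words.append(chunk >> 16)
            words.append(chunk & 0xFFFF)
            t += chunk
            delta = int(s - t)
        words.append((code << 10) | delta)
        t = int(s)
    words.append(0)  # EOF
    np.asarray(words, dtype="<u2").tofile(atr_path)
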