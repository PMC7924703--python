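"""ISHNE-Holter (*.ecg) reader and writer.

Layout: 8-byte magic ``ISHNE1.0``, a 16-bit CRC-CCITT of the 512-byte fixed
header that follows, the fixed header itself, an optional variable-length
comment block, then little-endian int16 samples interleaved by lead.  The
per-lead amplitude resolution is stored in integer nanovolts; samples are
converted to millivolts on read.

The CRC is verified but only warned about on mismatch — files in the wild
frequently carry a stale checksum.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass

import numpy as np

MAGIC = b"ISHNE1.0"
FIXED_HEADER_SIZE = 512
HEADER_TOTAL = 8 + 2 + FIXED_HEADER_SIZE  # magic + crc + fixed block

# fixed header layout (after magic and CRC), little-endian
_FMT = "<iiiih40s40s20shh3h3h3h3hh12h12h12hh40sh80s80s88s"
assert struct.calcsize(_FMT) == FIXED_HEADER_SIZE


class IshneFormatError(ValueError):
    """Malformed ISHNE file; the message names the offending field."""


def crc_ccitt(data: bytes, poly: int = 0x1021, init: int = 0xFFFF) -> int:
    crc = init
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ poly) if crc & 0x8000 else (crc << 1)
            crc &= 0xFFFF
    return crc


@dataclass
class IshneHeader:
    n_leads: int
    fs: float
    n_samples_per_lead: int
    resolution_nv: list[int]
    comment: bytes = b""


def write(
    path,
    channels: np.ndarray,
    fs: float,
    resolution_nv: int = 1000,
    comment: bytes = b"",
) -> None:
    """Write channels (n_leads, n_samples) in mV as an ISHNE file."""
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    n_leads, n_samples = channels.shape
    if n_leads > 12:
        raise IshneFormatError("ISHNE supports at most 12 leads")
    raw = np.round(channels * 1e6 / resolution_nv)
    if np.any(np.abs(raw) > 32767):
        raise IshneFormatError(
            "amplitude overflows int16 at the requested resolution; "
            "increase resolution_nv"
        )
    raw = raw.astype("<i2")

    res = [0] * 12
    for i in range(n_leads):
        res[i] = resolution_nv
    var_size = len(comment)
    fixed = struct.pack(
        _FMT,
        var_size,                      # variable-length block size
        n_samples,                     # ECG samples per lead
        HEADER_TOTAL,                  # offset of variable-length block
        HEADER_TOTAL + var_size,       # offset of ECG block
        1,                             # file version
        b"", b"", b"",                 # first name, last name, id
        0, 0,                          # sex, race
        0, 0, 0,                       # birth date
        1, 1, 2000,                    # record date
        1, 1, 2000,                    # file date
        0, 0, 0,                       # start time
        n_leads,
        *([0] * 12),                   # lead specification
        *([0] * 12),                   # lead quality
        *res,                          # amplitude resolution (nV)
        0,                             # pacemaker
        b"",                           # recorder type
        int(round(fs)),                # sampling rate (Hz)
        b"", b"", b"",                 # proprietary, copyright, reserved
    )
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<H", crc_ccitt(fixed)))
        fh.write(fixed)
        fh.write(comment)
        fh.write(raw.T.tobytes())  # interleaved by lead


def read(path) -> tuple[np.ndarray, float, IshneHeader]:
    """Read an ISHNE file; returns (channels in mV, fs, header)."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < HEADER_TOTAL:
        raise IshneFormatError("file truncated before end of header")
    if blob[:8] != MAGIC:
        raise IshneFormatError(f"bad magic number {blob[:8]!r}, expected {MAGIC!r}")
    (crc_stored,) = struct.unpack_from("<H", blob, 8)
    fixed = blob[10:HEADER_TOTAL]
    if crc_ccitt(fixed) != crc_stored:
        warnings.warn("ISHNE header CRC mismatch; continuing")
    fields = struct.unpack(_FMT, fixed)
    var_size, n_samples, var_off, ecg_off = fields[0], fields[1], fields[2], fields[3]
    n_leads = fields[22]
    res = list(fields[47:59])
    fs = float(fields[61])
    if not 1 <= n_leads <= 12:
        raise IshneFormatError(f"lead count field is {n_leads}, expected 1..12")
    if fs <= 0:
        raise IshneFormatError(f"sampling-rate field is {fs}, expected > 0")
    if n_samples <= 0:
        raise IshneFormatError(f"sample-count field is {n_samples}, expected > 0")
    comment = blob[var_off : var_off + var_size]
    data = np.frombuffer(blob, dtype="<i2", offset=ecg_off, count=n_leads * n_samples)
    channels = data.reshape(n_samples, n_leads).T.astype(float)
    for i in range(n_leads):
        r = res[i] if res[i] > 0 else 1000
        channels[i] *= r * 1e-6  # nV units -> mV
    header = IshneHeader(
        n_leads=n_leads,
        fs=fs,
        n_samples_per_lead=n_samples,
        resolution_nv=res[:n_leads],
        comment=comment,
    )
    return channels, fs, header
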