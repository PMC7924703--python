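"""R-peak correction operators and NN-interval extraction.

Automatic correctors: template cross-correlation, peak conversion (hill
climbing on |x|) and windowed maximum search.  Manual edits (add / move /
delete) are pure functions on annotation arrays.  ``remove_ectopic`` flags
premature-beat interval pairs in a tachogram without altering any RR value,
so HRV-style analyses can restrict themselves to normal-to-normal intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BeatTemplate",
    "Tachogram",
    "build_templates",
    "xcorr_correct",
    "peak_convert",
    "max_search",
    "remove_ectopic",
    "edit_peaks",
    "add_peak",
    "move_peak",
    "delete_peaks",
]

#: refractory spacing (s) below which two annotations cannot both be beats
REFRACTORY_S = 0.2


@dataclass
class BeatTemplate:
    """Trimmed-average normalized QRS template.

    samples are z-normalized (mean 0, sd 1 per contributing beat); length is
    odd, centered on the annotation; ``r_offset`` is the index of the R-peak
    within the template (defaults to the center, adjustable).
    """

    samples: np.ndarray
    window_ms: float
    r_offset: int
    polarity_class: str  # "positive" | "negative"
    n_beats: int = 0


@dataclass
class Tachogram:
    """RR-interval series with normal-to-normal flags.

    ``rr_ms[i]`` is the interval between beats i and i+1; flagged-out
    intervals are masked via ``nn_flags``, never dropped.
    """

    rr_ms: np.ndarray
    beat_times_s: np.ndarray
    nn_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.nn_flags is None:
            self.nn_flags = np.ones(len(self.rr_ms), dtype=bool)
        else:
            self.nn_flags = np.asarray(self.nn_flags, dtype=bool)
        if len(self.rr_ms) != max(0, len(self.beat_times_s) - 1):
            raise ValueError("rr_ms length must equal number of beats - 1")
        if len(self.nn_flags) != len(self.rr_ms):
            raise ValueError("nn_flags length must equal rr_ms length")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_peaks(cls, indices: np.ndarray, fs: float) -> "Tachogram":
        idx = np.asarray(indices, dtype=np.intp)
        times = idx / float(fs)
        rr = np.diff(idx) * 1000.0 / float(fs)
        return cls(rr_ms=rr, beat_times_s=times)

    @property
    def nn_ms(self) -> np.ndarray:
        """RR values of intervals still flagged normal-to-normal."""
        return self.rr_ms[self.nn_flags]

    def mean_hr_bpm(self) -> float:
        """Mean heart rate (bpm) over NN intervals: 60000 / mean(RR ms)."""
        nn = self.nn_ms
        if len(nn) == 0:
            return float("nan")
        return 60000.0 / float(np.mean(nn))


def _half_window(window_ms: float, fs: float) -> int:
    return max(1, int(round(window_ms * fs / 2000.0)))


def _as_sorted_unique(peaks) -> np.ndarray:
    return np.unique(np.asarray(peaks, dtype=np.intp))


def build_templates(
    x: np.ndarray,
    peaks,
    fs: float,
    window_ms: float = 300.0,
    trim_fraction: float = 0.2,
) -> tuple[BeatTemplate | None, BeatTemplate | None]:
    """Build positive and "negative" trimmed-average beat templates.

    Each beat's symmetric ``window_ms`` window is z-normalized (subtract
    mean, divide by sd).  A beat is classed *negative* — an RS-complex whose
    S-wave dominates, or a missing R — when |min| > |max| in its normalized
    window.  Per class with at least 3 members, the template is the pointwise
    ``trim_fraction``-trimmed mean (trimming that fraction from each tail),
    so isolated corrupted beats do not distort the template.

    Returns ``(positive, negative)``; a class with fewer than 3 beats yields
    ``None`` for that slot (with a warning).
    """
    x = np.asarray(x, dtype=float)
    peaks = _as_sorted_unique(peaks)
    half = _half_window(window_ms, fs)
    pos, neg = [], []
    for p in peaks:
        if p - half < 0 or p + half + 1 > len(x):
            continue
        w = x[p - half : p + half + 1]
        sd = np.std(w)
        if sd == 0:
            continue
        z = (w - np.mean(w)) / sd
        (neg if abs(z.min()) > abs(z.max()) else pos).append(z)

    def _make(beats: list, label: str) -> BeatTemplate | None:
        if len(beats) < 3:
            if beats:
                warnings.warn(
                    f"only {len(beats)} {label} beats: no {label} template", stacklevel=3
                )
            return None
        tmpl = stats.trim_mean(np.vstack(beats), trim_fraction, axis=0)
        return BeatTemplate(
            samples=tmpl,
            window_ms=window_ms,
            r_offset=half,
            polarity_class=label,
            n_beats=len(beats),
        )

    return _make(pos, "positive"), _make(neg, "negative")


def _zscore(w: np.ndarray) -> np.ndarray | None:
    sd = np.std(w)
    if sd == 0:
        return None
    return (w - np.mean(w)) / sd


def xcorr_correct(
    x: np.ndarray,
    peaks,
    template: BeatTemplate,
    fs: float,
    max_lag_ms: float = 150.0,
) -> np.ndarray:
    """Re-locate each annotation to the lag of highest template correlation.

    For every beat, the z-normalized window around each candidate lag in
    ±``max_lag_ms`` is correlated with the template; the annotation moves by
    the argmax lag (plus the template's r_offset displacement from center).
    Beats whose search window would cross the record edge are left unmoved.
    Two relocated beats colliding within the 200 ms refractory keep the one
    with the higher correlation.
    """
    x = np.asarray(x, dtype=float)
    peaks = _as_sorted_unique(peaks)
    tmpl = np.asarray(template.samples, dtype=float)
    L = len(tmpl)
    half = (L - 1) // 2
    shift = template.r_offset - half
    maxlag = max(1, int(round(max_lag_ms * fs / 1000.0)))
    out: list[tuple[int, float]] = []
    for p in peaks:
        lags = np.arange(-maxlag, maxlag + 1)
        lo = p + lags[0] - half
        hi = p + lags[-1] + half + 1
        if lo < 0 or hi > len(x):
            warnings.warn(f"beat at {p}: window clipped at record edge, left unmoved")
            out.append((int(p), -np.inf))
            continue
        best_corr, best_lag = -np.inf, 0
        for lag in lags:
            z = _zscore(x[p + lag - half : p + lag + half + 1])
            if z is None:
                continue
            c = float(np.dot(z, tmpl)) / L
            if c > best_corr or (c == best_corr and abs(lag) < abs(best_lag)):
                best_corr, best_lag = c, int(lag)
        out.append((int(p) + best_lag + shift, best_corr))
    out.sort()
    refr = int(round(REFRACTORY_S * fs))
    kept: list[tuple[int, float]] = []
    for idx, corr in out:
        if kept and idx - kept[-1][0] < refr:
            if corr > kept[-1][1]:
                kept[-1] = (idx, corr)
        else:
            kept.append((idx, corr))
    return np.asarray([i for i, _ in kept], dtype=np.intp)


def peak_convert(x: np.ndarray, peaks) -> np.ndarray:
    """Hill-climb each annotation on |x| to the nearest local extremum.

    If the annotation's absolute amplitude is larger than the previous
    sample's and smaller than the next's, the annotation slides forward until
    an extremum of |x|; in the mirrored case it slides backward.  Annotations
    already at a local extremum of |x| (and record edges) stay put, which
    makes the operation idempotent.
    """
    x = np.abs(np.asarray(x, dtype=float))
    peaks = _as_sorted_unique(peaks)
    n = len(x)
    out = []
    for p in peaks:
        q = int(p)
        if 0 < q < n - 1:
            if x[q] > x[q - 1] and x[q] < x[q + 1]:
                while q + 1 < n and x[q + 1] > x[q]:
                    q += 1
            elif x[q] < x[q - 1] and x[q] > x[q + 1]:
                while q - 1 >= 0 and x[q - 1] > x[q]:
                    q -= 1
        out.append(q)
    return _as_sorted_unique(out)


def max_search(
    x: np.ndarray,
    peaks,
    fs: float,
    window_ms: float = 300.0,
    mode: str = "max",
) -> np.ndarray:
    """Move each annotation to the extremum in a symmetric window.

    mode 'max' takes the maximum, 'min' the minimum, 'absolute' the sample of
    largest |x| within ±window_ms/2; ties resolve to the earliest sample.
    """
    if mode not in {"max", "min", "absolute"}:
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    peaks = _as_sorted_unique(peaks)
    half = _half_window(window_ms, fs)
    out = []
    for p in peaks:
        lo = max(0, int(p) - half)
        hi = min(len(x), int(p) + half + 1)
        seg = x[lo:hi]
        if mode == "max":
            q = lo + int(np.argmax(seg))
        elif mode == "min":
            q = lo + int(np.argmin(seg))
        else:
            q = lo + int(np.argmax(np.abs(seg)))
        out.append(q)
    return _as_sorted_unique(out)


def remove_ectopic(tachogram: Tachogram, alpha: float = 0.2) -> Tachogram:
    """Flag premature-beat interval pairs as not normal-to-normal.

    A beat is ectopic when its coupling interval is short and the following
    (compensatory / post-extrasystolic) interval is long relative to the
    local rhythm: RR(i-1) < (1-alpha)*m and RR(i) > (1+alpha)*m, with m the
    median of the up-to-5 nearest surrounding intervals.  Only ``nn_flags``
    change; every RR value is returned bit-identical.
    """
    rr = tachogram.rr_ms
    n = len(rr)
    if n < 6:
        warnings.warn("tachogram too short for ectopic detection; returned unchanged")
        return Tachogram(rr_ms=rr, beat_times_s=tachogram.beat_times_s,
                         nn_flags=tachogram.nn_flags.copy())
    flags = tachogram.nn_flags.copy()
    for i in range(1, n):  # beat between intervals i-1 and i
        ctx = []
        d = 1
        while len(ctx) < 5 and d < n:
            j = i - 1 - d
            if j >= 0:
                ctx.append(rr[j])
            if len(ctx) >= 5:
                break
            j = i + d
            if j < n:
                ctx.append(rr[j])
            d += 1
        if len(ctx) < 3:
            continue
        m = float(np.median(ctx[:5]))
        if rr[i - 1] < (1 - alpha) * m and rr[i] > (1 + alpha) * m:
            flags[i - 1] = False
            flags[i] = False
            logger.debug("ectopic beat flagged at interval pair (%d, %d)", i - 1, i)
    return Tachogram(rr_ms=rr, beat_times_s=tachogram.beat_times_s, nn_flags=flags)


class ConstraintError(ValueError):
    """A manual edit violates the ordering constraint between annotations."""


def add_peak(
    peaks,
    x: np.ndarray,
    fs: float,
    t_s: float,
    snap_ms: float = 300.0,
    polarity: str = "positive",
) -> np.ndarray:
    """Insert an annotation at the extremum of x within ±snap_ms/2 of t_s."""
    x = np.asarray(x, dtype=float)
    peaks = _as_sorted_unique(peaks)
    center = int(round(t_s * fs))
    if not 0 <= center < len(x):
        raise IndexError("add position outside the record")
    half = _half_window(snap_ms, fs)
    lo = max(0, center - half)
    hi = min(len(x), center + half + 1)
    seg = x[lo:hi]
    if polarity == "negative":
        q = lo + int(np.argmin(seg))
    elif polarity == "absolute":
        q = lo + int(np.argmax(np.abs(seg)))
    else:
        q = lo + int(np.argmax(seg))
    if q in peaks:
        warnings.warn(f"annotation at sample {q} already exists; add is a no-op")
        return peaks
    return _as_sorted_unique(np.append(peaks, q))


def move_peak(peaks, old: int, new: int) -> np.ndarray:
    """Relocate one annotation; it may not cross its neighbors."""
    peaks = _as_sorted_unique(peaks)
    pos = np.searchsorted(peaks, old)
    if pos >= len(peaks) or peaks[pos] != old:
        raise ValueError(f"no annotation at sample {old}")
    if pos > 0 and new <= peaks[pos - 1]:
        raise ConstraintError("move would cross the previous annotation")
    if pos < len(peaks) - 1 and new >= peaks[pos + 1]:
        raise ConstraintError("move would cross the next annotation")
    out = peaks.copy()
    out[pos] = new
    return _as_sorted_unique(out)


def delete_peaks(peaks, fs: float, t_start_s: float, t_end_s: float) -> np.ndarray:
    """Remove all annotations in the half-open time range [t_start_s, t_end_s)."""
    peaks = _as_sorted_unique(peaks)
    t = peaks / float(fs)
    return peaks[(t < t_start_s) | (t >= t_end_s)]


def edit_peaks(peaks, action: tuple, x: np.ndarray, fs: float, **kwargs) -> np.ndarray:
    """Dispatch a manual edit: ('add', t_s) | ('move', old, new) | ('delete', t0, t1)."""
    kind = action[0]
    if kind == "add":
        return add_peak(peaks, x, fs, action[1], **kwargs)
    if kind == "move":
        return move_peak(peaks, action[1], action[2])
    if kind == "delete":
        return delete_peaks(peaks, fs, action[1], action[2])
    raise ValueError(f"unknown edit action {kind!r}")
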