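"""R-peak detection on the flattened ECG.

Pipeline: flatten -> select_candidates -> adaptive_threshold
[-> postprocess_rr] -> refine_rpeaks -> tachogram.

Candidate selection is a three-stage rule on the flattened signal F:
(1) mark every sample whose amplitude is lower than the sample one step
(80 ms) further, which selects the upward slopes; (2) keep only marked runs
longer than the step, excluding small peaks; (3) per kept run, take the
maximum of F in a step-long window starting at the run's last marked sample.

The decision stage applies Pan–Tompkins adaptive thresholding to the
candidate amplitudes: running signal (SPKI) and noise (NPKI) peak estimates,
THR1 = NPKI + 0.25*(SPKI - NPKI), THR2 = THR1/2, a 200 ms refractory, and a
search-back at THR2 when a gap exceeds 1.66 times the running average of the
normal-to-normal RR intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .correction import Tachogram
from .envelope import FlattenedSignal, flatten

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "CandidateSet",
    "ThresholdState",
    "RPeakAnnotations",
    "select_candidates",
    "adaptive_threshold",
    "postprocess_rr",
    "refine_rpeaks",
    "detect_rpeaks",
]

REFRACTORY_S = 0.2  # minimum physiologic beat-to-beat spacing


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the detector.

    envelope_width_ms : secant-envelope window t (ms).  Wider windows merge
        closely-coupled beats (fewer false positives, more false negatives);
        narrower windows enhance more peaks.
    step_ms : step of the candidate-selection rule (ms).
    refine_ms : search radius on the original ECG around each flattened-signal
        peak; large S-waves can shift the peak in F away from the R apex.
    avg_hr_bpm : prior average heart rate used to seed the RR-interval
        averages before any beat has been accepted.
    post_process : enable RR-interval search-back / spurious-beat pruning.
    polarity : which extremum of the original ECG the R-peak is
        ('positive', 'negative', or 'absolute' for |x|).
    """

    envelope_width_ms: float = 300.0
    step_ms: float = 80.0
    refine_ms: float = 50.0
    avg_hr_bpm: float = 70.0
    post_process: bool = False
    polarity: str = "positive"

    def __post_init__(self) -> None:
        for name in ("envelope_width_ms", "step_ms", "refine_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 20 <= self.avg_hr_bpm <= 300:
            raise ValueError("avg_hr_bpm must be within [20, 300]")
        if self.polarity not in {"positive", "negative", "absolute"}:
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class CandidateSet:
    indices: np.ndarray
    amplitudes: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class ThresholdState:
    """Snapshot of the adaptive-threshold recursion after one decision."""

    SPKI: float
    NPKI: float
    THR1: float
    THR2: float
    rr_avg1: float
    rr_avg2: float
    rr_low: float
    rr_high: float
    rr_missed: float


@dataclass
class RPeakAnnotations:
    """Per-channel strictly increasing R-peak sample indices."""

    channels: list[np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        self.channels = [np.asarray(c, dtype=np.intp) for c in self.channels]
        for c in self.channels:
            if len(c) > 1 and np.any(np.diff(c) <= 0):
                raise ValueError("R-peak indices must be strictly increasing")
            if len(c) and (c[0] < 0):
                raise ValueError("R-peak indices must be nonnegative")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def _f_array(F) -> np.ndarray:
    if isinstance(F, FlattenedSignal):
        return F.F
    return np.asarray(F, dtype=float)


def select_candidates(F, fs: float, step_ms: float = 80.0) -> CandidateSet:
    """Three-stage candidate peak selection on the flattened signal."""
    f = _f_array(F)
    s = max(1, int(round(step_ms * fs / 1000.0)))
    n = len(f)
    if n <= s:
        warnings.warn("signal shorter than the step size: no candidates")
        return CandidateSet(np.empty(0, dtype=np.intp), np.empty(0))
    marked = f[: n - s] < f[s:]
    idx: list[int] = []
    i = 0
    m = len(marked)
    while i < m:
        if marked[i]:
            j = i
            while j + 1 < m and marked[j + 1]:
                j += 1
            if j - i + 1 > s:  # strict: runs longer than the step survive
                last = j
                w_end = min(last + s, n - 1)
                idx.append(last + int(np.argmax(f[last : w_end + 1])))
            i = j + 1
        else:
            i += 1
    indices = np.asarray(sorted(set(idx)), dtype=np.intp)
    return CandidateSet(indices=indices, amplitudes=f[indices])


def adaptive_threshold(
    candidates: CandidateSet,
    fs: float,
    avg_hr_bpm: float = 70.0,
    f: np.ndarray | None = None,
) -> tuple[np.ndarray, list[ThresholdState]]:
    """Pan–Tompkins adaptive thresholding over candidate peaks.

    Returns the accepted beat indices and the per-decision threshold trace so
    every constant of the recursion is auditable.  ``f`` (the flattened
    signal) seeds the initial noise estimate (NPKI = half the mean of F over
    the first 2 s); without it NPKI starts at 0.
    """
    idx = np.asarray(candidates.indices, dtype=np.intp)
    amp = np.asarray(candidates.amplitudes, dtype=float)
    if len(idx) == 0:
        return np.empty(0, dtype=np.intp), []

    warm = amp[idx < 2 * fs]
    SPKI = float(warm.max()) if len(warm) else float(amp[0])
    if f is not None and len(f):
        NPKI = 0.5 * float(np.mean(np.asarray(f)[: int(2 * fs)]))
    else:
        NPKI = 0.0
    NPKI = min(NPKI, SPKI)  # guard: noise estimate may not exceed signal estimate

    rr_avg1 = rr_avg2 = 60000.0 / avg_hr_bpm
    rr_buf: list[float] = []
    rr_sel: list[float] = []

    def thr1() -> float:
        return NPKI + 0.25 * (SPKI - NPKI)

    refr = REFRACTORY_S * fs
    accepted: list[int] = []
    skipped: list[int] = []  # candidate positions labelled noise since last beat
    trace: list[ThresholdState] = []

    def snapshot() -> None:
        trace.append(
            ThresholdState(
                SPKI=SPKI,
                NPKI=NPKI,
                THR1=thr1(),
                THR2=0.5 * thr1(),
                rr_avg1=rr_avg1,
                rr_avg2=rr_avg2,
                rr_low=0.92 * rr_avg2,
                rr_high=1.16 * rr_avg2,
                rr_missed=1.66 * rr_avg2,
            )
        )

    def push_rr(new_idx: int) -> None:
        nonlocal rr_avg1, rr_avg2
        if accepted:
            rr = (new_idx - accepted[-1]) * 1000.0 / fs
            rr_buf.append(rr)
            rr_avg1 = float(np.mean(rr_buf[-8:]))
            if 0.92 * rr_avg2 <= rr <= 1.16 * rr_avg2:
                rr_sel.append(rr)
                rr_avg2 = float(np.mean(rr_sel[-8:]))

    for k in range(len(idx)):
        i, a = int(idx[k]), float(amp[k])
        if accepted and (i - accepted[-1]) < refr:
            continue  # inside the refractory of the last beat
        # search-back: the expected beat did not arrive
        if accepted and (i - accepted[-1]) * 1000.0 / fs > 1.66 * rr_avg2 and skipped:
            gap = [p for p in skipped if accepted[-1] + refr <= idx[p] <= i - refr]
            if gap:
                best = max(gap, key=lambda p: amp[p])
                if amp[best] > 0.5 * thr1():
                    push_rr(int(idx[best]))
                    accepted.append(int(idx[best]))
                    SPKI = 0.25 * float(amp[best]) + 0.75 * SPKI
                    skipped = [p for p in skipped if idx[p] > idx[best]]
                    snapshot()
        if a > thr1():
            push_rr(i)
            accepted.append(i)
            SPKI = 0.125 * a + 0.875 * SPKI
            skipped = []
        else:
            NPKI = 0.125 * a + 0.875 * NPKI
            skipped.append(k)
        snapshot()

    logger.debug(
        "adaptive_threshold: %d/%d candidates accepted (final THR1=%.4g)",
        len(accepted), len(idx), thr1(),
    )
    return np.asarray(accepted, dtype=np.intp), trace


def _surrounding_median(rr: np.ndarray, i: int, k: int = 5) -> float:
    """Median of up to k RR intervals nearest to interval i, excluding i."""
    ctx: list[float] = []
    d = 1
    n = len(rr)
    while len(ctx) < k and d < n:
        if i - d >= 0:
            ctx.append(rr[i - d])
        if len(ctx) >= k:
            break
        if i + d < n:
            ctx.append(rr[i + d])
        d += 1
    return float(np.median(ctx[:k])) if ctx else float("nan")


def postprocess_rr(
    peaks,
    F,
    fs: float,
    thr2: float | None = None,
    max_passes: int = 3,
) -> np.ndarray:
    """Search-back correction of physiologically unreasonable RR intervals.

    Long intervals (> 1.8x the median of the 5 surrounding RR) trigger a
    search of F inside the gap for a peak above THR2, which is reinstated;
    short intervals (< 0.4x that median) delete the member of the pair with
    the smaller F amplitude.  Repeats to fixpoint, at most ``max_passes``.
    """
    f = _f_array(F)
    peaks = np.unique(np.asarray(peaks, dtype=np.intp))
    if len(peaks) < 3:
        warnings.warn("fewer than 3 peaks: RR post-processing skipped")
        return peaks
    if thr2 is None:
        thr2 = 0.25 * float(np.median(f[peaks]))
    refr = int(round(REFRACTORY_S * fs))
    for _ in range(max_passes):
        changed = False
        rr = np.diff(peaks) * 1000.0 / fs
        # insert missed beats in long gaps
        inserts = []
        for i in range(len(rr)):
            m = _surrounding_median(rr, i)
            if np.isfinite(m) and rr[i] > 1.8 * m:
                lo = peaks[i] + refr
                hi = peaks[i + 1] - refr
                if hi > lo:
                    q = lo + int(np.argmax(f[lo:hi]))
                    if f[q] > thr2:
                        inserts.append(q)
        if inserts:
            peaks = np.unique(np.concatenate([peaks, inserts]))
            changed = True
        # delete spurious beats forming too-short intervals
        rr = np.diff(peaks) * 1000.0 / fs
        drop = set()
        for i in range(len(rr)):
            m = _surrounding_median(rr, i)
            if np.isfinite(m) and rr[i] < 0.4 * m:
                a, b = peaks[i], peaks[i + 1]
                if a in drop or b in drop:
                    continue
                drop.add(a if f[a] < f[b] else b)
        if drop:
            peaks = np.asarray([p for p in peaks if p not in drop], dtype=np.intp)
            changed = True
        if not changed:
            break
    return peaks


def refine_rpeaks(
    x: np.ndarray,
    peaks_on_F,
    fs: float,
    refine_ms: float = 50.0,
    polarity: str = "positive",
) -> np.ndarray:
    """Relocate peaks from the flattened signal onto the original ECG.

    Each annotation moves to the extremum of x within ±refine_ms — the
    maximum for 'positive', minimum for 'negative', largest |x| for
    'absolute'; ties resolve to the earliest sample.  Peaks that collapse
    within the refractory afterwards are merged, keeping the larger extremum.
    """
    x = np.asarray(x, dtype=float)
    peaks = np.unique(np.asarray(peaks_on_F, dtype=np.intp))
    r = max(1, int(round(refine_ms * fs / 1000.0)))
    out: list[int] = []
    for p in peaks:
        lo = max(0, int(p) - r)
        hi = min(len(x), int(p) + r + 1)
        seg = x[lo:hi]
        if polarity == "negative":
            q = lo + int(np.argmin(seg))
        elif polarity == "absolute":
            q = lo + int(np.argmax(np.abs(seg)))
        else:
            q = lo + int(np.argmax(seg))
        out.append(q)
    refined = np.unique(out)
    # merge any pair driven inside the refractory by the relocation
    refr = int(round(REFRACTORY_S * fs))
    merged: list[int] = []
    for q in refined:
        if merged and q - merged[-1] < refr:
            keep = max(merged[-1], q, key=lambda i: abs(x[i]))
            merged[-1] = keep
        else:
            merged.append(int(q))
    return np.asarray(merged, dtype=np.intp)


def detect_rpeaks(
    record, config: DetectionConfig | None = None
) -> tuple[RPeakAnnotations, list[Tachogram]]:
    """Run the full detector on every channel of an ECG record.

    Returns per-channel R-peak annotations (sample indices into the record)
    and per-channel tachograms with RR intervals in milliseconds.
    """
    if config is None:
        config = DetectionConfig()
    fs = record.fs
    per_channel: list[np.ndarray] = []
    tachos: list[Tachogram] = []
    for ch, x in enumerate(record.channels):
        flat = flatten(x, fs, config.envelope_width_ms)
        cands = select_candidates(flat, fs, config.step_ms)
        accepted, trace = adaptive_threshold(cands, fs, config.avg_hr_bpm, f=flat.F)
        logger.debug("channel %d: %d candidates, %d accepted", ch, len(cands), len(accepted))
        if config.post_process and len(accepted) >= 3:
            thr2 = trace[-1].THR2 if trace else None
            accepted = postprocess_rr(accepted, flat, fs, thr2=thr2)
        peaks = refine_rpeaks(x, accepted, fs, config.refine_ms, config.polarity)
        per_channel.append(peaks)
        tachos.append(Tachogram.from_peaks(peaks, fs))
    return RPeakAnnotations(channels=per_channel, fs=fs), tachos
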