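"""Beat-matching evaluation: TP/FP/FN counts, sensitivity and PPV.

Detections are matched one-to-one to reference beats within a tolerance
window (default 150 ms, the ANSI/AAMI EC57 convention).  Because both lists
are sorted and compatibility is an interval condition, the sorted two-pointer
sweep below produces a maximum-cardinality matching: whenever the earliest
unmatched reference and test beats are compatible they can be matched without
loss of optimality (exchange argument), otherwise the earlier of the two can
never match anything later and is discarded.
"""

from __future__ import annotations

import glob
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import DetectionConfig, detect_rpeaks
from .formats import wfdb as _wfdb

__all__ = ["EvaluationResult", "match_beats", "se_ppv", "bench_mitbih"]


@dataclass
class EvaluationResult:
    """Beat-detection performance: counts plus Se and PPV in percent.

    Se or PPV is None when its denominator is zero (undefined metric),
    never NaN.
    """

    TP: int
    FP: int
    FN: int
    Se: float | None
    PPV: float | None


def match_beats(reference, test, fs: float, tol_ms: float = 150.0):
    """Match test beats to reference beats within ±tol_ms, one-to-one.

    Returns (TP, FP, FN).  Unmatched reference beats count as false
    negatives, unmatched test beats as false positives.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if np.any(np.diff(ref) < 0) or np.any(np.diff(tst) < 0):
        raise ValueError("beat lists must be sorted")
    tol = tol_ms * fs / 1000.0
    i = j = tp = 0
    while i < len(ref) and j < len(tst):
        d = tst[j] - ref[i]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            j += 1
        else:
            i += 1
    return tp, len(tst) - tp, len(ref) - tp


def se_ppv(TP: int, FP: int, FN: int) -> EvaluationResult:
    """Sensitivity and positive predictive value, in percent to two decimals.

    Se = 100*TP/(TP+FN); PPV = 100*TP/(TP+FP).  A zero denominator leaves
    the metric undefined (None).
    """
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be nonnegative")
    se = round(100.0 * TP / (TP + FN), 2) if TP + FN > 0 else None
    ppv = round(100.0 * TP / (TP + FP), 2) if TP + FP > 0 else None
    return EvaluationResult(TP=TP, FP=FP, FN=FN, Se=se, PPV=ppv)


def evaluate(reference, test, fs: float, tol_ms: float = 150.0) -> EvaluationResult:
    """match_beats followed by se_ppv."""
    tp, fp, fn = match_beats(reference, test, fs, tol_ms)
    return se_ppv(tp, fp, fn)


def bench_mitbih(
    directory,
    config: DetectionConfig | None = None,
    tol_ms: float = 150.0,
    beat_codes: frozenset = _wfdb.BEAT_CODES,
) -> pd.DataFrame:
    """Run the detector over a directory of WFDB records with annotations.

    For every ``*.hea`` record with a sibling ``.atr`` annotation file, the
    first channel is analysed and matched against the reference beats
    (annotation types outside ``beat_codes`` are ignored).  Returns a table
    with one row per record plus a pooled 'Total' row.  Records without
    annotations are skipped with a warning.
    """
    from .io import read_record  # avoid a module cycle

    if config is None:
        config = DetectionConfig()
    rows = []
    for hea in sorted(glob.glob(os.path.join(os.fspath(directory), "*.hea"))):
        name = os.path.splitext(os.path.basename(hea))[0]
        atr = os.path.join(os.path.dirname(hea), f"{name}.atr")
        if not os.path.exists(atr):
            warnings.warn(f"{name}: no annotation file, skipped")
            continue
        record = read_record(hea, format="wfdb", channel_selection=[0])
        truth = _wfdb.read_annotations(atr, beat_only=True, codes=beat_codes)
        annotations, _ = detect_rpeaks(record, config)
        res = evaluate(truth, annotations.channels[0], record.fs, tol_ms)
        rows.append(
            {
                "record": name,
                "total": len(truth),
                "TP": res.TP,
                "FP": res.FP,
                "FN": res.FN,
                "Se": res.Se,
                "PPV": res.PPV,
            }
        )
    df = pd.DataFrame(rows, columns=["record", "total", "TP", "FP", "FN", "Se", "PPV"])
    if len(df):
        pooled = se_ppv(int(df.TP.sum()), int(df.FP.sum()), int(df.FN.sum()))
        df.loc[len(df)] = {
            "record": "Total",
            "total": int(df.total.sum()),
            "TP": pooled.TP,
            "FP": pooled.FP,
            "FN": pooled.FN,
            "Se": pooled.Se,
            "PPV": pooled.PPV,
        }
    return df
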