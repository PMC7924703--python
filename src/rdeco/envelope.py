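"""Secant-method signal envelopes and the flattened ECG.

The QRS enhancement works by chaining *secant anchors*: starting from the
first sample, the next anchor of the upper envelope is the sample within a
forward window of width ``t`` (default 300 ms) that maximises the secant
slope ``(x[j] - x[a]) / (j - a)`` from the current anchor ``a``.  The lower
envelope uses the steepest *negative* slope (argmin).  Piecewise-linear
interpolation through the anchors gives the envelopes U and L, and

    F = max(U - L, 0)

is a nonnegative, baseline-free signal in which QRS complexes stand out as
isolated bumps: adding a constant or a linear trend to the input shifts every
secant slope by the same amount, so the anchor chain — and hence F — is
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["EnvelopePair", "FlattenedSignal", "secant_envelopes", "flatten"]


@dataclass
class EnvelopePair:
    """Upper/lower envelopes with the anchor indices where they touch x."""

    U: np.ndarray
    L: np.ndarray
    anchors_U: np.ndarray
    anchors_L: np.ndarray
    width_ms: float


@dataclass
class FlattenedSignal:
    """The flattened ECG F = max(U - L, 0).

    ``clipped_fraction`` is the fraction of samples where the piecewise-linear
    envelopes locally crossed (U < L between anchors) and F was raised to 0.
    """

    F: np.ndarray
    clipped_fraction: float = 0.0
    envelopes: EnvelopePair | None = field(default=None, repr=False)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.F)


def _window_samples(width_ms: float, fs: float) -> int:
    return max(1, int(round(width_ms * fs / 1000.0)))


def _anchor_chain(x: np.ndarray, W: int, sign: int) -> np.ndarray:
    """Chain of steepest-secant anchors.

    sign=+1 follows the steepest positive slope (upper envelope), sign=-1 the
    steepest negative slope (lower envelope).  Ties are broken toward the
    farthest sample so a linear ramp yields anchors exactly W apart and an
    envelope equal to the signal itself.
    """
    n = len(x)
    anchors = [0]
    a = 0
    while a < n - 1:
        hi = min(a + W, n - 1)
        seg = x[a + 1 : hi + 1]
        slopes = sign * (seg - x[a]) / np.arange(1, hi - a + 1)
        # argmax on the reversed array picks the *last* maximum
        rev = slopes[::-1]
        off = len(slopes) - 1 - int(np.argmax(rev))
        a = a + 1 + off
        anchors.append(a)
    return np.asarray(anchors, dtype=np.intp)


def secant_envelopes(x: np.ndarray, fs: float, width_ms: float = 300.0) -> EnvelopePair:
    """Compute upper and lower secant envelopes of a signal.

    Parameters
    ----------
    x : array-like
        Signal samples (mV for ECG, but any unit works).
    fs : float
        Sampling frequency in Hz.
    width_ms : float
        Envelope window length t in milliseconds (default 300 ms).

    Returns
    -------
    EnvelopePair
        Envelopes interpolate their anchors exactly; consecutive anchors are
        at most ``round(width_ms * fs / 1000)`` samples apart.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional sample sequence")
    if len(x) < 2:
        raise ValueError("envelope computation needs at least 2 samples")
    W = _window_samples(width_ms, fs)
    idx = np.arange(len(x))
    anchors_u = _anchor_chain(x, W, +1)
    anchors_l = _anchor_chain(x, W, -1)
    U = np.interp(idx, anchors_u, x[anchors_u])
    L = np.interp(idx, anchors_l, x[anchors_l])
    return EnvelopePair(U=U, L=L, anchors_U=anchors_u, anchors_L=anchors_l, width_ms=width_ms)


def flatten(x: np.ndarray, fs: float, width_ms: float = 300.0) -> FlattenedSignal:
    """Flatten a signal: F = max(U - L, 0) from the secant envelopes."""
    env = secant_envelopes(x, fs, width_ms)
    diff = env.U - env.L
    clipped = float(np.mean(diff < 0.0))
    if clipped > 0.0:
        logger.info("flatten: %.3f%% of samples clipped to 0", 100 * clipped)
    return FlattenedSignal(F=np.maximum(diff, 0.0), clipped_fraction=clipped, envelopes=env)
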