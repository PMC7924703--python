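"""Synthetic ECG generator with ground-truth R-peak locations.

Beats are sums of Gaussian waves (P, R with an optional S undershoot, T)
placed at RR intervals drawn from a truncated normal distribution, so the
true R-peak sample of every beat is known by construction.  Premature
(ectopic) beats are inserted with a 0.25*RR coupling interval and a full
compensatory pause (the pre- plus post-ectopic intervals sum to two normal
RR intervals), a widened QRS and no P wave — the pattern the ectopic-removal
corrector and the envelope-width trade-off are sensitive to.  Contaminants
(baseline wander, powerline interference, broadband noise at a target SNR)
are added after the truth is recorded; inversion negates the final signal.

This generator emulates morphology and rhythm, not conduction physiology:
real recordings add QRS shape variability, electrode artifacts and
non-stationary noise that no fixture here reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EcgRecord
from .formats import ishne as _ishne
from .formats import wfdb as _wfdb

__all__ = ["SyntheticSpec", "SyntheticEcg", "generate_ecg",
           "write_ishne_fixture", "write_wfdb_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic ECG.

    Amplitudes in mV, durations in seconds, rates in bpm.  ``noise_snr_db``
    of None disables broadband noise; baseline wander and powerline are
    (amplitude mV, frequency Hz) pairs with amplitude 0 disabling them.
    The seed fixes the output bit-exactly.
    """

    duration_s: float = 60.0
    fs: float = 360.0
    mean_hr_bpm: float = 70.0
    hr_sd_bpm: float = 3.0
    qrs_amplitude_mV: float = 1.0
    s_wave_ratio: float = 0.3
    ectopic_rate: float = 0.0
    baseline_wander: tuple[float, float] = (0.0, 0.25)
    powerline: tuple[float, float] = (0.0, 50.0)
    noise_snr_db: float | None = None
    inverted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if not 0 <= self.ectopic_rate <= 0.3:
            raise ValueError("ectopic_rate must be within [0, 0.3]")
        if not 20 <= self.mean_hr_bpm <= 300:
            raise ValueError("mean_hr_bpm must be within [20, 300]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class SyntheticEcg:
    record: EcgRecord
    truth_indices: np.ndarray
    beat_labels: list[str] = field(default_factory=list)


# Gaussian wave table: (amplitude factor of R, center offset s, width sd s)
_NORMAL_WAVES = [
    ("P", 0.15, -0.180, 0.025),
    ("R", 1.00, 0.000, 0.012),
    ("S", None, 0.035, 0.012),  # amplitude = -s_wave_ratio * R
    ("T", 0.30, 0.300, 0.060),
]
# ectopic: widened dome-like QRS without the sharp S undershoot, no P wave,
# inverted T — the classic broad PVC silhouette
_ECTOPIC_WAVES = [
    ("R", 0.75, 0.000, 0.030),
    ("T", -0.20, 0.330, 0.070),
]


def _add_beat(x: np.ndarray, fs: float, t_r: float, amp: float,
              s_ratio: float, ectopic: bool) -> None:
    n = len(x)
    waves = _ECTOPIC_WAVES if ectopic else _NORMAL_WAVES
    for _, a, mu, sd in waves:
        a = -s_ratio if a is None else a
        c = t_r + mu
        lo = max(0, int((c - 4 * sd) * fs))
        hi = min(n, int((c + 4 * sd) * fs) + 1)
        if hi <= lo:
            continue
        t = np.arange(lo, hi) / fs
        x[lo:hi] += amp * a * np.exp(-0.5 * ((t - c) / sd) ** 2)


def generate_ecg(spec: SyntheticSpec) -> SyntheticEcg:
    """Generate one synthetic ECG channel with ground-truth R-peaks."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    mean_rr = 60.0 / spec.mean_hr_bpm
    if mean_rr < 0.35:
        raise ValueError(
            f"mean RR {mean_rr:.2f} s is too short for the beat morphology: "
            "beats would overlap"
        )
    sd_rr = mean_rr * spec.hr_sd_bpm / spec.mean_hr_bpm

    # rhythm: beat times first, truth recorded before any contamination
    events: list[tuple[float, str]] = []
    t = 0.4
    while t < spec.duration_s - 0.4:
        events.append((t, "normal"))
        rr = float(np.clip(rng.normal(mean_rr, sd_rr), 0.6 * mean_rr, 1.5 * mean_rr))
        if spec.ectopic_rate > 0 and rng.random() < spec.ectopic_rate:
            t_ect = t + 0.25 * rr  # short coupling interval
            t_next = t + 2.0 * rr  # full compensatory pause
            if t_ect < spec.duration_s - 0.4 and t_next < spec.duration_s - 0.4:
                events.append((t_ect, "ectopic"))
                t = t_next
                continue
        t += rr

    n = int(round(spec.duration_s * fs))
    x = np.zeros(n)
    truth = []
    labels = []
    for t_beat, kind in events:
        # place the apex exactly on a sample so truth is the argmax
        idx = int(round(t_beat * fs))
        _add_beat(x, fs, idx / fs, spec.qrs_amplitude_mV, spec.s_wave_ratio,
                  kind == "ectopic")
        truth.append(idx)
        labels.append(kind)

    # contamination after the truth is fixed
    time = np.arange(n) / fs
    bw_amp, bw_freq = spec.baseline_wander
    if bw_amp:
        x = x + bw_amp * np.sin(2 * np.pi * bw_freq * time + rng.uniform(0, 2 * np.pi))
    pl_amp, pl_freq = spec.powerline
    if pl_amp:
        x = x + pl_amp * np.sin(2 * np.pi * pl_freq * time + rng.uniform(0, 2 * np.pi))
    if spec.noise_snr_db is not None:
        p_signal = float(np.var(x))
        p_noise = p_signal / 10 ** (spec.noise_snr_db / 10.0)
        x = x + rng.normal(0.0, np.sqrt(p_noise), n)
    if spec.inverted:
        x = -x

    record = EcgRecord(
        channels=x[np.newaxis, :],
        fs=fs,
        labels=["Synthetic ECG"],
        inverted=spec.inverted,
    )
    return SyntheticEcg(
        record=record,
        truth_indices=np.asarray(truth, dtype=np.intp),
        beat_labels=labels,
    )


def write_ishne_fixture(ecg: SyntheticEcg, path, resolution_nv: int = 1000) -> None:
    """Serialize a synthetic ECG as a standard-conformant ISHNE file."""
    _ishne.write(path, ecg.record.channels, ecg.record.fs, resolution_nv=resolution_nv)


def write_wfdb_fixture(ecg: SyntheticEcg, directory, name: str = "synth") -> str:
    """Write a WFDB record plus its truth annotations; returns the .hea path."""
    hea = _wfdb.write_record(directory, name, ecg.record.channels, ecg.record.fs)
    import os

    _wfdb.write_annotations(os.path.join(os.fspath(directory), f"{name}.atr"),
                            ecg.truth_indices)
    return hea
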