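import numpy as np
import pytest

from rdeco.detection import (
    CandidateSet,
    DetectionConfig,
    adaptive_threshold,
    detect_rpeaks,
    postprocess_rr,
    refine_rpeaks,
    select_candidates,
)
from rdeco.envelope import flatten
from rdeco.evaluation import evaluate
from rdeco.io import EcgRecord

from oracles import brute_select_candidates

FS = 360.0


# ---------------------------------------------------------------- candidates

def test_no_candidates_on_flat_signal():
    assert len(select_candidates(np.zeros(2000), FS)) == 0


def test_one_candidate_per_triangular_bump():
    # ten clean bumps one second apart
    x = np.zeros(int(10.5 * FS))
    apices = (np.arange(10) * FS + 180).astype(int)
    tri = 1.0 - np.abs(np.arange(-20, 21)) / 20.0
    for a in apices:
        x[a - 20 : a + 21] = tri
    cands = select_candidates(x, FS, 80.0)
    assert len(cands) == 10
    np.testing.assert_array_equal(cands.indices, apices)


def test_ramp_then_plateau_yields_single_candidate_at_onset():
    fs = 250.0  # s = 20 samples
    x = np.concatenate([np.linspace(0, 1, 300), np.full(200, 1.0)])
    cands = select_candidates(x, fs, 80.0)
    assert len(cands) == 1
    # the ramp top (first sample attaining the plateau value) wins the window
    assert cands.indices[0] == 299
    from oracles import brute_select_candidates
    assert cands.indices.tolist() == brute_select_candidates(x, 20)


def test_signal_shorter_than_step_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        cands = select_candidates(np.ones(10), FS, 80.0)
    assert len(cands) == 0


def test_select_candidates_matches_brute_force_oracle(rng):
    s = int(round(80.0 * FS / 1000.0))
    for _ in range(100):
        n = int(rng.integers(50, 800))
        kind = rng.integers(3)
        if kind == 0:
            f = np.abs(rng.normal(size=n))
        elif kind == 1:
            f = np.abs(rng.normal(size=n).cumsum())
        else:  # bumpy: sparse positive spikes smoothed
            f = np.convolve(rng.random(n) < 0.02, np.hanning(25), mode="same")
        got = select_candidates(f, FS, 80.0).indices.tolist()
        assert got == brute_select_candidates(f, s)


# ------------------------------------------------------------- thresholding

def _train(times_s, amps, fs=100.0):
    idx = np.asarray([int(round(t * fs)) for t in times_s], dtype=np.intp)
    return CandidateSet(indices=idx, amplitudes=np.asarray(amps, dtype=float)), fs


def test_regular_equal_amplitude_train_fully_accepted():
    cands, fs = _train(np.arange(20.0), np.ones(20))
    accepted, trace = adaptive_threshold(cands, fs, avg_hr_bpm=60)
    assert len(accepted) == 20
    final = trace[-1]
    assert final.NPKI <= final.THR1 <= final.SPKI
    assert final.THR2 == pytest.approx(0.5 * final.THR1)


def test_small_midway_candidate_rejected_as_noise():
    times = list(np.arange(20.0)) + [10.5]
    amps = [1.0] * 20 + [0.05]
    order = np.argsort(times)
    cands, fs = _train(np.asarray(times)[order], np.asarray(amps)[order])
    accepted, _ = adaptive_threshold(cands, fs, avg_hr_bpm=60)
    assert len(accepted) == 20
    assert int(round(10.5 * fs)) not in accepted


def test_search_back_recovers_low_amplitude_beat():
    # 1 s rhythm; the beat at t=5 s has 40% amplitude and is first rejected
    # (noise floor seeded at NPKI=0.25 via F), then the >1.66*RRavg gap at the
    # next beat triggers the THR2 search-back which recovers it.
    times = np.arange(11.0)
    amps = np.where(times == 5.0, 0.4, 1.0)
    cands, fs = _train(times, amps)
    f = np.full(int(11 * fs) + 1, 0.5)  # NPKI warm-up = 0.5 * mean = 0.25
    accepted, _ = adaptive_threshold(cands, fs, avg_hr_bpm=60, f=f)
    assert int(5 * fs) in accepted
    assert len(accepted) == 11


def test_empty_candidates_give_empty_output():
    cands = CandidateSet(np.empty(0, dtype=np.intp), np.empty(0))
    accepted, trace = adaptive_threshold(cands, FS)
    assert len(accepted) == 0 and trace == []


# ----------------------------------------------------------- post-processing

def _bumpy_f(peak_samples, n, height=1.0):
    f = np.zeros(n)
    for p in peak_samples:
        f[p] = height
    return f


def test_postprocess_reinstates_missed_beat_in_long_gap():
    fs = 100.0
    full = np.arange(0, 1100, 100)
    detected = np.delete(full, 5)  # 2 s gap at t=5
    f = _bumpy_f(full, 1200)
    out = postprocess_rr(detected, f, fs)
    np.testing.assert_array_equal(out, full)


def test_postprocess_removes_spurious_close_peak():
    fs = 100.0
    true = np.arange(0, 1100, 100)
    spurious = 415  # 150 ms after a true beat
    f = _bumpy_f(true, 1200)
    f[spurious] = 0.5
    out = postprocess_rr(np.sort(np.append(true, spurious)), f, fs)
    np.testing.assert_array_equal(out, true)


def test_postprocess_is_identity_on_clean_rhythm():
    fs = 100.0
    peaks = np.arange(0, 1100, 100)
    out = postprocess_rr(peaks, _bumpy_f(peaks, 1200), fs)
    np.testing.assert_array_equal(out, peaks)


def test_postprocess_warns_below_three_peaks():
    with pytest.warns(UserWarning):
        out = postprocess_rr(np.array([0, 100]), np.ones(200), 100.0)
    np.testing.assert_array_equal(out, [0, 100])


# --------------------------------------------------------------- refinement

def _rs_complex(n, apex, s_depth=0.8):
    """R spike with a large S wave 40 ms later (fs=360)."""
    x = np.zeros(n)
    t = np.arange(n)
    x += 1.0 * np.exp(-0.5 * ((t - apex) / 4.0) ** 2)
    x -= s_depth * np.exp(-0.5 * ((t - apex - 14) / 4.0) ** 2)
    return x


def test_refine_moves_f_peak_back_to_r_apex():
    apex = 500
    x = _rs_complex(1000, apex)
    # the flattened-signal peak sits ~30 ms late, toward the S valley
    late = apex + int(0.030 * FS)
    out = refine_rpeaks(x, [late], FS, refine_ms=50.0, polarity="positive")
    assert out.tolist() == [apex]


def test_refine_fixed_point_and_polarities():
    apex = 300
    x = _rs_complex(800, apex)
    assert refine_rpeaks(x, [apex], FS).tolist() == [apex]
    out = refine_rpeaks(-x, [apex + 5], FS, polarity="absolute")
    assert out.tolist() == [apex]
    out = refine_rpeaks(-x, [apex + 5], FS, polarity="negative")
    assert out.tolist() == [apex]


# ------------------------------------------------------------- full pipeline

def test_clean_synthetic_ecg_detected_perfectly(clean_ecg):
    annotations, tachograms = detect_rpeaks(clean_ecg.record, DetectionConfig())
    res = evaluate(clean_ecg.truth_indices, annotations.channels[0],
                   clean_ecg.record.fs, tol_ms=100.0)
    assert res.Se == 100.0 and res.PPV == 100.0
    rr = tachograms[0].rr_ms
    assert np.all(rr > 200.0)
    # indices strictly increasing with > 200 ms spacing
    d = np.diff(annotations.channels[0])
    assert np.all(d * 1000.0 / clean_ecg.record.fs > 200.0)


def test_detection_invariant_under_linear_drift(clean_ecg):
    base, _ = detect_rpeaks(clean_ecg.record)
    t = np.arange(clean_ecg.record.n_samples) / clean_ecg.record.fs
    drifted = EcgRecord(clean_ecg.record.channels + 0.5 * t,
                        clean_ecg.record.fs)
    out, _ = detect_rpeaks(drifted)
    np.testing.assert_array_equal(base.channels[0], out.channels[0])


def test_detection_invariant_under_inversion_with_absolute_polarity(clean_ecg):
    base, _ = detect_rpeaks(clean_ecg.record)
    inverted = EcgRecord(-clean_ecg.record.channels, clean_ecg.record.fs)
    out, _ = detect_rpeaks(inverted, DetectionConfig(polarity="absolute"))
    np.testing.assert_array_equal(base.channels[0], out.channels[0])


def test_post_processing_trades_false_positives_for_false_negatives(noisy_ecg):
    res = {}
    for post in (False, True):
        ann, _ = detect_rpeaks(noisy_ecg.record, DetectionConfig(post_process=post))
        res[post] = evaluate(noisy_ecg.truth_indices, ann.channels[0],
                             noisy_ecg.record.fs, tol_ms=100.0)
    assert res[True].FP <= res[False].FP
    assert res[True].FN >= res[False].FN


def test_envelope_width_controls_premature_beat_detection(pvc_ecg):
    labels = np.asarray(pvc_ecg.beat_labels)
    ectopic = pvc_ecg.truth_indices[labels == "ectopic"]
    assert len(ectopic) >= 5
    tol = int(0.1 * pvc_ecg.record.fs)

    def detected_ectopics(width):
        ann, _ = detect_rpeaks(pvc_ecg.record,
                               DetectionConfig(envelope_width_ms=width))
        det = ann.channels[0]
        return sum(int(np.abs(det - t).min() <= tol) for t in ectopic)

    assert detected_ectopics(150.0) == len(ectopic)
    assert detected_ectopics(600.0) < len(ectopic)


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(envelope_width_ms=0)
    with pytest.raises(ValueError):
        DetectionConfig(avg_hr_bpm=10)
    with pytest.raises(ValueError):
        DetectionConfig(polarity="sideways")
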