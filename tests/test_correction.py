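import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdeco.correction import (
    ConstraintError,
    Tachogram,
    add_peak,
    build_templates,
    delete_peaks,
    edit_peaks,
    max_search,
    move_peak,
    peak_convert,
    remove_ectopic,
    xcorr_correct,
)

FS = 360.0


def _beat_train(n_beats=10, rr_s=1.0, apex_amp=1.0, s_depth=0.3, fs=FS, seed=None):
    """Identical Gaussian R-S beats at exact apices; returns (x, apices)."""
    n = int((n_beats + 1) * rr_s * fs)
    x = np.zeros(n)
    t = np.arange(n)
    apices = (np.arange(n_beats) * rr_s * fs + 0.5 * fs).astype(int)
    for a in apices:
        x += apex_amp * np.exp(-0.5 * ((t - a) / 4.0) ** 2)
        x -= s_depth * np.exp(-0.5 * ((t - a - 14) / 4.0) ** 2)
    if seed is not None:
        x += np.random.default_rng(seed).normal(0, 0.01, n)
    return x, apices


# ---------------------------------------------------------------- templates

def test_template_of_identical_beats_equals_one_normalized_beat():
    x, apices = _beat_train(10)
    pos, neg = build_templates(x, apices, FS)
    assert neg is None
    assert pos.polarity_class == "positive" and pos.n_beats == 10
    half = pos.r_offset
    w = x[apices[0] - half : apices[0] + half + 1]
    z = (w - w.mean()) / w.std()
    np.testing.assert_allclose(pos.samples, z, atol=1e-12)
    assert len(pos.samples) % 2 == 1


def test_trimmed_mean_excludes_a_corrupted_beat():
    x, apices = _beat_train(11)
    ref_pos, _ = build_templates(x, apices[:10], FS)
    x_bad = x.copy()
    x_bad[apices[10]] += 5.0  # spike on the 11th beat
    pos, _ = build_templates(x_bad, apices, FS, trim_fraction=0.2)
    np.testing.assert_allclose(pos.samples, ref_pos.samples, atol=1e-9)


def test_prominent_s_wave_classifies_negative():
    x, apices = _beat_train(10, apex_amp=0.3, s_depth=1.0)  # RS complex
    pos, neg = build_templates(x, apices, FS)
    assert pos is None
    assert neg is not None and neg.polarity_class == "negative"


# ----------------------------------------------------------------- xcorr

def test_xcorr_restores_jittered_annotations_exactly(rng):
    x, apices = _beat_train(12)
    template, _ = build_templates(x, apices, FS)
    jitter = rng.integers(-7, 8, size=len(apices))  # up to ~20 ms
    corrected = xcorr_correct(x, apices + jitter, template, FS)
    np.testing.assert_array_equal(corrected, apices)


def test_xcorr_zero_displacement_when_already_aligned():
    x, apices = _beat_train(12)
    template, _ = build_templates(x, apices, FS)
    corrected = xcorr_correct(x, apices, template, FS)
    np.testing.assert_array_equal(corrected, apices)
    # second pass moves nothing either
    np.testing.assert_array_equal(xcorr_correct(x, corrected, template, FS), apices)


def test_inverted_beat_correlates_worse_than_aligned_beats():
    x, apices = _beat_train(12)
    x_mod = x.copy()
    a = apices[5]
    x_mod[a - 54 : a + 55] = -x[a - 54 : a + 55]
    template, _ = build_templates(x_mod, np.delete(apices, 5), FS)
    half = template.r_offset

    def corr_at(p):
        w = x_mod[p - half : p + half + 1]
        z = (w - w.mean()) / w.std()
        return float(np.dot(z, template.samples)) / len(z)

    assert corr_at(apices[5]) < min(corr_at(p) for p in np.delete(apices, 5))


# ------------------------------------------------------------ peak_convert

def test_peak_convert_ascends_to_apex():
    x = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0])
    assert peak_convert(x, [1]).tolist() == [3]


def test_peak_convert_respects_absolute_extremum():
    x = np.array([0.0, -1.0, -2.0, -3.0, -2.0])
    assert peak_convert(x, [3]).tolist() == [3]


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_peak_convert_idempotent_on_random_signals(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=200).cumsum()
    peaks = np.sort(rng.choice(200, size=5, replace=False))
    once = peak_convert(x, peaks)
    np.testing.assert_array_equal(peak_convert(x, once), once)


# -------------------------------------------------------------- max_search

def test_max_search_finds_apex_and_trough():
    x, apices = _beat_train(5)
    off = apices + int(0.05 * FS)  # 50 ms to the right of each apex
    np.testing.assert_array_equal(max_search(x, off, FS, mode="max"), apices)
    troughs = max_search(x, apices, FS, mode="min")
    np.testing.assert_array_equal(troughs, apices + 14)  # the S valleys
    np.testing.assert_array_equal(
        max_search(np.abs(x), off, FS, mode="absolute"),
        max_search(np.abs(x), off, FS, mode="max"),
    )


def test_max_search_idempotent_on_beat_trains(rng):
    # each apex dominates its own +-150 ms window, so one pass reaches a
    # fixed point; verified over jittered annotations on noisy beat trains
    for seed in range(10):
        x, apices = _beat_train(8, seed=seed)
        peaks = np.unique(apices + rng.integers(-18, 19, len(apices)))
        for mode in ("max", "absolute"):
            once = max_search(x, peaks, FS, mode=mode)
            np.testing.assert_array_equal(max_search(x, once, FS, mode=mode), once)


# ----------------------------------------------------------- remove_ectopic

def test_constant_rhythm_has_no_ectopic_flags():
    tach = Tachogram.from_peaks(np.arange(0, 12000, 1000), 1000.0)
    out = remove_ectopic(tach)
    assert out.nn_flags.all()


def test_premature_pair_flagged_without_touching_rr_values():
    rr = np.array([1000.0] * 5 + [600.0, 1400.0] + [1000.0] * 5)
    times = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    tach = Tachogram(rr_ms=rr, beat_times_s=times)
    out = remove_ectopic(tach, alpha=0.2)
    expected = np.ones(len(rr), dtype=bool)
    expected[5] = expected[6] = False
    np.testing.assert_array_equal(out.nn_flags, expected)
    # bit-identity of every RR value
    assert out.rr_ms.tobytes() == rr.tobytes()
    # degenerate threshold flags nothing
    assert remove_ectopic(tach, alpha=1.0).nn_flags.all()


def test_short_tachogram_warns_and_returns_unchanged():
    tach = Tachogram.from_peaks(np.array([0, 1000, 2000]), 1000.0)
    with pytest.warns(UserWarning):
        out = remove_ectopic(tach)
    np.testing.assert_array_equal(out.rr_ms, tach.rr_ms)


def test_mean_hr_uses_only_nn_intervals():
    rr = np.array([1000.0] * 5 + [600.0, 1400.0] + [1000.0] * 5)
    times = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    out = remove_ectopic(Tachogram(rr_ms=rr, beat_times_s=times))
    assert out.mean_hr_bpm() == pytest.approx(60.0)


# ------------------------------------------------------------- manual edits

def test_add_snaps_to_nearby_apex():
    x, apices = _beat_train(5)
    target = apices[2]
    peaks = np.delete(apices, 2)
    t_click = (target - int(0.03 * FS)) / FS  # 30 ms off the apex
    out = add_peak(peaks, x, FS, t_click)
    np.testing.assert_array_equal(out, apices)
    with pytest.warns(UserWarning):  # duplicate add is a no-op
        again = add_peak(out, x, FS, target / FS)
    np.testing.assert_array_equal(again, apices)


def test_move_is_bounded_by_neighbors():
    peaks = np.array([100, 200, 300])
    out = move_peak(peaks, 200, 250)
    np.testing.assert_array_equal(out, [100, 250, 300])
    with pytest.raises(ConstraintError):
        move_peak(peaks, 200, 301)
    with pytest.raises(ConstraintError):
        move_peak(peaks, 200, 100)


def test_delete_range_and_tachogram_bookkeeping():
    fs = 100.0
    peaks = np.array([100, 200, 300, 400, 500])
    out = delete_peaks(peaks, fs, 2.0, 4.0)  # removes 200, 300 (half-open)
    np.testing.assert_array_equal(out, [100, 400, 500])
    tach = Tachogram.from_peaks(out, fs)
    assert len(tach.rr_ms) == 2


def test_edit_peaks_dispatcher():
    x, apices = _beat_train(5)
    assert len(edit_peaks(apices, ("delete", 0.0, 2.0), x, FS)) < len(apices)
    with pytest.raises(ValueError):
        edit_peaks(apices, ("teleport", 1), x, FS)


def test_corrections_preserve_sortedness_uniqueness_and_bounds(rng):
    x, apices = _beat_train(10, seed=3)
    template, _ = build_templates(x, apices, FS)
    jittered = np.unique(apices + rng.integers(-10, 11, len(apices)))
    for op in (
        lambda p: xcorr_correct(x, p, template, FS),
        lambda p: peak_convert(x, p),
        lambda p: max_search(x, p, FS),
    ):
        out = op(jittered)
        assert np.all(np.diff(out) > 0)
        assert out[0] >= 0 and out[-1] < len(x)
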