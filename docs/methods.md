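# Methods

This note documents the models, algorithms and numerical choices behind
`rdeco`, in the spirit of a package reference manual: what each stage
assumes, which parameters matter, and what the synthetic fixtures do and do
not demonstrate about real data.

## Envelope flattening

The pre-processing stage builds upper and lower signal envelopes by a
*secant* construction.  Starting at the first sample, the next anchor of
the upper envelope is the sample `j` within a forward window of `W =
round(width_ms · fs / 1000)` samples that maximizes the secant slope
`(x[j] − x[a])/(j − a)` from the current anchor `a`; the lower envelope
uses the minimizer.  Piecewise-linear interpolation through the anchors
gives U and L, and the flattened signal is `F = max(U − L, 0)`.

Design choices:

* **Windowing** is anchored forward from the current anchor, not centered;
  this is what makes the chain construction well-defined and O(n·W).
* **Tie-breaking** between equal secant slopes picks the farthest sample.
  Consequently a linear ramp yields U = L = x exactly and the anchor count
  is minimal on locally linear stretches.
* **Clipping at zero**: piecewise-linear envelopes can cross locally
  between anchors, so F is clipped at 0 and the clipped fraction is
  reported on the `FlattenedSignal`.  On clean signals it is 0; a nonzero
  value is informational, never fatal.
* **Baseline elimination**: adding a constant or a linear trend `b·i`
  shifts every secant slope by the same amount, so the anchor chains are
  unchanged and F is invariant.  The invariance is exact in exact
  arithmetic; in floating point the interpolation introduces round-off at
  the 1e-12 (constant) / 1e-9 (trend) level, which is what the tests
  assert.

The envelope width `t` (default 300 ms) is the detector's most influential
parameter.  It acts as an RR-interval filter: a width much larger than the
shortest expected RR interval merges closely-coupled beats into one bump of
F (premature beats are lost — fewer false positives, more false
negatives), while a very small width enhances non-QRS peaks as well
(the opposite trade-off).  Widths between 250 and 350 ms behave comparably
on normal rhythms; 150 ms resolves premature beats with 250 ms coupling
intervals that 600 ms demonstrably merges away (this pair of operating
points is exercised in the acceptance tests).

## Candidate selection and adaptive thresholding

Candidates are selected on F by a three-stage rule with step `s = round(80
ms · fs / 1000)`: (1) mark samples with `F[i] < F[i+s]` (upward slopes);
(2) keep maximal marked runs strictly longer than `s` (the strict
comparison is a deliberate choice; it excludes bumps of exactly one step);
(3) per run, take the argmax of F over the step-long window starting at the
run's last marked sample.  A brute-force restatement of these three passes
serves as the test oracle.

The decision stage is the Pan–Tompkins threshold recursion applied to
candidate amplitudes:

* accepted beat: `SPKI ← 0.125·a + 0.875·SPKI`;
* rejected (noise): `NPKI ← 0.125·a + 0.875·NPKI`;
* `THR1 = NPKI + 0.25·(SPKI − NPKI)`, `THR2 = THR1/2`;
* a 200 ms refractory after each accepted beat;
* search-back: when the gap since the last beat exceeds `1.66·RRavg2`, the
  largest rejected candidate in the gap above THR2 is accepted with the
  slower update `SPKI ← 0.25·a + 0.75·SPKI`;
* `RRavg1` is the mean of the last 8 RR intervals, `RRavg2` the mean of
  the last 8 falling within `[0.92, 1.16]·RRavg2`; both are seeded from a
  configurable prior heart rate (default 70 bpm), which is how the
  normal-to-normal boundaries are initialized before any beat exists.

Warm-up is deterministic: SPKI starts at the largest candidate amplitude in
the first 2 s, NPKI at half the mean of F over the first 2 s (0 when F is
not supplied to the standalone function).  Every decision appends a
`ThresholdState` snapshot, so all constants above are auditable from the
trace.  The slope-based T-wave discrimination of the original Pan–Tompkins
decision rules is *not* implemented; the envelope flattening already
suppresses T-waves on the fixtures used here, but this is a known fidelity
gap on real recordings with tall T-waves.

Optional RR post-processing re-examines the annotation series: an interval
longer than 1.8× the median of its 5 nearest neighbours triggers a search
of F inside the gap (a peak above THR2 is reinstated); an interval shorter
than 0.4× that median deletes whichever of its two endpoints has the
smaller F amplitude; the rules iterate to a fixpoint, at most 3 passes.
The 1.8/0.4 factors, the 5-interval median and the pass cap are this
package's concrete choices for a "physiologically unreasonable" interval.

Finally each accepted peak is relocated to the extremum of the original ECG
within ±50 ms (symmetric, earliest sample on ties), because a prominent
S-wave shifts the bump of F toward the S valley.  Polarity `positive`
(default) takes the maximum, `negative` the minimum, `absolute` the largest
|x| — the latter makes detection invariant under signal inversion.

## Correction operators

* **Templates**: each beat's symmetric 300 ms window is z-normalized; beats
  with |min| > |max| are classed "negative" (RS-complex / dominant S); per
  class with ≥ 3 members the template is the pointwise 20%-trimmed mean
  (20% cut from each tail), so isolated corrupted beats cannot distort it.
  The template's R position defaults to the window center and is
  adjustable.
* **Cross-correlation**: each beat's normalized window is correlated with
  the template over lags in ±150 ms (half the window); the annotation
  moves by the argmax lag.  Collisions within the 200 ms refractory keep
  the higher-correlation beat; beats whose window would cross the record
  edge stay unmoved.
* **Peak conversion** hill-climbs |x| from each annotation in the
  direction indicated by its two neighbouring samples, stopping at the
  first local extremum; a second application changes nothing.
* **Maximum search** jumps to the extremum (max/min/|x|) within a
  symmetric 300 ms window.  It is idempotent on beat-like signals, where
  each apex dominates its own window — not on arbitrary signals, where the
  re-centered window can expose a larger sample (a documented limitation,
  and the reason peak conversion exists: it cannot "jump" to a
  neighbouring larger wave).
* **Ectopic flagging** marks a beat as ectopic when its coupling interval
  is `< (1−α)·m` and the following interval `> (1+α)·m` (α = 0.2, `m` the
  median of the 5 nearest surrounding intervals) — the premature +
  compensatory-pause signature.  Exactly that interval pair is flagged
  non-NN; RR values are returned bit-identical, so downstream HRV code
  masks rather than mutates.
* **Manual edits** are pure functions: `add` snaps to the configured
  extremum within ±150 ms, `move` may not cross neighbouring annotations,
  `delete` removes a half-open time range.

## Evaluation

Beats are matched one-to-one within a tolerance window, 150 ms by default
(the ANSI/AAMI EC57 convention; detection tests against synthetic truth use
the stricter 100 ms).  Because both lists are sorted and compatibility is
an interval condition, the two-pointer sweep (match when compatible,
otherwise discard the earlier of the two heads) attains maximum-cardinality
matching; tests verify equality with Hopcroft–Karp on random instances.
Se = 100·TP/(TP+FN) and PPV = 100·TP/(TP+FP) are reported to two decimals;
a zero denominator yields an explicit "undefined", never NaN.  The
WFDB benchmark harness scores the first channel of every annotated record
in a directory and appends a pooled-counts total row; by default only
beat-type annotations count as reference beats, and the annotation-type
filter is exposed.

## Synthetic fixtures

The generator builds beats from Gaussian waves (P at −180 ms, an R spike of
12 ms sd, an S undershoot, T at +300 ms) at RR intervals drawn from a
truncated normal (clipped to [0.6, 1.5]× the mean RR).  Defaults follow the
study conditions used throughout the tests: 360 Hz sampling, 70 bpm with
3 bpm spread, 1 mV QRS.  The canonical *clean* fixture is 5 minutes of this
signal with a 30 dB broadband-noise floor; on it the detector attains
Se = PPV = 100% at 100 ms tolerance and its annotations are unchanged by a
0.5 mV/s drift or by inversion (with absolute polarity).  At noticeably
lower SNR single-sample refinement shifts can appear at near-tied apex
samples, which is a float-level sensitivity of argmax refinement, not a
detection failure.

Premature beats are inserted at a 0.25·RR coupling interval with a full
compensatory pause (pre + post = 2·RR), a widened dome-like QRS at 0.75
amplitude without the sharp S undershoot, no P wave, and an inverted T —
chosen so the premature beat is both the one a too-wide envelope merges
away and the pattern the ectopic flagger keys on.  Baseline wander and
powerline interference are single sinusoids; broadband noise is white
Gaussian at a target SNR relative to the constructed signal's variance.

What passing these fixtures does **not** show: robustness to electrode
motion artifacts, non-stationary noise, QRS morphology change over time,
atrial fibrillation or other rhythms beyond isolated premature beats, and
multi-lead disagreement.  The external WFDB benchmark harness exists
precisely for such validation on real recordings (e.g. the MIT/BIH
arrhythmia database), which must be obtained separately.

## File formats

* **ISHNE-Holter**: 8-byte magic, CRC-CCITT over the 512-byte fixed
  header, optional comment block, little-endian int16 samples interleaved
  by lead; per-lead amplitude resolution in nanovolts converts samples to
  mV.  The CRC is verified but only warned about, since files in the wild
  often carry stale checksums.  The writer defaults to 1000 nV resolution
  (±0.0005 mV worst-case quantization over a ±32 mV range).
* **EDF**: ASCII headers, int16 data records; physical values are
  recovered from each signal's calibration and converted to mV when the
  physical dimension is a recognizable voltage unit.  Channels selected
  together must share one sampling rate; resampling is out of scope by
  design.
* **WFDB**: header parsing plus signal formats 16 and 212 and MIT-format
  annotations (including SKIP/AUX/NUM/SUB/CHN records); the format-16
  writer and annotation writer exist so the benchmark harness can be
  exercised without any download.
* **Text/CSV**: one column per channel, comma/semicolon/tab/space
  delimited, optional header row; the sampling frequency must be supplied.
* **Sessions** are versioned JSON documents (schema version 1) that
  round-trip the detection config, filter list, analysis window and
  per-channel peaks field-by-field; a version mismatch or truncated file
  is an explicit schema error, never a silent partial load.
* Exports are CSV (a summary file plus one re-readable table per channel)
  or a single JSON document; mean heart rate is 60000/mean(RR ms) over
  NN intervals.

Conventions everywhere: 0-based sample indices, half-open time windows,
ms→samples conversion rounds to nearest with a minimum of one sample.

## Filters

High-pass: zero-phase Butterworth of design order 2; low-pass: order 4;
notch: IIR notch with Q = 30 by default (the narrowness needed for
powerline removal without touching QRS energy).  Forward–backward
application doubles the effective order and cancels phase delay; the stated
orders describe the underlying design.  Filters are intended to be applied
to the caller's pristine original samples so repeated filter exploration is
reproducible.  The Welch spectrum uses 500-sample Hamming-tapered,
mean-detrended segments with 60% overlap; segment length and overlap are
configurable.

## Problem sizes and determinism

Test fixtures range from seconds-long constructed signals to the 5-minute
clean fixture; oracle-equivalence tests run 100 random signals (candidate
selection) and 200 random instances (beat matching).  These sizes keep the
full suite in the low seconds while exercising every code path; all
randomness flows through explicit integer seeds, and a fixed seed makes the
generator — and therefore every detection run — bit-reproducible.
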