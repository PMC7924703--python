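# rdeco

Scriptable R-peak detection and correction for ECG signals: a full
raw-ECG → tachogram workflow built around an envelope-based QRS detector,
with no GUI required.

## Who this is for

Researchers and clinicians who need reliable R-peak annotations as the
starting point for HRV, beat-to-beat variability or ECG-derived respiration
analyses — and who need to script the detection, audit every threshold
decision, and correct individual annotations reproducibly.

## The method

The detector works in three steps:

1. **Pre-processing (envelope flattening).** Upper and lower envelopes
   *U* and *L* are built by the secant method: from each anchor sample the
   next anchor is the sample within a window of length *t* (default 300 ms)
   with the steepest positive (for *U*) or negative (for *L*) secant slope
   (x[j] − x[a])/(j − a).  The flattened signal

   F = max(U − L, 0)

   is nonnegative and baseline-free (a constant or linear trend shifts all
   secant slopes equally), and QRS complexes stand out as isolated bumps.
2. **Decision.** Candidate peaks of F are selected by a three-stage rule
   (samples lower than the sample 80 ms ahead → upward slopes; only slopes
   longer than the step survive; the maximum in a step-long window after
   each slope becomes the candidate).  Candidates then pass Pan–Tompkins
   adaptive thresholding: running signal/noise estimates SPKI and NPKI,
   THR1 = NPKI + 0.25·(SPKI − NPKI), a 200 ms refractory, and a search-back
   at THR2 = THR1/2 when an expected beat fails to appear within
   1.66 times the running normal-RR average.
3. **Post-processing.** Optional RR-interval search-back/pruning, then each
   peak is relocated to the extremum of the *original* ECG within ±50 ms,
   because a large S-wave can shift the flattened-signal peak away from the
   R apex.

Correction operators (template cross-correlation with a trimmed-average
QRS, peak conversion, windowed maximum search, add/move/delete, ectopic
flagging that masks — never edits — RR intervals), a tolerance-windowed
beat-matching evaluator (Se = TP/(TP+FN), PPV = TP/(TP+FP)), a synthetic
ECG generator with ground-truth R-peaks, and readers/writers for
ISHNE-Holter, EDF, delimited text and WFDB records round out the package.

## Worked example

```sh
rdeco synth --duration 60 --fs 360 --hr 70 --noise-snr 30 --seed 1 \
      --out ecg.csv --truth truth.csv
# -> 70 beats written to ecg.csv
rdeco detect ecg.csv --fs 360 --out peaks.csv
# -> 70 beats detected across 1 channel(s)
rdeco eval --ref truth.csv --test peaks_ch1.csv --fs 360 --tol-ms 100
# -> TP=70 FP=0 FN=0 Se=100.00% PPV=100.00%
```

The first command synthesizes one minute of 70 bpm ECG at 360 Hz with a
30 dB broadband-noise floor and writes both the signal and the true R-peak
locations.  `detect` runs the envelope detector with its defaults (300 ms
envelope, 80 ms step, ±50 ms refinement) and writes a per-channel table of
R-peak samples, times and RR intervals; all 70 beats are found.  `eval`
matches detections to the truth one-to-one within 100 ms: every beat is a
true positive, so sensitivity and positive predictive value are both 100%.

The same workflow applies to real recordings
(`rdeco detect holter.ecg --out peaks.csv`), optionally preceded by the
built-in zero-phase filters (`--highpass 0.66`, `--lowpass 40`,
`--notch 50`) and an analysis window (`--start`/`--duration`).
`rdeco correct` applies one correction operator to an existing annotation
set, and `rdeco bench-mitbih DIR --out table.csv` scores the detector
against reference annotations for any directory of WFDB records, such as a
locally downloaded copy of the MIT/BIH arrhythmia database.

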