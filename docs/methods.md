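# Methods

## Processing model

A recording is a time-aligned pair: one ECG channel and a map of
accelerometer (SCG) channels indexed by (patch, axis), all at a common
sampling rate (records are typically downsampled to 1 kHz with polyphase
anti-aliased decimation before analysis; the downsampling method is our
choice — any correctly anti-aliased decimator would do). Episode windows
are half-open `[start, start + episode_s)` with 0-based sample indexing;
random episode starts are drawn uniformly from the feasible range with a
seeded generator, and non-overlapping placement is preferred whenever it
fits (overlap is allowed with a warning otherwise, or forced/forbidden via
a flag — the sampling policy is deliberately exposed because nothing in
the problem pins it down).

### Preprocessing

All cleanup stages are applied **zero-phase**: forward–backward
application for recursive (Butterworth) filters, odd-length symmetric
kernels for FIR and smoothing stages. Beat-interval analysis depends on
peak *times*; any phase lag would bias JJ intervals relative to RR, so
zero-phase application is a hard design constraint, verified by the
contract that a symmetric pulse's argmax moves at most 1 sample through
any pipeline. Edge effects are handled by 1 s of reflect padding, trimmed
after filtering, so 60-s episodes do not lose boundary beats. Filters are
re-designed per signal sampling rate with cutoffs fixed in Hz. The
powerline stage is a rectangular moving average over exactly one mains
period (fs/50 samples), which nulls the 50 Hz fundamental and all its
harmonics. The FIR bandpass uses a Hamming window with tap count
round(0.3·fs), forced odd so the group delay is an integer and exactly
compensable. Designed Butterworth stages are checked against the analytic
magnitude formula: −3.01 dB at each corner, and the bilinear-prewarped
rolloff elsewhere.

### Sliding-window maximum detection

Sample *i* is a beat iff it is the maximum of the window of width
`window_ms` (default 400 ms) centered on it. Ties: a strict maximum is
required against the trailing half-window and a non-strict one against
the leading half-window, so a plateau of equal maxima yields its earliest
sample — the closest deterministic reading of "highest point in the
window, not the first high point". Edge samples with incomplete windows
never fire. The vectorised implementation (two running-maximum passes) is
required to be output-identical to a literal per-index brute-force oracle;
this equivalence is a test, not an assumption. The full variant adds the
original post-detection: candidate peaks below `amplitude_fraction`
(default 0.4) times the running mean of accepted peak amplitudes are
rejected, and a peak is interpolated at the midpoint of any inter-peak gap
exceeding 1.5× the median accepted interval. Both constants are exposed
in `DetectorConfig`; only their existence, not their values, is fixed by
the method's description, so they are configuration, not contract.

The comparison detectors (derivative–squaring–integration with adaptive
dual thresholds; rectified-envelope adaptive thresholding; two
moving-average block detection; absolute-gradient steepness) follow their
classical descriptions with the constants stated in their docstrings
(150 ms integration window, 200 ms refractory, search-back at 1.66× the
running average interval, 97/611 ms moving averages, etc.). Two numerical
choices matter: all thresholds are proportional to signal statistics, so
every detector is invariant to amplitude rescaling; and the gradient
detector's threshold carries a floor of 64·eps·max(envelope) so that
numerically silent stretches (exact zeros plus float dust) never activate
— degenerate all-zero inputs must return empty trains.

The probabilistic combiner convolves each method's binary detection train
with a Gaussian (σ default 10 ms), accumulates across methods, normalises
to max 1, and keeps local maxima above the threshold.

### Matching and scores

J-peaks are trimmed to the half-open reference span `[first R, last R)`;
within each RR interval `[R_i, R_{i+1})` the first contained J-peak is a
TP, later ones FP, an empty interval FN. No tolerance window after the
R-peak is applied: for heart-rate agreement only the interval hit matters.
The counts satisfy TP+FN = #intervals and TP+FP = #retained J-peaks by
construction; a brute-force containment enumeration is kept as the test
oracle. Whether "deleting J-peaks after the last R-peak" also discards the
final reference peak is ambiguous; the half-open-span reading is the
default and the alternative (`drop_last_reference=True`) is a switch.
Precision and recall are reported in percent, F1 on [0, 1]; with zero
retained J-peaks precision is undefined and reported as 0 with a warning
flag. HR = 60·(n−1)·fs/(last − first) — i.e. 60 s over the mean
beat-to-beat interval — and the HR difference is the absolute value.
RR-vs-JJ interval precision pairs intervals in order after trimming,
drops trailing unpaired ones, and reports the count dropped.

The grid harness crosses pipelines × detectors × seeded episodes ×
records, never aborts on a failing combination (the failure becomes a
missing episode; an all-failed row is flagged), and ranks rows by mean
absolute HR difference, ascending.

### Channel selection and morphology

Every (patch, axis) is scored either by |HR_SCG − HR_ECG| (needs ECG) or
by the SDNN of the detected JJ train (ECG-free); the argmin wins, ties
resolving to the lexicographically smallest channel id, visibly marked in
the report. SDNN is the **population** standard deviation of successive
intervals in ms (HRV-tooling convention; the sample/population difference
is negligible beyond ~100 beats). No "normal-interval" ectopy exclusion
is applied — there is no principled rule to apply, and users should know
the estimate is of raw, not artifact-cleaned, variability. Averaged beats
stack `[anchor − pre, anchor + post)` windows (defaults 200/600 ms,
covering the systolic and diastolic complexes) without amplitude
normalisation; anchors with incomplete windows are excluded and counted.

## Synthetic generator

The generator emulates a seated lab recording with two accelerometer
patches × three axes plus ECG at 1 kHz. Beat times are Gaussian intervals
(mean 60/HR s, sd = SDNN, floored at 300 ms); ECG gets 20 ms triangular
R-spikes and small Gaussian T-bumps. Each SCG channel receives, per beat,
a systolic and a diastolic complex — an exponentially damped 15 Hz
sinusoid — at latencies 100 ms and 450 ms after R (shared per-beat jitter,
sd 2 ms at rest), scaled by per-channel (systolic, diastolic) gains, plus
a 0.25 Hz respiration sinusoid (amplitude 0.3), white noise (sd 0.01 of
systolic amplitude, per-channel overridable), and Poisson-scheduled 1–3 s
bursts of 5–35 Hz band-limited noise. The `interference` preset models
reading aloud: 12 bursts/min at 5× systolic amplitude and doubled timing
jitter.

Two generator choices deserve justification:

* **Wavelet decay 180 ms.** Real chest recordings oscillate continuously
  through the cardiac cycle; a centered-window-max detector exploits this,
  since any quiet stretch longer than the window lets arbitrarily small
  noise maxima fire. A fast-decaying wavelet would create an artificial
  silent diastole and an artificial failure mode. The slow tail keeps
  every inter-beat window dominated by beat energy, reproducing the regime
  in which this detector family is reported to work on real rest
  recordings.
* **A systolic-only channel (`patch1_z`).** An *isolated* diastolic
  complex is, to a window-max detector, indistinguishable from a beat —
  with a 400 ms window, any secondary complex more than 200 ms from the
  primary peak fires as a false positive per beat. Clean-recovery
  properties are therefore stated on the sternal z channel, whose
  diastolic gain is zero; the mixed channels exist precisely so channel
  selection has something non-trivial to do.

What the generator does **not** model: inter-subject morphology
variability, heteroscedastic motion artifacts, sensor saturation,
autoregressive HRV structure (only interval mean/sd matter to the
statistics under test), or respiratory modulation of complex amplitude.
Passing tests therefore demonstrate the correctness of the pipeline and
its statistics under controlled conditions, not field performance on real
patients.

## Problem sizes

The test suite and the acceptance script use 60-s episodes (the standard
evaluation unit), 20-seed Monte-Carlo batteries for recovery and
degradation properties, 300-s records for SDNN recovery (~350 beats),
400–1000 random instances for the oracle equivalences, and small
(2–3 × 2–3) grids on 200-s records for the harness contract. These sizes
give stable medians and tight Monte-Carlo bounds while keeping the whole
suite fast.

## Known limitations

* The WFDB reader covers single-segment format-16 records with one `.dat`
  file — sufficient for the CEBS database, not a general WFDB
  implementation.
* The ECG reference is itself detected (absolute-gradient detector on the
  0.5 Hz-highpass pipeline) unless an annotation train is supplied;
  reference errors propagate into all scores.
* Fiducial-point labelling of averaged beats (valve-event waves) is out of
  scope; the module exposes the traces for manual inspection only.
* The out-of-scope classical detectors (wavelet, visibility-graph,
  finite-state-machine families) are not implemented; the registry accepts
  them as plug-ins.
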