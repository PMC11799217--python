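# Methods

## Model and estimation

The package assumes the auditory cortex behaves as a linear time-invariant
system whose input is the speech envelope-onset signal and whose output is
the continuous recording: r(n) = Σ_m T(m) s(n−m) + e(n). The onset signal
is computed as band-limited (200–5000 Hz, zero-phase 2nd-order Butterworth)
Hilbert-envelope magnitude, low-passed at 10 Hz (zero-phase 2nd-order
Butterworth), resampled to the 128/s analysis rate, differentiated
(forward difference × rate, first sample 0) and half-wave rectified.
Recordings are band-passed 1–20 Hz (zero-phase 4th-order Butterworth) and
resampled to 128/s before estimation.

TRFs are estimated over lags −500…1000 ms (193 lags at 128/s) from a lagged
design matrix. Lags that would reach outside a trial are zero-padded within
the trial, so there is no cross-trial leakage, and the cue second at the
start of each two-stream trial is dropped row-wise after lagging. The ridge
penalty is λ·r̄·I with r̄ the mean diagonal of XᵀX, so the λ grid
(decade steps, 1e−6…1e10) is portable across data sizes; the intercept is
unpenalized and the penalty is the identity (not a derivative penalty), so
kernel amplitudes remain directly comparable across conditions, which the
component analysis relies on. Envelope regressors are used in natural units
(no z-scoring) for the same reason.

λ is selected by leave-one-trial-out cross-validation of held-out MSE on
single-stream (prime) data and reused for all of a subject's conditions.
Ties on the flat, fully-shrunk plateau (which arise whenever the response
contains no stimulus-locked signal) are broken by the one-standard-error
rule: the largest λ whose mean CV error is within one SE of the minimum.
One λ is selected per subject (configurable).

Peak latencies are estimated by resampling subjects with replacement 5000
times and taking the polarity-signed argmax of each resampled grand-average
kernel inside the search window; the mean and SD of those latencies are
reported.

## Source projection

Instead of dipole fitting with a head model, the package uses a transparent
algebraic spatial filter with the same role: the single-stream sensor
kernel restricted to the P1 window (50–100 ms) is SVD-decomposed separately
over left- and right-hemisphere channels; the two leading lateralized
singular vectors become forward topographies and their pseudo-inverse is
the sensor→source unmixing. The sign convention forces the P1 positive in
each source waveform. The filter is fitted once per subject on prime data
and reused unchanged for all conditions and for continuous data (encoding).
Both hemispheres are kept through the pipeline; averaging happens only at
the statistics stage (flag-controlled, on by default), mirroring the
practice of collapsing hemispheres when no hemisphere effects exist.

## Components, reliability, statistics

Component amplitudes are means over closed latency windows snapped to the
lag grid by rounding the window edges to the nearest sample: P1/N1/P2
(50–100/125–175/195–245 ms) for single-stream kernels; P1 (60–110 ms) and
Nd (150–250 ms) for two-stream kernels. Cronbach's α treats the 16 design
cells as items and participants as cases: α = k/(k−1)·(1 − Σ item
variances / variance of participant sums).

The mixed repeated-measures ANOVA is computed with per-subject contrast
scores, which is exact for balanced all-two-level designs: each within
effect's signed cell mean per subject is submitted to a one-way group
analysis, yielding the effect F (grand-mean test), the effect × group F
(group-difference test), and the matching subject-level error. With
two-level factors sphericity is moot and univariate and multivariate
statistics coincide. Every effect has df (1, N−2); partial η² =
SS_eff/(SS_eff+SS_err). Unequal group sizes are rejected rather than
approximated. The implementation is cross-checked in the test suite
against a hand-computed sums-of-squares decomposition and against
pingouin's mixed ANOVA on a one-within-factor design.

## Behavioral scoring

A press within (offset, offset + 2 s] of a target-stream word is a hit;
words claim presses earliest-word-first and each press is used at most
once, so later presses inside an already-claimed window are ignored rather
than counted as false alarms (the event tables do not disambiguate double
presses). False alarms are presses in the window of masker-stream words —
only those are scored, and the false-alarm opportunity count is the number
of masker-stream target words. Response times are press − word offset,
consistent with the window anchor. Perfect and empty rates are corrected
to (n−0.5)/n and 0.5/n before d′.

## Synthetic-scene generator

The generator emulates the two-speaker measurement situation, not speech
acoustics. Envelope-onset streams are gamma-renewal point processes
(shape 2, mimicking syllabic regularity; Poisson would under-disperse
inter-syllable intervals) at language-specific mean rates of 7.9/s
(German-like) and 6.6/s (Chinese-like), convolved with a one-sided
Gaussian pulse of ~30 ms support (σ = 10 ms). Ground-truth kernels are
Gaussian bumps — P1 (90 ms, +1.0), N1 (150 ms, −0.7), P2 (219 ms, +0.5) —
plus a smoothed 150–250 ms boxcar Nd (base −0.5) whose amplitude is
multiplied by 2.0 for attended streams and 1.5 for native-language
streams. Target trials last 7 s; the masker (6 s) starts 1 s later; trials
are separated by a 2-s gap so kernel tails cannot leak across trials.
Target-word events (0/1/2 per stream with probabilities 0.1/0.8/0.1, none
before 1 s, ≥2 s apart across streams, 0.4-s word duration) drive
word-evoked responses, and simulated presses (hit/false-alarm
probabilities, truncated-normal RT in 0.2–2.0 s) drive a press-evoked
response, so unmodeled event regressors demonstrably bias envelope
kernels. When both streams draw two words the separation constraint is
unsatisfiable in a 7-s trial, so the counts are redrawn; this slightly
censors the (2,2) combination in scene generation (the count-distribution
property is verified at a longer trial duration where all combinations
are feasible).

Sources are mixed into the sensor array through seeded unit-norm
topography columns supported on disjoint channel halves (standing in for
bilateral dipoles — no head model), with mild per-source stream gains.
Noise is 1/f^α (α = 1) plus a 10% white floor, scaled to a sensor-space
SNR in the 1–20 Hz band. What the generator does **not** emulate —
phonemes, acoustic fine structure, eye/muscle artifacts, head geometry,
sensor inhomogeneity — bounds what passing tests show: they validate the
estimation chain's correctness and calibration, not robustness to real
MEG artifact structure.

Cohorts draw lognormal subject amplitude jitter (σ = 0.2, a realistic
between-subject spread for evoked amplitudes) over the full 16-cell grid.
`mode="full"` generates sensor-space scenes per condition for end-to-end
estimation; `mode="kernels"` synthesizes per-subject source-kernel
estimates directly (truth × jitter + white kernel noise, SD 0.5 amplitude
units per hemisphere) and is used for power studies where running the full
estimator for hundreds of subjects would add nothing but runtime.

## Problem sizes and numerical choices

The validation suite uses scaled-down but structurally complete problems:
kernel-recovery runs use a 43-trial (~300 s of trial time) scene at the
full −500…1000 ms lag axis; most other simulation tests use a reduced
−100…450 ms axis that still contains every kernel component, 5–10 trials
per condition, and cohorts of 2–17 subjects per group. ANOVA type-I
calibration uses 2000 null replicates of a 10+10-subject one-within-factor
design (the finer Monte Carlo halves the standard error of the estimated
rate relative to 1000). Encoding folds are contiguous trial blocks by
default (a seeded random alternative exists); the 80/20 scheme needs at
least 5 trials. Degenerate inputs raise explicit errors rather than
warnings: singular designs at λ = 0, flat kernels in a latency window,
empty lambda grids, zero-variance series in correlations, incomplete or
unbalanced ANOVA tables.

## Known limitations

- No real-data readers beyond mono WAV and the package's own array
  containers; native MEG formats are out of scope.
- The spatial filter assumes hemisphere-labeled channels and exactly two
  sources; it is a stand-in for subject-specific dipole models, suitable
  for lateralized auditory responses only.
- The paper-style printed peak *rates* (7.9/s, 6.6/s) are generator inputs,
  not outputs; only count-based percent excess is treated as a checkable
  quantity, because total stimulus durations per language are not part of
  the stimulus-level arithmetic.
- Reliability coefficients (Cronbach's α) on synthetic cohorts reflect the
  generator's jitter-to-noise ratio and are property-tested (parallel rows
  → 1, independent noise → 0, monotone in shared variance) rather than
  matched to any empirical value.
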