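# cocktailtrf

Analysis toolkit for selective-attention experiments with two simultaneous
speech streams ("cocktail-party" listening) recorded with continuous M/EEG.
It is written for auditory cognitive neuroscientists who want a tested,
reusable implementation of the full chain from speech audio to group
statistics — and a synthetic-scene generator with known ground truth so that
every stage can be validated by parameter recovery instead of trust.

## What it computes

**Temporal response functions.** The continuous neural response is modeled
as a convolution of the speech envelope-onset signal with an unknown kernel,

    r(n) = Σ_m T(m) s(n − m) + e(n),

where `s(n)` is the half-wave-rectified first derivative of the low-passed
Hilbert envelope of the speech waveform, and `T(m)` is the temporal response
function (TRF) over lags −500…1000 ms. `T` is estimated per channel from a
lagged design matrix by ridge regression, `β = (XᵀX + λ r̄ I)⁻¹ Xᵀy`, with the
penalty scaled by the mean Gram diagonal `r̄` and λ selected by
leave-one-trial-out cross-validation on single-stream data. Target and
masker envelope-onset regressors are fitted jointly with unit-impulse
regressors for target-word onsets (per stream) and button presses.

**Source projection and components.** Sensor kernels are projected onto two
lateralized cortical sources by a P1-anchored spatial filter
(hemisphere-partitioned SVD of the kernel in the P1 window; unmixing =
pseudo-inverse of the topographies). Component amplitudes are window means
on the source kernels — P1/N1/P2 (50–100, 125–175, 195–245 ms) for
single-stream responses, P1 (60–110 ms) and the attention-related negativity
Nd (150–250 ms) for two-stream responses. Reliability across the 16 design
cells is summarized with Cronbach's α.

**Encoding accuracy.** Forward prediction ("neural tracking"): the Pearson
correlation between the TRF-convolved envelope and the held-out recorded
signal, averaged over five 80/20 cross-validation folds, separately for the
attended and the ignored stream; windowed variants zero the kernel outside
the P1 or Nd range.

**Behavior.** Button presses are scored against target-word events with a
2-s post-offset window; extreme rates are corrected ((n−0.5)/n, 0.5/n) and
sensitivity is d′ = z(H) − z(F).

**Group statistics.** A mixed repeated-measures ANOVA over the 2×2×2×2
within design (attention × language × consistency × priming) with listener
group (native language) as the between factor; every effect has df (1, N−2)
and effect size partial η² = SS_eff/(SS_eff + SS_err).

**Synthetic scenes.** The generator emulates the measurement situation:
gamma-renewal envelope-onset streams at language-specific peak rates (7.9/s
vs 6.6/s), a 7-s target starting 1 s before a 6-s masker, ground-truth
kernels with P1 (90 ms), N1 (150 ms), P2 (219 ms) and an Nd whose amplitude
is multiplied by an attention gain (2.0) and a native-language gain (1.5),
two-source sensor mixing, 1/f noise, target words (0/1/2 per stream at
10/80/10%), and probabilistic button responses.

## Worked example

`examples/full_pipeline.py` simulates a small cohort (3 listeners per
group, 5 trials per condition, 10 dB SNR), runs TRF estimation, source
projection, component windowing, and the Nd ANOVA:

```
per-subject Nd window means (source amplitude):
attention  masker  target
subject
ch00       -0.316  -0.679
ch01       -0.285  -0.613
ch02       -0.324  -0.708
ge00       -0.539  -1.143
ge01       -0.430  -0.910
ge02       -0.497  -1.068

attention effect: {'F': 500.254, 'p': 0.0, 'partial_eta_sq': 0.992}
reliability: {'chinese': 0.982, 'german': 0.987}
```

Attended (target) streams evoke a more negative Nd-window amplitude than
ignored (masker) streams in every subject — the generator's attention gain
recovered through the full estimation chain — and the ANOVA quantifies the
effect. The other scripts in `examples/` each demonstrate one capability
(envelope onsets, kernel recovery, behavioral d′, encoding accuracy,
component statistics) and print a line explaining their numbers.

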