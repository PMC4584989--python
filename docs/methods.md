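# Methods

## Scope and data model

A *session* is one subject's synchronized recording of four channels — ECG
(mV), palmar electrodermal activity (μS), a thoracic respiration strap
(arbitrary expansion units) and trapezius surface EMG (mV) — at a common
sampling rate (500 Hz by default; any rate is accepted), with a phase
manifest partitioning session time into a seated baseline (≥ 300 s), a
15-minute socioevaluative stressor ("tsst": anticipation, speech, mental
arithmetic) and five task scenarios. Phases are half-open intervals
`[start, end)` in seconds from session start; sample `i` covers
`[i/fs, (i+1)/fs)`, so phase slicing never duplicates a sample. Sessions
live on disk as plain-text files (per-channel CSV with a `#key: value`
header; TSV manifests and tables) so fixtures are inspectable and
diff-able.

## Feature extraction

**R peaks.** Band-pass 5–15 Hz (4th-order zero-phase Butterworth), squared
derivative, 150 ms moving integration, peak picking above an adaptive
threshold (0.2 × the envelope's 95th percentile, floored at 2 × its
median), then refinement of each detection to the raw-signal maximum within
±50 ms. On clean synthetic ECG the refined peak lands within one sample of
the rendered R wave. R-R intervals implying rates outside 40–180 bpm are
masked invalid and excluded from every downstream statistic.

**Heart rate and SDNN.** HR = 60 / mean(valid R-R) over the phase. SDNN is
the *population* standard deviation (n denominator) of the valid R-R
intervals in ms; the denominator convention is recorded in the
configuration, and windows shorter than 300 s are computed with a
`short_window` warning rather than refused.

**Spectral HRV.** The valid R-R series, timestamped at each interval's
closing beat, is linearly interpolated onto a 4 Hz grid, linearly
detrended, and analyzed with a Welch periodogram (64 s Hann segments, 50%
overlap). LF and HF are rectangle-rule integrals over [0.04, 0.15) and
[0.15, 0.4] Hz. The ratio is reported missing when HF is numerically zero
(below 1e-12), which happens only for degenerate constant tachograms. All
of this — grid rate, segment length, band edges — is configuration, since
only the transform family and the band limits are fixed by the protocol.

**Respiration.** Cycles are delimited by rising zero-crossings of the
0.05–1 Hz band-passed strap signal (inspiration onsets), with sub-sample
linear interpolation of the crossing instant; the rate is cycles per minute
between the first and last onset. A flat strap yields no cycles, not an
error.

**Peak–valley RSA.** Instantaneous HR is stepwise 60/RR, one value per beat
(assigned to the beat opening the interval). Within each respiratory cycle
holding at least two beats, the HR range (max − min) is taken; RSA is the
mean range over cycles, requiring at least three qualifying cycles. With
~4–5 beats per breath this sampling recovers a sinusoidal modulation's
peak-to-peak amplitude to within about 10–15% (it can only underestimate),
which is inherent to the peak–valley method, not to this implementation.

**Electrodermal activity.** The channel is first decimated by block mean to
~20 Hz: the phasic band tops out at 1 Hz and designing a 0.05 Hz corner at
500 Hz is numerically ill-conditioned. The phasic component is the 0.05–1 Hz
band-pass; an EDR event opens at an upward crossing of the 0.05 μS onset
threshold and closes when the signal falls below onset minus a 0.001 μS
hysteresis band (the published 0.05–0.051 μS thresholding span read as a
Schmitt trigger), with a 1 s refractory period against ripple
double-counting. The EDR rate is the phase's event count divided by the
phase length in minutes (phase totals, not sliding minutes). Tonic SCL is
the mean of the < 0.05 Hz low-pass. Zero-phase filters are padded by three
periods of the low corner; the default padding leaves multi-second edge
transients at these frequencies.

**EMG.** RMS over non-overlapping 100-sample blocks (200 ms at 500 Hz),
averaged across the phase.

Missing inputs (absent channel, too few beats) yield NaN features with a
log line; only structurally broken inputs (flat ECG) raise.

## Stress score and trend rules

The physiological stress score is the equally weighted mean of the
heart-rate and SCL ratios to the control group's per-phase means (weights
and a grand-mean normalization variant are configuration). Per-phase
control means are the default because control trajectories then sit at 1.0
by construction in every phase, which makes the score interpretable as
"multiples of control-typical arousal".

Percent changes from baseline to the stressor phase and to the scenario
aggregate (mean of available scenario scores; `last` and `max` are
selectable) feed the four-way rule with a 5% threshold: resistant
(ΔTSST ≤ 5%), resilient (ΔTSST > 5%, Δscen ≤ 5%), recovery (both > 5%,
scenario aggregate below the stressor score) and dysfunctional (both > 5%
with the scenario aggregate *above* the stressor score — the "kept rising"
reading of a class that is defined narratively and rarely observed). The
rules are scale-invariant and exhaustive: every complete trajectory gets
exactly one label. Subjects lacking SCL (e.g. a detached EDA electrode) are
excluded from trend labeling but keep their non-EDA features.

Mission performance is scored
`clamp(10·objectives_met/objectives_total − 0.5·times_shot −
2·civilian_hits − 2·max(0, duration/par − 1), 0, 10)`. Only the 0–10 bounds
and the penalty components are protocol-fixed; the weights are
configuration with defaults chosen so both bounds are attainable.

## Outlier screen and classifier

Subjects are screened on (cortisol, anxiety) with a robust z-score:
flag when `|x − median| / (1.4826·MAD) > z_cut` on either biomarker, with a
mean/SD fallback when the MAD degenerates to zero. The default
`z_cut = 2.2` is calibrated, not conventional: the screen must reliably
flag subjects at the reference outlier positions (cortisol 1.36 μg/dl ≈
3.5 σ, anxiety 71 ≈ 4.6 σ under the cohort moments 0.38 ± 0.28 and 30 ± 9)
despite the sampling noise of a median/MAD estimate at n ≈ 40, where a cut
of 3 misses the cortisol outlier in roughly a quarter of replicates.
Flagged subjects are excluded from training but retained in all reports.

The trend classifier is a one-vs-rest linear hinge-loss model fitted by
stochastic gradient descent: L2 penalty α = 10⁻⁴, the "optimal"
learning-rate schedule, 1000 epochs, tolerance 1e-3, features standardized
to training mean/SD (an unstandardized variant is selectable for
boundary-plot parity on raw axes). Because "library defaults" drift across
versions, every hyperparameter is pinned in the configuration and
serialized with the model. Training uses the full non-discarded set and the
reported accuracy is resubstitution accuracy, matching the small-sample
protocol this reproduces; `cross_validate()` provides a stratified k-fold
estimate and is labeled an extension. Subjects are sorted into a canonical
order before fitting so results do not depend on input row order given the
same shuffle seed. Comparison classifiers (logistic regression, perceptron,
linear-kernel SVM, 1-NN, Gaussian naive Bayes, per-class Gaussian
mixtures) share the evaluation contract.

## Synthetic cohorts

The generator emulates the study conditions as its defaults: 20 control and
19 experimental subjects; 300 s baseline, 900 s stressor, five scenarios of
600 s each (scenario lengths are unreported in the protocol, so 600 s is a
package choice and configurable) at 500 Hz. Experimental subjects draw a
phenotype from the mix 12/19 resilient, 3/19 resistant, 4/19 recovery
(multinomial, seeded). A phenotype sets the percent rise of HR and SCL at
the stressor (25% for reactive classes, 2% for resistant) and the residual
elevation through scenarios (2% resilient, 12% recovery, 1% resistant);
each phase target also gets 1% multiplicative Gaussian noise, a realistic
within-subject stability for multi-minute means. Subject baselines draw
HR ~ N(70, 5) bpm and SCL ~ N(4, 1) μS.

Signals are rendered as: template Gaussian R waves (1 mV, σ = 8 ms) at beat
times integrating the phase HR target, sinusoidal respiratory modulation
(default 6 bpm peak-to-peak at 15 breaths/min) and Gaussian R-R jitter
(default 30 ms); EDA as smoothed tonic phase steps plus a < 0.02 Hz drift
and discrete skin-conductance responses (1 s rise, 4 s decay, 0.3 μS);
respiration as a phase-continuous sinusoid; EMG as Gaussian noise at the
target RMS. SCR event times follow a homogeneous Poisson process
*conditioned on its expected count* (uniform order statistics, 2 s minimum
separation) so the configured rate is realized exactly and round-trip
detection tests are well-posed. Final-sample cortisol is drawn as ~0.32 of
baseline, reflecting the morning diurnal decline rather than any stressor
kinetics. A single seed determines every draw through per-subject spawned
generators, making generated cohorts byte-identical across runs; a
`noise_scale` multiplier scales all noise terms at once (0 = noiseless).

Biomarker profiles are phenotype-conditioned truncated normals whose
default mixture reproduces the cohort moments (cortisol 0.38 ± 0.28 μg/dl,
anxiety 30 ± 9) with the gradient: resistant high-cortisol/low-anxiety
(0.65 ± 0.20, 24 ± 4), recovery the reverse (0.18 ± 0.10, 38 ± 5),
resilient intermediate (0.38 ± 0.25, 30 ± 6). A `separation` parameter
rescales class means away from the grand reference and `spread` rescales
the SDs; "strong separation" in the tests means `separation = 1.5,
spread = 0.4`.

**What the generator does not emulate:** real ECG morphology (P/T waves,
artifacts), movement and electrode noise, SCR amplitude variability and
overlap at high rates, nonstationary breathing, or any correlation between
biomarkers and physiological reactivity beyond the phenotype gradient.
Passing round-trip tests therefore demonstrates the estimators' correctness
on signals with known ground truth, not their robustness to hostile
recordings.

## Numerical choices and degenerate inputs

- Zero-phase (forward–backward) filtering throughout, in second-order
  sections; band edges, orders and padding as above.
- R-R intervals are attributed to a window only when both endpoints fall
  inside it; ties at phase boundaries resolve by the half-open convention.
- Constant signals: flat ECG raises (no rhythm); flat EDA returns rate 0
  with the SCL still computed; flat respiration returns no cycles.
- The EDR scan and the classifier both run identically at any sampling
  rate; tests exercise 100 Hz and 500 Hz.
- Accuracy is an exact ratio of counts; no averaging over classes.

## Problem sizes in the shipped tests

Unit tests run on ≤ 600 s single-window signals and small (≤ 7-subject)
cohorts at 100 Hz; the end-to-end recovery check runs the full 39-subject
cohort at 500 Hz with full-length phases, once at default noise and once
noiseless. Replicate suites (outlier screen, classifier geometry) use 100
seeded replicates of the biomarker-only generator.

## Known limitations

- The trend rule compares two percent changes to one threshold; subjects
  near the 5% boundary flip labels under small measurement noise, which is
  a property of the rule, not the estimator.
- Resubstitution accuracy on n ≈ 16–19 overstates generalization; the
  cross-validation mode exists for that reason.
- The hinge-loss SGD fit at these sample sizes is sensitive to its shuffle
  seed; seeds are therefore explicit everywhere and recorded in the model
  serialization.
- The outlier screen's calibrated cut (2.2) trades specificity for
  sensitivity at the reference outlier positions; with well-behaved
  cohorts it may flag ~1 borderline subject in 20.
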