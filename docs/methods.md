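# Methods

This note documents the models, conventions, and numerical choices behind
`wmdecode`: what the synthetic generator simulates, how the decoding
pipeline is constructed, and what its tests do and do not establish about
real recordings.

## Task and analysis windows

The simulated task is single-item delayed recognition. Each trial:
jittered inter-trial interval (800–1200 ms, uniform on a 50 ms grid),
1000 ms stimulus (Sensory period), 2000 ms blank Delay, 1000 ms probe,
up to 2000 ms response window. A session holds 128 trials for each of
three categories (visual, spatial, verbal), randomly intermixed, with
exactly half of each category's probes matching, 16 stimulus identities
per category used as evenly as possible, and eight equal blocks in
temporal order (break points). Epochs span the half-open window
[−300, 3000) ms around stimulus onset; all window boundaries in the
package are half-open [start, end), so Baseline [−300, 0), Sensory
[0, 1000) and Delay [1000, 3000) partition the epoch disjointly.

Probe matching is balanced exactly (not Bernoulli) so the scheduler's
output is testable; seeds propagate as one master seed with per-subject
seeds `master + index`.

## Synthetic forward model

Channels carry 1/f^α background noise (α = 1, sd 20 μV per channel,
realized by spectrally shaping white noise and rescaling). Each category
has a fixed unit-norm channel topography; the three topographies are
constructed (eigendecomposition of the requested Gram matrix mapped onto
a random orthonormal frame) so that realized pairwise cosines equal the
request to machine precision — by default visual·spatial = 0.6 and
verbal orthogonal to both, the geometry that drives the expected
confusability structure. Trial signals add
`snr_multiplier × envelope(t) × topography` to the noise; per-subject SNR
multipliers are log-normal (spread 0.5 by default), which produces the
across-subject correlation between Sensory and Delay decodability.
Artifact trials (default 5%) receive a ±200 μV square pulse (100 ms) on a
random channel subset, placed inside the epochable window so the ±150 μV
rejection rule can see it. Behavioral responses are Bernoulli in the
subject's accuracy (drawn per cohort from N(0.90, 0.08), clipped);
missing responses would score as incorrect.

### The response envelope and the analysis filter

The time-averaged-voltage features this analysis uses interact strongly
with the zero-phase 1–40 Hz bandpass: a zero-phase highpass redistributes
any waveform's area locally (±∼1 s), so window means after filtering are
dominated by transients near window *boundaries*, and a naive sustained
boxcar envelope leaks roughly four times more signal into the Baseline
window (backward smearing across the onset boundary) than it leaves in
the Sensory window. Children's data decoded with exactly this filter
show a clean pre-stimulus baseline, so the generator's default envelope
("phasic" profile) models the response as transient deflections placed
away from the onset boundary:

- a late-sensory raised-cosine deflection (center 850 ms, width 300 ms);
- opposite-polarity delay-period reactivations (200 ms bumps every
  200 ms, starting 150 ms after stimulus offset) whose amplitudes decay
  exponentially with `delay_decay_tau_ms` (default 600 ms) and a global
  `delay_gain` (default 0.5) — a sustained negativity following the
  sensory complex;
- an anticipatory pre-probe component (gain 0.4, straddling the
  delay/probe boundary). Its filter counterpart lands in the probe
  period, which the epoch excludes; this is what lets the net Delay
  window mean sit *below* the Sensory mean, because local area
  conservation of the zero-phase highpass otherwise pins the Delay
  window to about half the Sensory window's (absolute) mean.

One consequence is documented rather than hidden: through the canonical
1–40 Hz filter the Delay window retains some decodable signal even if
the maintenance reactivations decay instantly, because the sensory
response necessarily exports part of its filtered area across the
1000 ms boundary. The decay-time semantics are exact for the
alternative "sustained" profile (constant amplitude then exponential
decay), which is intended for temporal-generalization contract checks
together with a permissive low filter edge (e.g. 0.02 Hz) — a strong
highpass would remove a sustained plateau outright.

Default amplitude (18 μV against 20 μV noise) was calibrated once so
that a simulated cohort, run through the full pipeline at the reduced
problem sizes below, reproduces the study-like pattern: Baseline not
significant (~33–35%), Sensory ≈ 55–60%, Delay ≈ 43–46%, a consistent
within-subject Sensory−Delay gap of ~11–15 percentage points, and a
strong positive across-subject Sensory–Delay correlation.

The generator does **not** model volume conduction through a head model,
blink/EOG morphology, line noise, channel drift or impedance variation,
response times, or any trial-to-trial variability in the response
latency. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under the stated statistical structure, not
performance on real recordings.

`rotate_at_offset` switches the delay period to an independently drawn
topography frame (the representation "rotates" at stimulus offset); it
exists for temporal-generalization contracts and the `rotating_pattern`
fixture.

## Preprocessing

Downsampling uses polyphase resampling; the bandpass is a 2nd-order
Butterworth (12 dB/octave per pass) applied forward and backward
(`sosfiltfilt`), preceded by DC removal. Only the automatic ±150 μV
rejection criterion is implemented — ICA-based blink removal, visual
inspection, and spline channel interpolation are interactive steps that
users of real data should perform upstream — and the exclusion report
notes this. Exclusion rules: behavioral accuracy at or below 0.50
(inclusive), or retained trials not strictly greater than 200. Both
correct and incorrect trials are kept for decoding.

## Decoding pipeline

Per cross-validation iteration, in this order: (1) trial-level stratified
split, 2/3 train / 1/3 test, so no source trial can contribute to
averages on both sides; (2) within each partition independently,
pseudo-trial construction — random permutation, consecutive groups of 5,
remainder dropped to keep noise homogeneous; (3) stratified up-sampling
to equal class counts within each partition; (4) demeaning with
training-partition column means only; (5) shrinkage-LDA fit and
prediction. Pseudo-trial groupings are redrawn fresh on every iteration.
The shrinkage weight defaults to the analytic Ledoit–Wolf optimum toward
the scaled identity (closed form in `wmdecode.lda`), because 64 channels
can exceed the per-class pseudo-trial count inside a fold; λ is
configurable and reported in the fitted model. Priors are empirical
(uniform after balancing). Prediction ties break deterministically
toward the smallest class index.

Whether the original analysis demeaned over all trials jointly or
train-only is not determinable from its description; train-only is the
stricter (leakage-free) choice and is what this package does.

Temporal generalization reuses the same iterated 2/3–1/3 scheme (an
assumption; the scheme is configurable), shares one trial split and one
pseudo-trial grouping across all bins within an iteration, uses per-bin
time-averaged channel voltages as features, and demeans each bin with
the training partition's means at that bin. A caveat for cross-condition
reading: when the tested representation is genuinely different from the
trained one (e.g. rotated topographies), that per-bin train-mean
centering makes the held-out class means anti-correlated, which biases
cross-block accuracy slightly *below* chance — the correct null reading
is "no above-chance transfer", not "exactly 1/3".

Cross-decoding between disjoint datasets (early→late session halves)
fits on all usable pseudo-trials of the training set and iterates over
pseudo-trial resamples (100 by default) to produce a comparable accuracy
distribution; no trial-level split is needed since the halves are
disjoint by construction.

## Group statistics

Tests against theoretical chance (1/3) are one-sample, one-sided
(greater) t-tests, Bonferroni-corrected within an analysis family (the
three windows, or all time bins); both corrected and uncorrected modes
exist because the correction family for the three time-averaged windows
is ambiguous in the source description. The subject-wise permutation
test shuffles every subject's trial labels independently, recomputes each
subject's mean accuracy (with a reduced iteration count inside
permutations, default 10, logged and configurable), uses the
cross-subject mean as the group statistic, and reports the add-one
p-value (1 + #{null ≥ observed})/(1 + N) — never exactly zero. The
Sensory-vs-Delay comparison is a paired right-tailed t-test; individual
differences use Pearson correlation; the age analysis is an ordinary
least-squares regression of accuracy on age in months (R², slope, p).

## Problem sizes used in tests and the acceptance script

Full-scale defaults (128 trials/category at 1000 Hz synthesis, 500 Hz
analysis, 100 iterations) are what the package ships; the test suite and
`scripts/acceptance.py` run the same code at reduced sizes chosen as the
package's own verification conditions: synthesis at 125–250 Hz with
analysis at the same or half rate, 24–60 trials per category, 8–30
cross-validation iterations, cohorts of 6–20 subjects, permutation
N = 99 with 10 iterations per permutation. Statistical thresholds in the
tests carry the binomial/t slack appropriate to those sizes. One
spec-level expectation was reformulated on statistical grounds: with
~24 test pseudo-trials per iteration a null subject's mean accuracy has
sd ≈ 0.04, so an absolute cap of 0.40 on the maximum of 50 null subjects
would fail ~94% of the time even for a perfectly calibrated decoder; the
null-calibration property instead checks a centred mean (±0.01),
symmetric tails, and a 3.5-sd bound.

## Known limitations

- The forward model is a minimal statistical emulation (see above); its
  response kernel is calibrated against the canonical 1–40 Hz zero-phase
  filter, and analyses with very different filters will see different
  window-mean magnitudes.
- Decoded accuracy at reduced problem sizes is lower than at full size;
  the acceptance script's numbers are reduced-scale quantities.
- The permutation test's reduced inner iteration count trades p-value
  resolution per subject for tractability; it is exchangeable and exact
  regardless, but noisier per subject than the full 100 iterations.
- Behavioral simulation is accuracy-only (no response times or error
  structure by stimulus identity).
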