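# Methods

This note records the models, parameter choices and numerical decisions
behind `mepkit`, in the order data flow through the package.

## Signal model and units

All signals are differential EMG in mV sampled at `fs` Hz (20 kHz by
default); all event times are stored in seconds and every analysis
quantity is reported in ms or mV·ms. The single seconds→ms conversion
happens at epoching. Weeks are integers with baseline encoded as −1 so
panels sort numerically.

## Conditioning chains

Evoked traces are conditioned per sweep as rectify → 5-point moving
average → zero-phase low-pass → DC correction. Rectification first is
essential: the EMG burst is a zero-mean high-frequency interference
pattern, and only after rectification does its envelope occupy the
passband of the 230 Hz filter. Voluntary-contraction trials use the
opposite order (low-pass the raw trace, then rectify the timestamped
portion); both orders are locked by tests on zero-mean sinusoids where
they differ by an order of magnitude.

The low-pass is a Butterworth of configurable order (default 8) applied
forward–backward (`sosfiltfilt`), which squares the magnitude response
(~96 dB/octave effective) and leaves passband components undelayed.
Edges are handled by reflection, both here and in the moving average, so
short MEP windows are not contaminated by filter transients. Two
consequences of the steep zero-phase filter matter downstream and are
handled explicitly:

* it is non-causal, smearing a sharp response foot ~2–4 ms leftward;
* it rings at sharp edges, producing sidelobes of a few per cent of the
  response peak.

DC correction subtracts the mean over a reference window. In the MEP
pipeline the reference is the **late** pre-stimulus span (−25..0 ms),
deliberately disjoint from the **early** span (−50..−25 ms) used to
score sweep cleanliness: selecting the quietest sweeps biases the scored
span low, and a baseline referenced to the same span would leave a
spurious positive offset over the whole post-stimulus region.

## Epoching, selection, averaging

One sweep is cut per stimulus (−50..+100 ms). The first 3 ms after the
stimulus are replaced by reflected pre-stimulus samples — a fill with
identical second-order statistics — rather than a constant, because a
constant fill sits at zero in the rectified domain and the filter's edge
overshoot at that level step mimics a response onset. Events whose
window would leave the recording are skipped with a warning.

Cleanliness is the rectified RMS of the early pre-stimulus span; the 20
lowest-scoring sweeps of the 60 acquired are averaged pointwise (ties
resolve to earlier sweeps, so selection is deterministic). The source
protocol reports 30 or 60 acquired triggers and 10–20 averaged in
different places; both counts are configuration parameters, defaulting
to acquire 60 / select 20.

## Response recognition

On the averaged trace, baseline is the mean rectified level over the
late pre-stimulus window, and the detection level is
`max(baseline·1.15, baseline + 0.005 mV)`: the absolute floor keeps the
15% criterion meaningful as the baseline approaches zero after DC
correction. An excursion above the level counts as the response when it

* starts inside the onset-latency window, default 3–30 ms (past the
  artifact blanking; cortically evoked biceps responses in rat begin
  near 8 ms and never tens of ms later; the offset may extend beyond),
* is sustained for at least 1 ms (`min_run_ms`) and at most 60 ms
  (`max_run_ms` — slow movement humps that survive averaging run far
  longer than any MEP),
* reaches at least 25% of the tallest qualifying excursion
  (`satellite_frac` — filter ringing sidelobes must not set the onset),
* and is supported by the median-across-sweeps trace exceeding the same
  level (the stimulus-locking gate: a genuine evoked response is present
  in every sweep; a movement artifact riding on one or two of twenty
  sweeps inflates only the mean).

Onset is the first qualifying crossing, offset the end of the last
qualifying run, AUC the trapezoidal integral between them, and an
undetected response reports zero AUC and duration. A variability-based
criterion (baseline + k·SD) is available via `criterion_mode="sd"`.
The threshold current is the smallest grid current with a detected
response; non-monotone detection along the series is reported with a
warning but still yields the smallest detected current.

## MVC quantification

Each trial is cut with a 50 ms guard margin, low-pass filtered, trimmed,
rectified, and integrated over the full trial window (unnormalised by
duration; durations are emitted alongside). The guard makes the result
exactly invariant to signal content away from the trial windows while
honouring the filter-before-rectify order. Limb means average the three
trial AUCs; the session MVC averages the two limb means. Grip-force
readings are averaged separately and never enter the EMG AUC, preserving
the dissociation between muscle activity and apparatus force as an
analysable output.

## Statistics

All sums of squares are computed directly from the data; only
distribution functions (F, t, studentized range) come from scipy.

*Split-plot repeated-measures ANOVA.* Between factor group (g levels, n
subjects each), within factor week (k levels), complete balanced panels
enforced. The Greenhouse–Geisser ε comes from the double-centred pooled
within-group covariance of the repeated measures and multiplies the
within-factor degrees of freedom — ε(k−1) and ε(k−1)(N−g) —
unconditionally (no sphericity pre-test), matching the non-integer df
convention of the source analyses. ε is clamped to its algebraic range
[1/(k−1), 1].

*Post-hocs.* Tukey uses the studentized-range distribution on all pairs
with the pooled within-group MS; Bonferroni multiplies pooled-variance
pairwise t p-values by the number of comparisons; Dunnett many-to-one
p-values come from a seeded Monte-Carlo sample (default 200 000 draws)
of the max-|t| null, since the exact critical values need multivariate-t
machinery — their Monte-Carlo error is ~1/√n_mc and is covered by a
tolerance test against an independent implementation.

*Exact Mann–Whitney.* U from mid-ranks of the pooled sample; two-tailed
p is the fraction of all C(n1+n2, n1) assignments whose U deviates from
n1·n2/2 by at least the observed deviation (the reflection rule, which
yields p-values in multiples of 2/56 at 5 vs 3). Enumeration is
guarded at 10^6 assignments; larger problems are directed to a normal
approximation rather than silently approximated.

## Motor-neuron pool mapping

The packaged count table ships as CSV in wide layout (one row per animal, level columns C2–T2) with
a per-animal total column that is verified on load. SDs use the n−1
denominator (the convention that reproduces the summary rows from the
per-animal counts). Levels with all-zero counts in both groups (C2, C3,
T2) are reported as non-testable rather than assigned a p-value. The
injured animal perfused earlier than the others is retained; no
sensitivity exclusion is implemented.

## Synthetic-data generator

The generator is the package's study stand-in, with defaults fixed at
the study conditions: 20 kHz sampling, 60 triggers every 2 s, 3 groups ×
6 animals × 12 time points, threshold 1.5 mA probed on a 0.5–3 mA grid,
MEP recordings at 1.5× threshold.

*Bursts.* A gamma-shaped envelope (latency 8 ms, duration 15 ms, shape
k=4, peak-normalised) multiplies a carrier and rides on background EMG.
The carrier is band-limited (100–1000 Hz) Gaussian noise by default —
the realistic asynchronous interference pattern — or a deterministic
400 Hz sinusoid (`carrier_mode="sine"`), whose rectified mean has the
exact closed form (2/π)·amp·envelope used by the noise-free validation
tests. Burst amplitude scales with the group-week multiplier, a
per-animal lognormal factor (σ=0.2), and current above threshold
(linear, capped at 2× threshold), which builds recruitment monotonicity
into the ground truth.

*Background and artifacts.* Background EMG is Gaussian noise band-limited
to 100–3000 Hz — the acquisition bandwidth of a standard EMG chain — at
0.05 mV RMS. Synthesis filters run over a margin and cut the interior so
variance is spatially uniform (filter edge transients would otherwise
depress the burst region by ~8%). Stimulation artifacts are single
biphasic ±5 mV transients at each trigger (the 5-pulse 500 Hz train of
the therapeutic stimulation is carried as metadata; evoked-response
probes use single pulses, which also keeps the artifact inside the 3 ms
blanking). Movement artifacts are 2–10 Hz noise bursts (0.3 mV RMS,
0.5 s, Hann-windowed) at Poisson rate 0.1/s — these are what the
selection and stimulus-locking stages exist to reject.

*Effect profiles.* Group-week multipliers on burst amplitude: 1.0 at
baseline for all groups; after injury the untreated and single-treatment
groups stay near 0.3–0.35 while the triple-treatment group recovers from
week 4 (0.5), through week 5 (0.7), to a 0.9 plateau from week 6 — the
qualitative time course of the treatment effect. `flat_group_profiles`
sets every multiplier to 1.0 for null-calibration studies.

*Ground truth.* Each session carries its effective burst amplitude and
the expected analysis outcome. For MEPs the truth onset/offset/AUC is
the detector applied to the noise-free expectation of the measurement —
the expected rectified level √(2/π)·√(σ_bg² + (amp·g)²) passed through
the same smoothing and filtering — i.e. the infinite-averaging estimand,
so recovery error measures estimation noise rather than the
deterministic filter response. For MVC the expected trial AUC integrates
the expected rectified level of the *filtered* signal, accounting for
the low-pass attenuation of the background and carrier bands and for the
expected contribution of movement artifacts (without the artifact term,
expected group-AUC ratios would be biased, since artifacts add the same
absolute area to every group). Validation tests that must be independent
of this machinery (the noise-free recovery checks) compute their own
closed forms from the gamma envelope instead.

*Motor-neuron counts.* Negative-binomial per animal and level with
variance μ + d·μ² (Poisson at d=0); zero-mean levels give exactly zero.

*Determinism.* Every generator is a pure function of (config,
identifiers, seed) through `numpy.random.Generator` with spawned seed
sequences; identical inputs give bit-identical sessions.

## Scaled problem sizes

Cohort-level studies (type-I calibration, effect recovery) run on a
reduced configuration chosen from a variance budget: 8 kHz sampling,
30 acquired / 20 selected triggers every 0.2 s, 4 animals per group,
weeks (−1, 1, 4, 6, 11), 2 s grip trials. The sampling rate is kept at
8 kHz rather than lower because the detection margin is bandwidth-driven:
the background band must remain wide relative to the 230 Hz analysis
cutoff for the rectified-background fluctuation to average away. Under
this configuration the treatment-term type-I error of the full
simulate→score→model chain is nominal (5% ± 2% over 200 replicates) and
the week-11 triple/untreated MVC ratio is recovered within a few per
cent of the configured truth.

## What the simulations do and do not show

The generator reproduces the *statistical structure* the analysis
assumes: stimulus-locked bursts on stationary band-limited background,
sparse artifacts, lognormal between-animal scaling, and group-by-week
amplitude profiles. It does not model motor-unit action potential
trains, conduction velocities, electrode drift, habituation, or
correlated week-to-week physiological state; passing recovery tests
therefore demonstrates that the pipeline measures what the model
generates, not that the model captures every property of in-vivo
recordings. The original study's in-vivo statistics depend on its unreleased
recordings and are not reproduced here; the calibration and recovery
studies above are the verifiable counterpart.

## Known limitations

* The exact Mann–Whitney test enumerates assignments and is exponential;
  it is intended for the small group sizes of terminal histology.
* Dunnett p-values carry Monte-Carlo noise (~0.002 at the default draw
  count).
* The automated sweep selection ranks pre-stimulus RMS only; artifacts
  confined to the post-stimulus window are handled at detection (median
  gate), not at selection, by design.
* `validate` checks structural invariants, not signal plausibility.
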