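# Methods

## Scope

`gazedpa` estimates fixation divergence points in visual-world experiments
with a 2 × 2 gender-stereotype design: male and female participants hear
male and female speakers produce sentences with predictive verbs while four
objects are displayed (on gendered trials: a stereotypically masculine and
a feminine target, a masculine and a feminine distractor; on neutral
trials: two neutral targets and two neutral distractors). The package
covers binomial fixation coding, contrast construction, the three-step
bootstrap divergence procedure, a synthetic experiment generator with known
ground truth, and reporting.

## Fixation coding

Gaze is reduced to one indicator per (trial, 50 ms bin, object), bins
identified by their left edge on the lattice −1000, −950, …, +1450 ms
relative to verb onset (half-open intervals). An object is coded 1 iff
non-blink gaze inside its interest area covers a **strict majority**
(> 25 ms) of the bin; ties and everything else — blinks, gaze between
areas, off-screen samples — are 0 for every object, and such bins stay in
the data. The strict-majority rule is deterministic and symmetric: at most
one object can win a bin, which the table validator enforces. Binning is
invariant to splitting a fixation event into contiguous sub-events, so
event-level and sample-level reports code identically.

## Proportions and their denominator

For a contrast A vs B the per-participant proportion at each bin is
looks(A) / (looks(A) + looks(B)), aggregating over that participant's
selected trials; bins where a participant looked at neither set are
undefined (not imputed) and drop out of that bin's test *n*. This makes
0.50 the exact null. The alternative denominator — all selected trials,
counting none-looks — is available via `denominator="trial"`; it was not
made the default because none-looks depress both curves early in the trial
and shift the null away from 0.5. Aggregation is to participant means
("by-participant" analysis); the t-test's df is participants − 1.

## The divergence procedure

1. Per bin, a two-sided one-sample t-test of participant proportions
   against 0.50, computed in closed form (vectorised over bootstrap
   replicates). Degenerate bins follow explicit conventions: n < 2 →
   untestable (NaN, never significant); zero variance with mean ≠ μ₀ →
   t = ±∞, p = 0; zero variance at μ₀ → t = 0, p = 1.
2. Onset = left edge of the first bin starting ≥ `run_length_bins` (default
   10) consecutive bins with p < α (default 0.05, strict inequality) inside
   the 0–1500 ms window. Untestable bins break runs.
3. Non-parametric bootstrap, default 2000 resamples: within each
   participant × image-type stratum, trials are drawn with replacement
   (multinomial weights), each resampled trial contributing its entire time
   course; steps 1–2 are recomputed per resample. Whole-trial resampling is
   the default because resampling bins independently would destroy the
   temporal autocorrelation the bootstrap exists to respect; the
   strict-literal per-bin variant is available as `resampling="per_bin"`
   for comparison. The reported estimate is the mean of detected onsets and
   the percentile CI (2.5/97.5 for 95%) of their distribution, using the
   closest-observation quantile so CI bounds stay on the 50 ms lattice
   while the mean may fall off-lattice. Resamples with no detectable onset
   are excluded from mean and CI and disclosed through `detection_rate`;
   when none detects, the result reports "no divergence" rather than
   raising.

Randomness derives from a single seed; resamples are drawn in a fixed
vectorised order, so results are exactly reproducible for a given
(data, parameters, seed).

## Synthetic experiments

The generator reproduces the design: 32 participants (16 male, 16 female)
over 4 counterbalanced lists; per participant 28 gendered items rotating
through the speaker-gender × referent-stereotype cells in a Latin square
(exactly 7 per cell) and 28 neutral items with a half/half speaker split;
sentence landmarks drawn per speaker from normals matching the stimulus
statistics (verb onset 1621 ± 414 / 1532 ± 357 ms for male/female
speakers), with offset, target onset and duration built from positive gap
draws whose means match the published column means — this guarantees
verb onset < offset < target onset < duration on every draw. Verb onsets
are clipped at 1000 ms so the −1000 ms pre-window exists. Comprehension
responses are Bernoulli with a 1% error rate.

Gaze is a five-state Markov chain per trial (compatible target,
incompatible target, two distractors, none) over 50 ms bins: with
probability `stay_prob` (default 0.85, ≈ 300 ms mean dwell) the state
persists; otherwise it refreshes from a mixture with `p_offscreen`
(default 0.2) on "none" and the on-object mass split between target and
distractor pairs. Because the refresh distribution is also the chain's
stationary distribution, long-run occupancy equals the mixture exactly —
a property the tests verify against the closed form. The target share is
0.5 until `true_onset_ms` (default 500 ms after verb onset) and
`asymptote_pref` (default 0.75) afterwards; within the target pair the
participant-compatible target receives 0.5 + `egocentric_effect`
(default 0, the observed null).

`ramp_duration_ms` defaults to 0, i.e. the preference shift is abrupt.
With gaze persistence, occupancy is an exponentially smoothed version of
the refresh mixture, so any graded ramp makes the occupancy departure —
and hence any honest "true onset" — systematically lag the nominal one;
an abrupt shift keeps ground truth unambiguous for recovery studies. A
positive ramp remains available for generating more naturalistic curves.

What the generator does **not** emulate: post-target-word referent capture
(looks converging on the named object late in the trial), anticipatory
baseline preferences, saccade kinematics or pixel-level scan paths
(coordinate events exist only as an adapter that re-expands binned
indicators for reader tests), item-level random effects, and
participant-level heterogeneity beyond binomial noise. Passing recovery
tests therefore shows the estimator is correct under realistic temporal
autocorrelation and the design's stratification — not that real data meet
these assumptions.

## Validation studies and problem sizes

The acceptance suite runs, at the full 32-participant design: a 200-
experiment null study (no target preference) confirming the run-length
rule's false-alarm rate stays ≤ 0.05 — in practice the 10-bin run
requirement makes false alarms rare even with strong bin-to-bin
correlation; and a 50-experiment recovery study (true onset 500 ms,
asymptote 0.75) at 500 resamples per bootstrap, checking the mean
divergence lands within ±100 ms of truth in ≥ 90% of experiments and the
95% CI covers truth in ≥ 85%. The 500-resample setting keeps the study a
desk-scale computation; single analyses default to 2000 resamples.
Detection necessarily trails the true onset slightly (the first
post-onset bins move occupancy only by (1 − stay_prob) per bin), which is
why recovery is assessed with a ±100 ms band rather than exact equality.

## Known limitations

- The onset rule is two-sided: a sustained significant *deficit* of A-looks
  would also register as a divergence. Inspect the sign of `t` in
  `bin_stats_` when that matters.
- Percentile CIs on run-length onsets are not guaranteed nominal coverage;
  the recovery study quantifies coverage under the generator only.
- The mean divergence is conditional on detection; at low detection rates
  it summarises a selected subset of resamples and should be read together
  with `detection_rate`.
- Interest areas are axis-aligned rectangles with inclusive boundaries;
  overlapping areas resolve to the first match in display order.
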