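# gazedpa

Divergence-point analysis for visual-world eye-tracking experiments.

In the visual-world paradigm, listeners hear spoken sentences while viewing
a display of objects; the timing of their fixations indexes online
interpretation and prediction. A recurring question is *when* looks to one
set of objects (e.g. the two plausible targets of a predictive verb) begin
to reliably exceed looks to another set (the two distractors) — the
**divergence point**. `gazedpa` implements the bootstrap divergence-point
procedure used in gender-stereotype prediction studies, together with the
binomial fixation coding that feeds it and a design-faithful gaze simulator
for validating the whole pipeline against known ground truth.

## The procedure

Fixations are time-locked to verb onset and coded binomially per object and
50 ms bin over −1000…+1500 ms (an object scores 1 in a bin iff gaze lay in
its 300 × 300 px interest area for a strict majority of the bin; blinks and
out-of-area gaze score 0 everywhere). For a contrast of object sets A vs B,
each participant's fixation proportion at bin *t* is

  p̂ᵢ(t) = looks to A / (looks to A + looks to B),

so 0.50 is the exact no-preference value. Then:

1. **Pointwise tests** — at every bin, a two-sided one-sample *t*-test of
   the participant proportions against μ₀ = 0.50 (df = n − 1).
2. **Onset rule** — the divergence point is the left edge of the first bin
   opening a run of ≥ 10 consecutive significant bins (p < .05; 500 ms at
   50 ms bins), searched from 0 to 1500 ms after verb onset.
3. **Bootstrap** — trials are resampled with replacement within
   participant × image-type strata (each trial carrying its whole time
   course), steps 1–2 are recomputed for each of 2000 resamples, and the
   estimate is the mean of the detected onsets with a 2.5/97.5 percentile
   confidence interval. Resamples with no detectable onset are excluded and
   disclosed via the detection rate.

Two contrasts are built in: `targets_vs_distractors` (associative
prediction; also defined on gender-neutral trials) and
`compatible_vs_incompatible` (egocentric prediction: the target matching
the participant's own gender stereotype vs the other target, on gendered
trials or their speaker-gender match/mismatch halves).

## Worked example

```python
from gazedpa import (DivergencePointAnalysis, SimulationConfig,
                     build_design, simulate_gaze)
from gazedpa.preprocessing import comprehension_accuracy

cfg = SimulationConfig(seed=7)        # 32 participants, 56 trials each,
design = build_design(cfg)            # true divergence at 500 ms
table, truth = simulate_gaze(design, cfg)

acc, _ = comprehension_accuracy(design)
est = DivergencePointAnalysis(contrast="targets_vs_distractors",
                              subset="all_gendered",
                              n_boot=2000, random_state=7).fit(table)
print(acc, est.onset_ms_, est.mean_divergence_ms_,
      est.ci_low_ms_, est.ci_high_ms_, est.detection_rate_)
```

prints (to rounding):

```
0.989  500  522.6  500  600  1.0
```

Comprehension accuracy is 98.9%; the targets-vs-distractors contrast
diverges at 500 ms in the observed data, with a bootstrap mean divergence
of 522.6 ms and 95% CI [500, 600] — recovering the generator's true onset
of 500 ms. The same dataset run with
`contrast="compatible_vs_incompatible"` yields no divergence point
(detection rate 0.004), as it must: the generator gives both targets equal
attractiveness (`egocentric_effect=0`).

The estimator follows the scikit-learn contract (`get_params`,
`set_params`, `clone`, fitted attributes with trailing underscores);
`gazedpa.dpa.run_contrast` and friends are equivalent plain functions. A
CLI covers the same ground:

```sh
gazedpa simulate --seed 7 --out sim/
gazedpa dpa --table sim/binned_fixations.csv \
            --contrast targets_vs_distractors --seed 7
gazedpa all --sim-config cfg.yaml --seed 7 --out results/
```

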