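# otss

Psychophysics tooling for studying how the 3D organization of a scene
modulates **orientation-tuned surround suppression (OTSS)** — the reduction
in the perceived contrast of a central grating caused by an iso-oriented
surround. The package implements the full analysis chain for two-interval
contrast judgments with an explicit opt-out ("don't know", DK) response:

- the **difference-with-indecision model** and its multinomial
  maximum-likelihood fit,
- a **generative observer simulator** reproducing the balanced designs of a
  training task and three main experiments (2×2 orientation × depth
  designs and a three-condition depth-surface design),
- **stereo stimulus geometry**: the quantized cumulative-Gaussian disparity
  bump, annulus/wedge surrounds, non-oriented Gabor-filtered noise
  textures, and stereo-pair rendering,
- **within-subject group statistics** (repeated-measures ANOVA through
  subject contrasts, Bonferroni-corrected paired post-hocs).

It is aimed at vision scientists who want to fit 2-AFC-DK contrast data,
run parameter-recovery studies, or regenerate the stimulus geometry.

## The model

On each trial the observer compares a reference grating (contrast varied
over an 11-step ladder) with a test grating (fixed contrast, surrounded by
a context). The internal evidence is the perceived-contrast difference
between the second and first intervals,

    D ~ Normal( ±(x − μ), σ ),      x = reference − test physical contrast,

with the sign set by the presentation order of the reference. Two fixed
criteria partition D: D < δ₁ → "second lower", D > δ₂ → "second higher",
otherwise DK; interval-frame responses are mapped back to
"reference higher / lower" by order. The four parameters (μ, σ, δ₁, δ₂)
jointly generate six psychometric functions (3 responses × 2 orders) and
are fitted by maximum likelihood. Because the criteria live in the interval
frame, their midpoint absorbs interval bias, and **μ** — the contrast
offset at which the observer is maximally uncertain (the peak of the
order-averaged DK function) — estimates the perceived-contrast shift of
the test grating (Δ perceived contrast) free of that bias.

## Worked example

Simulate a full 2×2 study (8 observers × 3,520 trials, condition-mean
effects at realistic sizes), fit every observer × condition, and run the
group statistics:

```python
from otss import RunConfig, run_synthetic_study

report = run_synthetic_study(RunConfig(preset="exp1", n_observers=8, seed=7))
print(report["condition_means"])
for effect, a in report["anova"].items():
    print(f"{effect}: F(1,{a['df_den']}) = {a['F']:.2f}, p = {a['p']:.4g}")
```

prints (values in % Michelson contrast; Δ perceived contrast of the test
grating relative to the reference):

```
{'IsoFlat': -8.76, 'IsoDepth': -6.25, 'CrossFlat': -4.33, 'CrossDepth': -4.98}
orientation: F(1,7) = 60.56, p = 0.0001087
depth: F(1,7) = 2.93, p = 0.1306
interaction: F(1,7) = 20.08, p = 0.002863
```

i.e. iso-oriented surrounds suppress perceived contrast more than
cross-oriented ones, and the orientation × depth interaction reflects the
release from suppression when the iso surround moves to a different depth
(post-hoc `report["posthoc"]`: IsoFlat vs IsoDepth t = −3.31,
Bonferroni-corrected p = 0.026; CrossFlat vs CrossDepth p = 0.48).

The same stages are available from the shell:

```bash
otss simulate --preset exp1 --seed 7 --n-observers 8 --out trials.csv
otss fit --data trials.csv --out fits.json
otss analyze --preset exp3 --n-observers 7 --seed 1 --out report.json
otss stimgen --stimulus bump --out bump        # stereo PNG pair
otss recover --preset exp1 --n-replicates 20 --out recovery.json
otss reanalyze --data deposit.csv --mapping mapping.yaml --out report.json
```

`reanalyze` ingests externally deposited trial tables through a YAML
column/code mapping (see `otss.pipeline_io.apply_column_mapping`).

## Stimulus geometry

`otss.stimulus_geometry` reproduces the display and stimulus constants:
36.5° / 1600 px pitch (5 px = 0.11°), the bump built from
`Disparity(r) = base · Φ((r − μ_r)/σ)` with σ = 0.5° and base −0.5°,
quantized to whole pixels — exactly 21 one-pixel disparity rings around a
2.26° flat top — and the region-averaged surround disparities of the
Average and Near control discs.

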