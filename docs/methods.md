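# Methods notes

## The difference-with-indecision model

The decision variable is defined in the **interval frame**: D is the
perceived contrast of the second interval minus the first, Gaussian with
standard deviation σ and mean ±(x − μ) (positive sign when the reference is
second), where x is the reference-minus-test physical contrast in percent
Michelson and μ the perceived-contrast shift of the test grating. Fixed
criteria δ₁ ≤ δ₂ partition D into "second lower" / DK / "second higher",
and responses are mapped to the reference frame by presentation order.

A criteria-in-the-reference-frame reading ("difference below δ₁ →
reference lower" regardless of order) would make the two presentation
orders statistically identical and could not represent a bias toward a
temporal interval — which is precisely what the method is meant to cancel.
The interval-frame construction is therefore used: the criterion midpoint
c = (δ₁+δ₂)/2 captures interval bias, the half-width w = (δ₂−δ₁)/2 the
size of the indecision zone, and the order-averaged DK psychometric
function is an even function of x − μ, so its peak identifies μ
independently of c. An additive order-bias term with reference-frame
criteria would be observationally similar; the two cannot be distinguished
from the published description, and the interval-frame form is the
standard construction for opt-out designs.

Closed forms (Φ the standard normal CDF):

- reference second: P(ref lower) = Φ((δ₁ − (x−μ))/σ),
  P(ref higher) = 1 − Φ((δ₂ − (x−μ))/σ);
- reference first: P(ref higher) = Φ((δ₁ + (x−μ))/σ),
  P(ref lower) = 1 − Φ((δ₂ + (x−μ))/σ);
- P(DK) is the remainder, zero when δ₁ = δ₂.

### Likelihood and fitting

The objective is the per-cell multinomial negative log-likelihood with the
combinatorial constant omitted; probabilities are floored at ε = 1e-9
inside the logarithm (configurable) so boundary parameter values keep the
objective finite. The fit is unweighted — each trial counts once.

Optimization runs in an unconstrained parameterization
(μ, log σ, c, log w), guaranteeing σ > 0 and δ₁ ≤ δ₂, with L-BFGS-B from a
deterministic moment-based start (μ₀ at the empirical DK maximum or the
count-weighted ladder mean; σ₀ from the ladder span; w₀ from the overall
DK rate) plus 8 jittered restarts drawn from a seeded generator; the best
objective wins, ties to the first found. `converged` records whether any
restart reported success.

Degeneracies are refused rather than silently fitted: a single
presentation order (the Fisher information for c vanishes and μ is
confounded with interval bias), fewer than two ladder levels, or all-DK
data raise `NonIdentifiableError`. Observers who never use the DK option
pin w = 0 and are fitted with three parameters (`criteria_collapsed` flag).
No lapse parameter is fitted by default; a fixed lapse rate is available
as an opt-in field in `FitOptions`. One σ is fitted per condition fit
(no contrast-dependent σ).

### DK-peak location

`dk_peak_location` evaluates the order-averaged DK curve on a dense grid
spanning |c| + w + 6σ around μ and refines each grid maximum with bounded
scalar optimization. When |c| is large relative to w and σ the averaged
curve is bimodal with maxima symmetric about μ; the result then flags
non-uniqueness and returns both locations instead of silently picking one.

## Synthetic observers

The simulator enumerates the exact balanced designs and samples responses
from the same generative rule the analytic functions describe — it shares
the probability model but not the code path used in fitting, so
simulate → aggregate → fit closes the loop as a genuine recovery test.

Design presets (repeats per session are derived from the published session
totals, which do not state them directly: 440 = 11·4·2·5, 396 = 11·3·2·6):

| preset   | ladder (% contrast)       | conditions                   | orders | repeats/session | sessions | total |
|----------|---------------------------|------------------------------|--------|-----------------|----------|-------|
| training | 21–39 step 2.25 (9)       | test at 27.75 / 32.25 (2)    | 2      | 12              | 1        | 432   |
| exp1     | 14, 18–34 step 2, 38 (11) | Iso/Cross × Flat/Depth (4)   | 2      | 5               | 8        | 3,520 |
| exp2     | same                      | Iso/Cross × Flat/Near (4)    | 2      | 5               | 8        | 3,520 |
| exp3     | same                      | Bump / Average / Near (3)    | 2      | 6               | 7        | 2,772 |

Trial order is a uniform seeded shuffle within each session (the balancing
granularity of the original pseudo-random order is not documented; per
session is the natural unit). The training task's acceptance rule is
exposed as `veridicality_gate`: all fitted |μ| within ±1 % contrast.

Group simulations draw per-observer parameters around condition-level
means: μ perturbed Normal(0, 1 %) per condition; log σ (sd 0.15), the
criterion midpoint (sd 0.5 %) and log half-width (sd 0.2) perturbed once
per observer, since sensitivity and criterion placement are observer
traits. These spreads are chosen to bracket the published group means and
produce observer scatter comparable to the published per-subject panels.
Default truth means reproduce the published condition means/marginals
(e.g. the 2×2 depth experiment: IsoFlat −9.33, IsoDepth −6.93, CrossFlat
−4.89, CrossDepth −4.89, which give the iso/cross marginals −8.13/−4.89
and flat/depth −7.1/−5.9 with the depth effect confined to the iso
surround; σ = 5, δ₁ = −1.5, δ₂ = 2.5).

What the simulator deliberately does not emulate: learning or fatigue
across sessions, lapses, contrast-dependent σ, serial dependence, or
image-computable responses. Passing recovery tests therefore shows the
estimator is consistent and unbiased **under the model's own assumptions**,
not that real observers satisfy them.

## Stimulus geometry

- **Pixel pitch**: linear convention, 36.5°/1600 px = 0.0228°/px. The
  published px↔deg pairs (5 px ↔ 0.11°) match this to rounding; a
  tangent-corrected pitch does not, so it is not used.
- **Bump**: d(r) = base · Φ((r − μ_r)/σ) with σ = 0.5°, base = −0.5°, and
  the Gaussian mean at μ_r = flat-top radius + 2σ = 2.13°. With the mean
  there, the disparity magnitude at the nominal flat-top edge (1.13°) is
  Φ(−2)·21.9 px ≈ 0.499 px — i.e. the nominal flat top is exactly the
  region that nearest-pixel rendering keeps at zero disparity, and
  `flat_top_diameter` measures it that way (sub-half-pixel criterion →
  2.261°). Placing the mean at the flat-top edge instead would make the
  1°-ring average ≈ −18 px, far from the published −5 px.
- **Quantization**: floor of the disparity magnitude in pixels. |base| is
  21.9 px, so flooring yields the published 21 one-pixel rings; rounding
  to nearest would create a 22nd. Both rules are exposed.
- **Region averages**: the published disc disparities do not pin down one
  spatial averaging convention, so three are implemented. The
  area-weighted mean over the 1°-wide ring [1.13°, 2.13°] gives −4.8 px →
  −5 px (the Near disc); the plain radial mean gives −4.3 px; the
  unweighted mean over the 21 quantized ring levels plus the zero level
  gives −10.5 px, closest to the published whole-bump Average disc of
  −10 px (no convention reproduces −10.0 exactly). `area_weighted` — the
  physically natural "average over the region" — is the default.
- **Texture**: Gaussian noise filtered in the frequency domain through 18
  Gabor filters (orientations equally spaced over 0–180°, center 2 cyc/deg,
  1-octave half-magnitude bandwidth, circular envelope), then affinely
  rescaled so the 0.1–99.9 luminance percentiles span the target Michelson
  contrast about mean 0.5, and clipped. Realized contrast lands within
  0.5 points of target. The isotropy check compares per-bin **mean** Fourier
  power (so uneven lattice coverage of orientation bins is not read as
  anisotropy) averaged over several noise draws, because any single draw's
  orientation spectrum fluctuates at the 1/√n-coefficients level (~0.25 CV
  at 256²) regardless of filter design; the bank itself has design CV ≈ 0.05.
- **Rendering**: left eye at zero disparity; right-eye elements shifted
  horizontally by their disparity rounded to integer pixels (no sub-pixel
  interpolation), matching the one-eye disparity convention. Random
  elements (dot squares, textures) are drawn once and shared between the
  eyes. The bump renders as concentric rings, each shifted by its own
  quantized disparity. The depth-surface experiment's surround outer
  diameter is not stated; 8° (the other experiments' surround) is the
  default.

## Group statistics

The 2×2 repeated-measures ANOVA is computed through per-subject contrasts
(±1 coding, halved): F = n·mean(c)²/var(c) with df (1, n−1), algebraically
the squared paired t — and equal to the classical two-factor
within-subject decomposition, which the tests verify against both a
brute-force sums-of-squares oracle and pingouin. The one-way
repeated-measures ANOVA uses the classical decomposition with sphericity
assumed (uncorrected df, as in the published analyses). Post-hoc paired t
tests are Bonferroni-corrected within the comparison family actually run
(2 planned depth-within-orientation comparisons for the 2×2 experiments,
3 pairwise for the three-condition experiment; configurable). Zero-variance
contrasts — possible with deterministic synthetic input — return a flagged
F of 0 (zero mean) or ∞ instead of raising, so simulation sweeps continue.

## Pipeline

Every study report embeds the resolved configuration, a SHA-256 hash of
it, the master seed, and the package version; per-observer seeds are
spawned deterministically from the master seed. Trial tables travel as
CSV, fits and reports as JSON, stimuli as 8-bit grayscale PNG. External
deposits are ingested via a column/code mapping (names, response codes,
order codes), with unknown codes reported by row. One fit is performed per
observer × condition pooling all sessions, as implied by the per-participant
trial totals of the published design.

## Problem sizes and numerical choices

Monte-Carlo validation of the analytic probabilities uses 10⁶ draws per
parameter/cell point (24 points), compared at 4 binomial standard errors
(using the larger of the analytic and empirical variance estimates, which
keeps the band honest when the true probability is ~10⁻⁷). Parameter
recovery runs 100 replicates of one 880-trial condition at the iso-surround
effect size; type-I calibration uses 10,000 null simulations at α = 0.05.
The dense radial grid for the bump uses 40,001 samples over 0–4°
(sample spacing ≈ 1/228 of a pixel of disparity change).

## Known limitations

- The model assumes a single σ per condition and no lapses; strongly
  lapsing observers will bias σ upward and can bias μ.
- `dk_peak_location` reports bimodality but does not arbitrate it; with
  extreme criterion bias the DK peak is not a usable estimator and the fit
  μ should be used directly.
- Rendering is geometric, not photometric: no gamma model, no anti-aliased
  sub-pixel disparity.
- The deposited raw data's schema must be described by the user's mapping
  file; the package does not guess it and does not download data.
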