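# Methods

This note records the modelling assumptions, defaults and numerical
choices behind `fearcurve`, and what the synthetic-data experiments do and
do not demonstrate about real camera-trap data.

## Response curves from detection logs

A *camera-day* is one camera's midnight-to-midnight calendar day.  Raw
frames are first collapsed into records: human-related frames (hikers,
vehicles, cyclists) at one camera merge whenever consecutive gaps are
under 1 hour; frames of one mammal taxon merge under a 5-minute gap.
Merging is chained — a 10:00/10:03/10:06 sequence is one record — because
a re-triggering animal extends its own burst; counts of individuals are
summed so none are lost.  The per-taxon response variable at human count
`x` is the fraction of camera-days with exactly `x` deduplicated human
records on which the taxon was photographed at least once.  Data are
pooled across cameras: the target is a study-area average, as in a
meta-analysis, not per-camera inference.

Choices that matter:

- **Day window.** Calendar binning is the default because it makes
  camera-days disjoint and the proportion denominator well defined.  A
  `rolling` option reads "disturbance less than 24 h before detection"
  literally (humans in the 24 h preceding the day's first mammal
  detection); it admits late-evening disturbance from the previous day at
  the cost of overlapping windows.
- **`min_days` (default 5).** Proportion points supported by fewer
  camera-days are dropped as noise.
- **`max_x` (default 30).** The heavy right tail of human counts is
  truncated, not pooled into a terminal bin, because the models are fit to
  per-integer disturbance levels.

## Curve models

Five families, all with `y(0) = y0` and monotone non-increasing in `x`:
exponential `y0·e^(−ςx)`, inverse-square power law `y0/(1+ςx²)`,
hyperbolic `y0·ς/(ς+x)`, harmonic `y0/(1+ςx)`, and the Arps decline
equation `y0·(1+dςx)^(−1/d)` whose discount exponent `d ∈ [0,1]` spans
exponential (`d→0`) through harmonic (`d=1`) decay.  For `d ≤ 1e−8` the
exponential limit is evaluated directly (guarding overflow in `1/d`), and
`d = 1` dispatches to the harmonic expression so the identity holds to the
bit.  Hyperbolic and harmonic are the same curve under `ς ↔ 1/ς`; both are
kept because their parameter scales — and hence flat priors on them —
differ, which is the only way their fits can differ.  `x` is accepted as a
real number (observed counts are integers) so fitted curves can be plotted
and integrated smoothly.

## Bayesian fitting

**Likelihood.** The default is Gaussian on the proportion scale,
`y_i ~ Normal(f(x_i), σ)`, with σ estimated under a U(0,1) prior — a
pragmatic choice for real curves whose scatter exceeds binomial noise
(site effects, weather, detector behaviour).  A matched binomial
likelihood (`likelihood="binomial"`, on `round(y_i·n_i)` detections out of
`n_i` camera-days) is available and is the right choice when the points
really are binomial proportions, as in the package's own synthetic
recovery experiments.  On such idealized data the homoskedastic Gaussian
is knowingly miscalibrated: a single pooled σ (≈0.003 at 2000 days/level)
treats the noisiest point, `x = 0` with true s.e. ≈0.010, as three times
more precise than it is, and its credible interval undercovers (measured
8/20 for `y0` versus 18/20 under the binomial likelihood).  Posterior
*means* are essentially unbiased under either.

**Priors.** "Flat" priors need supports: `y0 ~ U(0,1)`, `ς ~ U(0,50)`
(generous — the largest sensitivity seen across taxa is ≈12.5),
`d ~ U(0,1)`, `σ ~ U(0,1)`.

**Sampler.** Adaptive random-walk Metropolis, all chains advanced in
parallel: a coordinate-at-a-time phase adapts per-coordinate scales toward
44% acceptance; halfway through warm-up a pooled empirical covariance is
estimated and joint multivariate-normal proposals (scale `2.38²/k`,
adapting toward 23% acceptance) are mixed in — the curve parameters,
especially (ς, d), are strongly correlated and coordinate moves alone mix
poorly.  All adaptation freezes when warm-up ends, so kept draws come from
a fixed kernel.  Defaults: 4 chains, 5000 draws after 5000 warm-up.
Convergence contract: split-R̂ < 1.01 and bulk ESS > 400 per parameter
(computed via arviz); violations are attached to the result as warnings,
never silently dropped.  Identical seeds give bit-identical draws.

**WAIC.** Deviance scale: `lppd = Σ_i log mean_s exp(ll_si)`,
`p_waic = Σ_i var_s(ll_si)`, `WAIC = −2(lppd − p_waic)`; lower is better.
Pointwise log-likelihoods are per curve point.  Rankings break WAIC ties
toward fewer free parameters.  A single posterior draw degenerates to
`p_waic = 0` with a warning.

**HDI.** The shortest contiguous window containing `⌈0.95·n⌉` sorted
draws — exact for the sample, cross-checked against arviz in the tests.

## Pulse resilience

Around each high-disturbance event day `t` (a "wilderness access day",
roughly a 10-fold spike in visitation), mammal detection counts at each
camera are collected for offsets `j ∈ {−3,…,+2}` and fit independently per
offset:

```
y_j ~ NegBinomial(π_j, r_j),  π_j = r_j/(r_j + μ_j),  A_j = r_j(1−π_j)/π_j
```

so the activity metric `A_j` equals the NB mean `μ_j` exactly (the tests
assert the identity on every draw).  Priors: `μ ~ U(0,100)` (a flat gamma
in the vague limit); `r ~ Gamma(shape, rate)` with the shape fixed at the
mean detection count over the six offsets and the rate itself flat on
(0.01, 10).  `r` and the rate are sampled on the log scale (with Jacobian
corrections, priors unchanged) because the overdispersion is weakly
identified from a handful of cameras.  Counts are sorted before the
likelihood so the posterior is exactly exchangeable in camera labels.

A degenerate regime worth knowing: when the six-day mean count (the prior
shape for `r`) is small (≲4) and one offset has no detections at all, the
priors admit a plateau at `r → 0` where `μ` is unidentified and the
posterior goes diffuse instead of collapsing to zero.  With a moderately
active series (mean ≳8) the all-zero-offset posterior concentrates near
zero as expected.  Fits in that small-count regime should be read with the
convergence warnings in hand.

## The synthetic study system

The generator emulates the structure the analysis assumes, with defaults
at the study's scale: 50 cameras over nine years from 2007-06-01, seven
focal species (bobcat, puma, grey fox, coyote, striped skunk, raccoon,
mule deer) with their fitted Arps parameters as generating truth.

- **Disturbance.** Daily human-record counts per camera are
  negative-binomial — visitation is clustered, hence heavier-tailed than
  Poisson — with mean `λ·(1 + trend·t)·(1 + a·sin(2πt))`, `t` in years.
  Defaults `λ = 2`/day, dispersion 1.5, trend +15%/yr, seasonal amplitude
  0.3 are conventions (the real marginal is unpublished), chosen to give a
  visibly rising, seasonal series at realistic occupancy.
- **Detection.** Per camera-day and taxon, a single Bernoulli draw at the
  taxon's curve value for that day's human count — detection is an
  indicator, matching the response variable being a proportion of days.
- **Pulses.** Event days multiply the expected human count by `fold`
  (default 10) and detection probability is multiplied by suppression
  factors at offsets −1 and 0 (default 0.3 each), with recovery at +1 —
  activity dips a day early and rebounds a day after.
- **Event emission.** Records can be expanded into raw frame bursts
  (1–3 frames, minutes apart) that the deduplication stage must collapse;
  human records are spaced ≥62 min apart and capped at 22 per day so the
  1-hour merge is lossless and the emitted log round-trips *exactly* to
  the generator's truth table (the tests check every camera-day).
- **Seeding.** All randomness flows from one `SeedSequence`; no global
  state.

What the generator does *not* emulate: spatial or inter-camera
correlation, diel activity, site covariates, observer-side overdispersion
in detection (each proportion is exactly binomial).  Passing recovery
tests therefore show the estimator is correct and calibrated under the
model's own assumptions — not that real curves obey them.  Two honest
side-effects of the design: (i) because detection depends on the day's
human count, a rising disturbance trend induces a second-order *decline*
in the mammal series (≈−7%/yr at defaults) rather than the perfectly flat
trend seen in the real system — the trend test asserts the human rise
dominates, not exact flatness; and (ii) recovery experiments at 2000
camera-days per level are far cleaner than a real decade of data at one
site, which is why interval calibration, not interval width, is the tested
property.

## Problem sizes in the test-suite experiments

Recovery and selection experiments run at 2000 camera-days per
disturbance level over levels 0–15 (32 000 camera-days per curve).
Coverage is assessed over 20 seeded replicates (binomial likelihood, 4
chains × 5000 draws); WAIC selection over 10 replicates per generating
form at 2000 draws; pulse recovery over 20 replicates of 7 cameras × 6
offsets, and the dip-and-recovery shape over 10 replicates of a year of
monthly access days at 7 cameras.  The exponential-data selection
scenario uses ς = 0.3 so the curve declines across the whole observed
range rather than vanishing after the first level.
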