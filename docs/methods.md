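# Methods

`vascat` analyzes how school-age children's speech categorization changes
over time, using visual-analogue-scale (VAS) ratings of minimal-pair
continua collected in an accelerated longitudinal design.  The package
covers the full chain: simulating such a study with known ground truth,
preprocessing raw ratings, fitting a hierarchical Bayesian psychometric
model per testing year, extracting per-subject indices, and modeling their
longitudinal trajectories.

## The psychometric model

Each trial presents one step `x ∈ {1..7}` of a minimal-pair continuum; the
child taps a 0–100 line whose ends are anchored by the two endpoint
pictures.  The expected rating follows a four-parameter logistic (4PL)

```
mu(x) = L + (U − L) / (1 + exp(−(4 s / (U − L)) · (x − c)))
```

with lower and upper asymptotes `L`, `U` (VAS units), crossover `c` (step
units) and `s` the derivative of `mu` at `x = c` (VAS units per step).  The
slope is parameterized directly as the midpoint derivative — the quantity of
scientific interest (category gradiency: shallower = more gradient) — rather
than recovered post hoc from a rate constant; the internal rate is
`k = 4s/(U−L)`.

Ratings scatter around `mu` with a trial variance that is largest where the
stimuli are most ambiguous.  The model makes the log variance quadratic in
the centered step:

```
log sigma²_j(x) = w0 + theta_j + w1·(x − m) + w2·(x − m)²,   m = 4
```

with a subject-specific intercept `theta_j` (the "fifth parameter").  The
quadratic is centered at the fixed mid-step rather than at each subject's
crossover: that keeps the generator and the model aligned and the profile
identifiable, at the cost of mislocating the variance peak for subjects with
extreme boundaries.

One testing year at a time, trials enter a Gaussian likelihood with crossed
random intercepts: subject and item (continuum) intercepts on each of
`L, U, c, s`, plus the subject intercept on the log variance.  Fitting all
subjects and continua jointly lets sparse per-child data (28 trials per
continuum) borrow strength across the design.  The model is deliberately fit
per year; a joint longitudinal nonlinear model of this complexity is not
attempted, and longitudinal structure is instead handled downstream on the
extracted indices.

Priors are weakly informative on the measurement scale: `L0 ~ N(0, 20)`,
`U0 ~ N(100, 20)`, `c0 ~ N(4, 2)`, `s0 ~ N(15, 15)`, `w0 ~ N(log 150, 2)`,
`w1, w2 ~ N(0, 1)`; half-normal priors on random-intercept SDs (scale 10 for
VAS-unit parameters, 1 for the crossover and the variance intercept, half
that for items).  Positivity of the slope is encouraged by prior mass, not
enforced: screened data always show rising profiles, and a hard constraint
would distort boundary cases.

The observation family is Gaussian, not truncated to [0, 100]: free
asymptotes absorb edge effects in the mean.  The known cost is in the
variance: real (and simulated) ratings clip at the scale ends, compressing
observed dispersion near the asymptotes, which biases the log-variance
intercept slightly downward.  See "Known limitations".

### Sampling

No gradient-based probabilistic-programming backend is available in this
stack, and ensemble samplers mix poorly in the model's 150–400 dimensions,
so the package carries its own Hamiltonian Monte Carlo engine
(`vascat.hmc`): the log posterior and its gradient are fully analytic
(non-centered random effects; a numba kernel computes both in one pass over
trials, with a pure-numpy twin cross-checked in the tests).  Chains start
from the posterior mode (L-BFGS on the analytic gradient) with
Laplace-scaled jitter; the mode's curvature seeds a diagonal metric that a
warmup window then re-estimates; step size adapts by dual averaging toward
0.8 acceptance; trajectory lengths are jittered uniformly over the upper
half of `max_leapfrog`.  Defaults (4 chains, 1000 warmup + 1000 draws,
`max_leapfrog = 48`) hold split R-hat below 1.01 for all population
parameters on a 12-subject fixture, with bulk ESS in the hundreds from far
fewer draws than that.  Convergence diagnostics (arviz split R-hat and bulk
ESS for every population parameter and random-effect scale) are attached to
every fit and failures raise warnings — never silent.

### Subject indices

* **Slope** `slope_hat`: posterior mean of `s0 + s_j` (population slope plus
  the subject's intercept), VAS/step.
* **Response Variability** `rv_hat`: posterior mean of the subject's trial
  variance averaged over the seven steps, in squared VAS units.  Zero would
  mean perfectly repeatable responses; trial SDs near 23 VAS points put the
  index in the 500–600 range.  Averaging over steps (rather than reading the
  profile at the center step, or reporting an SD) is this package's
  documented convention; the alternatives are monotone transforms that would
  not change rank orderings or effect signs.

An unpenalized per-subject nonlinear least-squares 4PL
(`oracle_subject_fit`) exists purely as an independent cross-check: on
data-rich synthetic subjects it correlates with the hierarchical slopes
above 0.9, while on sparse noisy subjects the hierarchical estimates show
the expected partial-pooling shrinkage.

## Preprocessing

Half of all blocks are recorded with the endpoint pictures swapped; raw
ratings from those blocks are reversed (`100 − rating`) so high values
always correspond to step 7.  The transform is an involution, verified
property-wise.  A participant-year is retained only if its mean response
profile (per step, pooled over continua) reaches both scale regions:
minimum step-mean ≤ 25 and maximum ≥ 75, comparisons inclusive (the
permissive reading of "failed to reach").  Pooling over continua matches the
year-level granularity at which exclusions are reported; a stricter
per-continuum mode is available behind a switch.  Exclusion is
year-specific: a participant dropped for one year re-enters the others.

## The synthetic study

The generator (`synthetic` modules `design`, `population`, `simulate`)
emulates the reference design: 3 cohorts starting in grades 1–3, 4 annual
waves, 5 continua × 7 steps × 2 days × 2 repetitions = 140 trials per
participant-year (28 per continuum), picture orientation swapping on day 2,
step order randomized within blocks.  Defaults (chosen once, as study
conditions):

| quantity | default | rationale |
|---|---|---|
| subjects per cohort | 75 | final analyzed sample of 225 children |
| attrition per participant-year | 0.065 | 841 retained of 900 possible measures |
| slope mean / subject SD | 18 / 6 VAS·step⁻¹ | mid-childhood VAS slopes; wide individual differences |
| asymptote means / SDs | 5, 95 / 4 | children rarely use the exact scale ends |
| crossover mean / SD | 4 / 0.5 steps | continua engineered to be balanced |
| trial-variance base | 250 VAS² | trial SDs ≈ 13–20; index values in the hundreds with 500–600 attainable |
| variance profile | w1 = 0, w2 = −0.15 | variance peaks mid-continuum |
| item intercept SDs | 2, 2, 0.3, 2 | continua differ modestly |
| slope trends (year, grade, year×grade) | −1.39, +2.42, −0.81 | reference growth-model estimates |
| variability trends | −26.08, −36.78, +26.52 | reference growth-model estimates |
| subject log-variance SD (intercept, year slope) | 0.3, 0.06 | ±30% individual spread in consistency |

Slope heterogeneity is additive Gaussian with a per-subject intercept and
year-slope, so the growth stage faces a well-specified target.  Variability
heterogeneity is mean-corrected lognormal — `rv = (linear trend) ×
exp(eta − Var(eta)/2)` — which keeps the index positive while making the
configured additive trends exact in expectation (verified by Monte Carlo
test).  Trial noise is Gaussian on the VAS scale and clipped to [0, 100];
an explicit `clip=False` switch draws from the unbounded Gaussian for
estimator-validation runs where the fitted model should be exactly
well-specified.

What the generator does **not** emulate: response pile-up exactly at 0/100
beyond what clipping produces (no discrete edge-censoring process), lapses
and attention drifts within a session, order/practice effects, reaction
times, and any covariance between a child's slope and their variability.
Passing tests therefore certify the estimation machinery under the stated
generative assumptions, not the behavior of real children.

## Growth-curve stage

Each outcome (one value per participant-year) enters a linear mixed model
with fixed effects testing year (centered), start grade (centered, linear)
and their interaction, and the maximal converging random-effects structure
on participants: random intercept + random year slope with correlation,
estimated by REML (statsmodels MixedLM).  If that structure will not
converge the package falls back — uncorrelated random effects, then
intercept-only, then OLS — and every fallback or boundary (singular) fit is
flagged in the metadata.  An independent cross-check against R's
lme4/lmerTest on a shared fixture is part of the test suite.

t statistics use the residual degrees-of-freedom convention
`df = N − (fixed effects + variance-covariance parameters)` by default, with
a between-within (containment) convention available; both are documented
conventions, not exact finite-sample theory, and CI/p-values inherit
whichever is chosen.  A Satterthwaite-style approximation was considered and
not implemented: it needs the covariance of the variance-component
estimates, which the backend does not expose reliably; on this design's
sample sizes (hundreds of residual df) the conventions differ negligibly.
Standardized betas come from refitting the same structure on z-scored
outcome and predictors (interaction recomputed as the product of z-scored
terms).  Marginal predictions are fixed-effect linear combinations on a
year × grade grid with delta-method intervals.

The practice-effect contrast asks whether change is concentrated between the
first two sessions (task learning) or steady (development): per subject,
(year-1→2 change) minus the mean of later year-to-year changes, averaged
with a t-based interval.  It is exactly zero for constant or linear
trajectories and large for a one-time jump.

## Calibration and validation harnesses

Problem sizes were fixed in advance by power analysis so each check is
informative at the smallest tractable scale:

* **Parameter recovery** — 20 studies of 30 subjects × 2 continua, one
  year, reduced sampler (2 chains, 500+500), unclipped noise; 95% credible
  intervals for the population slope and log-variance intercept must cover
  the generating values in ≥ 18/20.
* **Growth calibration** — type-I error of the year effect over 500 null
  replicates (200 subjects × 4 years); CI coverage over 200 replicates per
  outcome at the reference effect sizes.  Binomial three-standard-error
  tolerances.
* **End-to-end signs** — 20 studies of 3 cohorts × 20 subjects × 3 continua
  with the default (reference-magnitude) trends, full pipeline, reduced
  sampler (2 chains, 200+250): negative year effects on both indices and a
  positive year×grade interaction on variability, each p < 0.05, in
  ≥ 18/20.  Sixty subjects and three continua give interaction power above
  0.95 at these magnitudes while keeping the 80 hierarchical fits tractable.
* **Practice contrast** — null rejection near 5% and power > 0.8 for an
  injected jump at 200 subjects.

## Numerical choices and degenerate inputs

* Non-finite parameter vectors or non-positive 4PL spans short-circuit to a
  −∞ posterior (the proposal is rejected) rather than raising.
* Log-variance values are capped at 500 inside the kernel to avoid overflow
  on wild proposals; the cap is unreachable in any region of nonnegligible
  posterior mass.
* The NLS oracle bounds parameters to a generous physical box and reports
  non-convergence explicitly; callers skip, never silently substitute.
* Zero-residual growth data collapse to the OLS rung of the fallback ladder,
  which reproduces the generating coefficients exactly (SE = 0 handled by
  convention: t = ±∞, p = 0 for nonzero effects).
* Trial tables round-trip CSV exactly (`%.17g` writing, round-trip float
  parsing), so ingesting a written study reproduces simulate-mode results
  byte for byte.

## Known limitations

* Edge clipping compresses observed trial variance near the scale ends, so
  with clipped data the fitted log-variance intercept sits slightly below
  the generating value; recovery harnesses therefore validate under the
  unclipped family, and absolute Response Variability levels on clipped
  data should be read as mildly conservative.  Effect *signs* and orderings
  are unaffected (the end-to-end harness keeps clipping on).
* The validity screen selects on slope, so screened-in samples are not a
  random subsample; population parameters from screened data are
  "kept-population" parameters.
* With only 2–5 items, item random-effect scales are weakly identified;
  population asymptotes inherit that uncertainty (prior-bounded), which is
  why the near-degenerate recovery fixture uses five items.
* Per-year fitting ignores cross-year correlation in psychometric
  estimation error; the growth stage treats indices as data, as in the
  two-stage approach it mirrors.
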