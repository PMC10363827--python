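# Methods

## Scope and data model

The package analyses long-term nest-observation data for a single-prey-
loading owl: per-watch prey-delivery counts, nest productivity records
(clutch, brood, fledglings), adult and nestling masses, and hourly
weather.  All analyses condition on annual weather categories; nothing in
the package models within-season weather.

Record-level rules applied before any model sees the data:

- a watch interval enters the analysis only if it lasted the full
  15 minutes and started no more than 90 minutes after sunset (the
  boundary itself is retained — only *later than* 90 min is excluded);
  intervals longer than 15 minutes are dropped with their own reason code
  rather than truncated, since the protocol defines only 15-min watches;
- a delivery is attributed to the male if the female was known to be on
  the nest, male vocalizations accompanied the delivery, or the female
  was heard off-nest while a second owl entered; mirror cues attribute to
  the female; if cues for both sexes fire the delivery stays unknown
  (conservative — the protocol never describes the case), and one event
  yields exactly one attribution;
- nests with unknown fate are excluded from all analyses; observations at
  known-fate nests are kept even when the nest later failed, because the
  protocol only records watches preceding failure.

## Weather classification

An owl year for breeding season Y spans 1 June Y−1 to 31 May Y.  Total
precipitation is the sum of hourly readings; temperature is the mean over
days of the daily minimum hourly reading.  Days with no temperature
reading are skipped in the mean and precipitation gaps contribute zero
with a logged warning — archive stations have outages and the alternative
(failing the year) discards more information than it protects.

Classification compares each year with a fixed fraction of the 1950–2000
historical mean (418.1 mm; −6.4 °C).  The fraction is the study-period
mean expressed as a *ratio of means* on the measurement scale; for
temperature this is a ratio of two negative Celsius quantities
(0.46599 × (−6.4) ≈ −2.98 °C), which reproduces all 17 published year
labels.  The alternative reading of "46.5% higher" as a relative increase
(Δ/|historical|) was rejected because only the ratio form reproduces the
published labels.  Exact-threshold ties go to the dry/cold side; no
study year sits on a threshold.  The temperature ratio recomputes to
0.46599 (46.6% at the printed precision; the source prints 46.5%) — the
ratio is always derived at run time, never hard-coded.

Candidate covariate windows (three daily temperature statistics × two
spans; four precipitation spans) are screened by the AIC of a log-link
Poisson regression of per-interval delivery counts on the year-level
scalar, one observation per interval.  The aggregation level is a choice
(the source is ambiguous); interval-level observations weight years by
their observation effort.  AIC is invariant to affine rescaling of the
covariate, which the tests assert.

## Delivery-rate changepoint model

Two joined log-linear segments with a single changepoint:

    log γ(x) = β₁ (min(x, Δ₁) − Δ₀) + [x > Δ₁] β₂ (min(x, Δ₂) − Δ₁)

- Δ₀ = 0 and the intercept is fixed at zero: deliveries cannot precede
  sunset (nightly axis) or hatch (seasonal axis), so E[count] at x = 0 is
  exactly e⁰ = 1.  This identity — not an estimate — is why the seasonal
  minimum delivery rate equals 1 in every category.
- Δ₂ is fixed at the largest observed x; it is part of the segment
  parameterization, not an estimated quantity.
- The link is log.  A logit link cannot produce a positive unbounded
  Poisson mean nor the exact minimum of 1 at the origin, so the model is
  implemented on the log scale.
- Counts are totals per 15-min interval (male + female + unknown).
  Exposure is constant by construction after filtering, so no offset.
- Priors: Δ₁ ~ uniform(min x, max x); β₁, β₂ ~ normal(0, variance 1000),
  the variance taken literally (sd ≈ 31.6).
- Each weather category is fitted independently; no shared parameters.

Posterior rate summaries (mean, minimum, maximum deliveries per 15 min)
are computed per posterior draw over the sorted unique observed x values,
then summarized.  The grid convention is a documented choice; a caller
can pass any grid.

An independent cross-check fits, for each changepoint on a 1-unit grid,
the two-slope zero-intercept Poisson model by maximum likelihood
(statsmodels GLM) and maximizes the profile likelihood.  Ties within
1e-8 log-likelihood (a flat profile, e.g. when β₂ = β₁) break to the
smallest grid value.  On large simulated datasets the Bayesian posterior
mode and the profile maximizer agree to within one grid step; the oracle
is used only in tests, never as the implementation.

## Hierarchical nestling growth

    mass_ij = α_j + b1_j · min(age_ij, δ_j) + [age_ij > δ_j] b2_j (age_ij − δ_j) + ε
    ε ~ N(0, σ²)

with per-nestling (α_j, b1_j, b2_j, δ_j) drawn from population normals.
A hatch-mass intercept is included because owlets weigh several grams at
hatch.  Hyperpriors: population changepoint uniform over the observed age
range; intercept/slope hypermeans normal(0, 1000); hyper-sds
half-normal(31.6) and residual sd half-normal(100) — weakly informative
on the gram scale, chosen because the source gives no scale priors.
Nestlings weighed fewer than twice cannot inform slopes and are excluded
with a warning.

## Supporting models

**Division of labor.**  Female share of sexed deliveries per interval
(unknown-sex deliveries excluded); intervals with no sexed deliveries are
dropped.  Boundary shares {0, 1} are mapped inside the open interval with
the Smithson–Verkuilen squeeze p′ = (p(N−1) + 0.5)/N, N = total sexed
deliveries in the dataset (the source does not say how boundary
proportions entered a beta likelihood; the squeeze is the standard fix).
Model: logit(μ) = b0 + b1·x, p′ ~ Beta(μφ, (1−μ)φ), φ ~ half-normal(100).
One data point per interval regardless of how many deliveries were sexed;
a weights-by-count variant is available behind a flag.  Per-category runs
(not a pooled category covariate) parallel the other models.

**Adult mass.**  mass = (a + u_j) + (b + v_j)·julian + ε with random
intercepts u_j and slopes v_j per band.  The stated prior ("uniform with
mean 0 and variance 1000") is self-contradictory; normal(0, 1000) is the
default, with uniform(±√3000 ≈ ±54.77) — the same mean and variance —
behind a switch.  Julian day is reported raw by default; internally the
sampler always works on the mean-centred day scale because the raw scale
makes intercept and slope ~perfectly correlated, and the intercept draws
are transformed back (the wide prior is applied to the raw-scale
intercept either way, so the reported posterior belongs to the raw-scale
model).  A trend is significant when the fixed slope's 95% CRI excludes
zero.

**Productivity.**  value ~ Poisson(exp(c0 + c1·indicator)) per outcome
(clutch, brood, fledglings) and contrast (wet/dry, warm/cold), wide
priors as above.  Besides c1, posterior distributions of the category
means exp(c0) and exp(c0 + c1) are returned for overlap displays.  An
all-zero category leaves c1 prior-dominated; this is flagged, not fatal.

## Sampler and diagnostics

Models are low-dimensional (≤ ~5 fixed effects plus grouped random
effects), so the package uses an adaptive random-walk Metropolis-within-
Gibbs sampler rather than a gradient method: per-parameter Gaussian
proposals with scales tuned toward ~0.44 acceptance during burn-in,
proposals folded into bounded supports by exact reflection (symmetric, so
no Hastings correction), and — for parameters with finite bounds, i.e.
changepoints — an occasional (10%) uniform independence proposal over the
support so chains can hop between changepoint modes.  The delivery model
initializes chains from crude binned-count moment estimates; the growth
sampler updates per-nestling parameters with vectorized Metropolis steps
(the likelihood factorizes over nestlings) and hypermeans with conjugate
Gibbs draws; the mass model samples on the centred-day scale.  Start
points are overdispersed by one proposal scale.

Chains are seeded deterministically from the run seed, so identical
(data, priors, config, seed) give bit-for-bit identical summaries.
Convergence is summarized by the classic Gelman–Rubin R-hat (the source
predates rank-normalized variants); R-hat ≥ 1.1 attaches a warning to the
posterior summary rather than raising.  Credible intervals are
equal-tailed quantile intervals (not HPD), matching the authors' tooling.
Significance rules: a slope is significant when its 95% CRI excludes
zero; two groups differ when their 95% CRIs do not overlap (touching
intervals overlap).  Pearson residuals are provided per family for
residual-vs-fitted diagnostics.

Default chain settings mirror the published analysis (deliveries and
productivity 3 × 20,000 with 4,000 burn-in; growth 3 × 4,000/2,000; labor
3 × 10,000/1,000; adult mass 3 × 200,000/50,000; thinning 1).  The test
suite and acceptance script use proportionally shorter, R-hat-checked
runs (2,500–4,000 iterations) to fit a single-CPU time budget; data sizes
are never scaled down for the stated-world checks.

## Synthetic data: what it emulates, and what a green test shows

The generator restates the study's conditions as defaults: 17 owl years
with correlated annual precipitation/minimum-temperature pairs (r = .67,
means 300.32 mm / −2.98 °C, sds 81.67 / 0.48); 80 nests × 10 full 15-min
watches at uniform 0–90 min after sunset across nestling ages 1–23; Poisson
counts from the two-segment intensity at the published per-category
posterior means (e.g. dry nightly Δ₁ = 37.85, β₁ = 0.05, β₂ = −0.02);
female attribution following the labor model with an unknown-sex fraction
of 0.13 (the share of deliveries the study could not sex); behavioural
cues emitted consistently so re-attribution reproduces the generated
counts exactly; ~54 nestlings weighed ~10.2 times (range 2–27) from the
hierarchical growth model with population changepoint day 16; adults
captured 1–3 times with a declining female and flat male mass trend;
clutches Poisson(3.5) truncated to {1..4} (mean ≈ 2.70, matching the
published 2.5–3.0 range) with binomial hatching (0.75) and fledging
(0.80) survival, the warm-year effect acting multiplicatively on fledging
survival.  Hourly weather expansion spreads precipitation evenly over
days and gives temperature a diurnal cycle whose daily minimum equals the
annual value, so owl-year aggregation round-trips exactly.

What the generator does *not* emulate: nest-level random effects in
delivery rates (intervals are independent given x), observer effort
imbalance across the season, weather-driven within-year variation,
renesting, or measurement error in nestling aging.  A green recovery test
therefore establishes that the estimators are correct for their own
data-generating processes at realistic sizes — not that the field data
satisfy those processes.

## Numerical choices

- Log-rate values are clipped at ±50 before exponentiation to survive
  early adaptation steps; the clip is never active near the posterior.
- The beta likelihood clips μφ and (1−μ)φ at 1e-8 from below.
- Truncated-Poisson clutches are drawn by rejection (support {1..4}).
- Changepoint draws are binned to the oracle grid when computing the
  posterior mode for the oracle comparison.
- The profile oracle drops a degenerate (all-zero) design column — at a
  grid point equal to the domain maximum the second segment vanishes.

## Test-design choices

Stochastic checks freeze their seeds and, where a single replicate's pass
probability is materially below one, use replicate designs chosen by
power analysis *before* the seed was frozen: the delivery-recovery check
runs 20 replicates and requires joint CRI coverage in ≥ 18; the female
mass-decline check runs 3 replicates and requires 2 successes (capture
dates confound with individual intercepts, making a single replicate's
realized slope wobble around the truth); the positive fledging-effect
check uses 500 nests per category (se of the log rate ratio ≈ 0.048, so
detection power > 95% at a true log ratio of log 1.2 ≈ 0.18).

## Known limitations

- The sampler is random-walk based: posteriors with strong curvature or
  high dimension (hundreds of random effects) mix slowly; the pipeline's
  published-scale mass setting (3 × 200,000) exists for exactly that
  reason.
- The beta labor model treats interval shares as beta-distributed even
  though they arise from small binomial counts; with few sexed deliveries
  per interval the precision parameter absorbs the granularity and slope
  estimates are mildly attenuated.  The published analysis shares this
  property.
- One published summary statistic is not reproducible from the published
  per-year table: the yearly precipitation–temperature Pearson
  correlation recomputes to 0.439 (p = .078) rather than the stated .67
  (p < .001, itself inconsistent with n = 17).  The corresponding check
  is left failing deliberately and the discrepancy is documented where it
  is asserted.
- Derived "percent earlier" contrasts between category changepoints are
  not implemented: their definition is not recoverable from the published
  description and simple ratios of the posterior means do not reproduce
  them.
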