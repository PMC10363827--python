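# owlprov

Bayesian analysis of year-round weather effects on nest provisioning in
Flammulated Owls (*Psiloscops flammeolus*) — small, insectivorous,
migratory owls of western conifer forests.  Because the species is a
single-prey loader (one prey item per nest visit), counting visits during
a 15-minute nest watch counts prey deliveries exactly.  This package
implements the full analysis chain for such long-term nest-observation
studies, plus a synthetic-study generator with known ground truth so every
stage is verifiable without the original field data.

## What it computes

**Weather classification.**  Hourly weather is aggregated into "owl
years" (1 June – 31 May).  A year is *wet* when its total precipitation
exceeds a fixed fraction of the 1950–2000 historical mean (the fraction
is the study-period mean as a share of the baseline, ≈ 71.8% of
418.1 mm), and *warm*/*cold* analogously for mean daily minimum
temperature (threshold ≈ 0.466 × (−6.4 °C) ≈ −2.98 °C).  Candidate
covariate windows (e.g. Jun–Jul vs the full Jun–May year) are screened by
AIC of Poisson regressions.

**Delivery-rate changepoint model.**  Deliveries per 15-min watch follow
a joined two-segment Poisson regression on the log scale.  With domain
origin Δ₀ = 0 (sunset, or hatch), changepoint Δ₁ and domain maximum Δ₂:

    log γ(x) = β₁ (min(x, Δ₁) − Δ₀) + [x > Δ₁] β₂ (min(x, Δ₂) − Δ₁)
    y_i ~ Poisson(γ(x_i))

with a zero intercept (no deliveries before sunset or hatch, so the
expected count at x = 0 is exactly e⁰ = 1).  Priors: Δ₁ uniform over the
observed x range, slopes normal(0, 1000).  Fitted separately for wet,
dry, warm and cold years, nightly (x = minutes after sunset) and
seasonally (x = nestling age).  Inference is by adaptive Metropolis-
within-Gibbs MCMC with Gelman–Rubin R-hat, trace and Pearson-residual
diagnostics; significance uses the 95% credible-interval (CRI) overlap
rule.  A profile-likelihood grid search provides an independent
frequentist cross-check of the changepoint.

**Hierarchical nestling growth.**  Mass follows the same joined-segment
form per nestling, with a hatch-mass intercept and per-nestling
intercepts, slopes and changepoints drawn from population-level normals
(the growth changepoint falls near day 16 of the ~23-day nestling
period).

**Supporting models.**  Division of labor (female share of sexed
deliveries) via a beta GLM on the logit scale with Smithson–Verkuilen
boundary squeezing; adult mass vs Julian day via a mixed model with
per-individual random intercepts and slopes; clutch/brood/fledgling
counts via Poisson GLMs with a wet/dry or warm/cold indicator.

## Worked example

```sh
python examples/02_delivery_changepoint.py
```

prints (simulating 80 nests × 10 watches at the dry-year truth
Δ₁ = 37.85 min, β₁ = 0.05, β₂ = −0.02, then refitting):

```
simulated 800 watch intervals at 80 nests (dry-year truth)
delta1:  37.604  95% CRI [ 36.060,  39.465]  (truth 37.85)  R-hat 1.001
 beta1:   0.050  95% CRI [  0.048,   0.052]  (truth 0.05)  R-hat 1.001
 beta2:  -0.019  95% CRI [ -0.022,  -0.016]  (truth -0.02)  R-hat 1.000

posterior delivery-rate functionals over the observed minutes:
  mean: 3.67 per 15 min  [3.54, 3.80]
   min: 1.01 per 15 min  [1.00, 1.01]
   max: 6.58 per 15 min  [6.17, 7.00]
the minimum sits at sunset where the zero-intercept log link forces
exactly 1 delivery per 15 min

independent profile-likelihood check: changepoint 38 min, slopes 0.050 / -0.019
```

The CRIs cover all three simulated truths; the posterior changepoint
agrees with the independent maximum-likelihood grid search.  The other
examples cover year classification (`01`), nestling growth (`03`), the
labor/mass/productivity models (`04`) and the end-to-end pipeline with
its report bundle (`05`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch: the 17-year climate
summary statistics, baseline ratios and all wet/dry, warm/cold labels
from the packaged study table; a delivery-changepoint fit to data
simulated at the published dry-year truth, cross-checked against the
profile-likelihood oracle; the hierarchical growth fit (population
changepoint near day 16); and the productivity contrast with a positive
warm-year fledging effect.  Progress and the recomputed values are
printed; the JSON metrics object is written to `--out`.

## Layout

- `src/owlprov/io_data.py` — typed records, CSV schemas, delivery
  sex-attribution and watch-interval filters
- `src/owlprov/weather.py` — owl-year aggregation, baseline
  classification, correlation screen, AIC window selection
- `src/owlprov/mcmc.py` — sampler, priors, R-hat, CRIs, overlap rule,
  Pearson residuals
- `src/owlprov/changepoint.py` — delivery and growth changepoint models,
  profile-likelihood oracle
- `src/owlprov/aux_models.py` — labor, adult-mass and productivity models
- `src/owlprov/synthetic.py` — ground-truth study generator and the
  packaged 17-year summary table
- `src/owlprov/pipeline.py` — end-to-end orchestration and report bundle
- `docs/methods.md` — modelling assumptions, priors, tuning choices and
  known limitations
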