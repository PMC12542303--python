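# Methods

## Exposure-response model

The hazard-ratio curve is the Global Exposure Mortality Model (GEMM): for an
annual-mean PM2.5 concentration *c* (µg/m³),

    z    = max(0, c − c₀)
    T(z) = log(1 + z/α) · 1/(1 + exp(−(z − µ)/ν))
    RR_a = exp(θ_a · T(z)),

a supra-linear form — approximately linear near the counterfactual and
flattening at high concentrations (T is concave for large z, well above µ).
The model's assumptions, inherited here, are that long-term IHD mortality
risk depends on the annual mean alone (no seasonality or lag structure),
acts proportionally on the baseline hazard within each 5-year age band, and
is exchangeable across populations — the fit pools cohorts mostly from
lower-exposure regions, which is the main caveat when applying it to an
East-Asian megacity.

### Parameters

| parameter | units | default | role |
|---|---|---|---|
| α | µg/m³ | 1.9 | concentration scale of the log term |
| µ | µg/m³ | 12.0 | midpoint of the logistic weight |
| ν | µg/m³ | 40.2 | width of the logistic weight |
| c₀ (counterfactual) | µg/m³ | 2.4 | exposure below which RR = 1 |
| θ_a, SE(θ_a) | per unit of T | 0.1938→0.0474 (age 25–29→80+) | band-specific log risk |

All five live in the parameter file (`data/gemm_ihd.csv`: a CSV of per-band
coefficients under a commented key:value header), never in code, so an
alternative fit — another cause, a fit excluding particular cohorts, a
different counterfactual — is a file swap. The packaged defaults are a
transcription of the published IHD fit including the Chinese cohort; the
`source_version` field records this, and the standard errors should be
regarded as approximate. The counterfactual 2.4 µg/m³ is the
lowest-observed-concentration anchor of that publication. Concentrations
below c₀ are clamped to RR = 1 rather than extrapolated; the clamp lives in
the transform (`z = max(0, c − c₀)`), so disabling it would require an
explicit parameter-file change, not a code path.

## Attribution algebra

Burden uses the general attributable fraction `p(RR−1)/(1+p(RR−1))` with
exposure prevalence p = 1 (ambient exposure is ubiquitous; this is the
convention of standard air-quality burden tools), where it reduces exactly
to `1 − 1/RR`. The two forms are kept distinct in the tests as a built-in
cross-check. Attributable deaths are computed as observed deaths × PAF: the
textbook `M × PAF × Population` cancels algebraically to this, and using
the raw counts avoids the double rounding that a printed rate times a
population would introduce. Benefit for a reference concentration r uses
`1 − RR(min(c, r))/RR(c)` per stratum; the `min` (on by default) encodes
reduction-scenario semantics — districts already below the target are left
unchanged, never "raised" to it, so benefits are non-negative. An RR below 1
(possible only with clamping disabled) yields a negative PAF that is passed
through with a warning, keeping configuration mistakes visible rather than
silently floored.

## Stratification and aggregation

The computational unit is district × year × 5-year age band (25 × 5 × 12 =
1,500 strata in the default setting): exposure is assigned at the district
level and the coefficients are band-specific, so any coarser unit would mix
risks. Reporting groups 25+, 45+ and 65+ are sums over the bands at or above
each threshold. Yearly rates divide by that year's group population; the
period ("Total") row sums counts over the years and divides by the
*period-mean* population — the convention consistent with a period rate over
a shifting population at risk (summing yearly rates gives a slightly
different, harder-to-interpret number). Rounding — integer deaths, one
decimal for rates and percentages — is applied only when tables are written;
all in-memory values are full precision.

## Uncertainty propagation

Only coefficient uncertainty (SE of θ_a) is propagated; Poisson noise in the
observed counts and exposure-model error are not. Two methods:

- **endpoint** (default, deterministic): θ_a ± 1.96·SE pushed through every
  formula. Because every output is a monotone transform of θ_a, these are
  the exact 2.5/97.5 quantiles of the induced distribution, not a
  linearization.
- **montecarlo**: θ_a ~ Normal(θ_a, SE²), 2.5/97.5 percentiles of the
  *aggregated* outputs across draws (default 1,000, minimum 100, seeded).
  For a single stratum it converges to the endpoint bounds; for sums across
  bands it is the more defensible interval, since the endpoint method
  perturbs all bands jointly.

Within a stratum the same coefficient value (bound or draw) enters both the
baseline and the reference risk: they share one θ_a, and perturbing them
independently would overstate benefit uncertainty. Across bands the
coefficients are treated as independent in the Monte-Carlo method; the
published fit reports no cross-age covariance, so independence is the
neutral choice (the endpoint method is effectively the perfectly-correlated
alternative, which is why its intervals on sums are slightly wider).

## Synthetic data generator

`simulate_panels` emulates the structure of the Seoul study inputs:
25 districts over 2016–2020; district PM2.5 = city-year mean (defaults are
the observed annual means 25.9, 24.5, 22.7, 24.0, 20.3 µg/m³) plus
Normal(0, 2 µg/m³) noise truncated at zero (a warning reports realized
moments if truncation bites); a 7.4-million adult population split equally
across districts and by an elderly-heavy age-share profile; baseline
(counterfactual-exposure) IHD mortality rising from 0.4 to 240 per 100,000
across the bands, chosen so the realized crude IHD death rate lands near the
~29–33 per 100,000 observed in Seoul. Expected stratum deaths are
`population × baseline rate × RR(pm25, band)` — the generator embeds the
same curve the pipeline applies — and realized deaths are Poisson draws
(binomial available for tiny strata; Poisson is the standard rare-event
approximation at these rates). `GroundTruth` carries the closed-form
expectations of deaths, attributable deaths and per-scenario avoided deaths,
so recovery tests are exact-bookkeeping checks with no model
misspecification. A deliberately misspecified mode (log-linear generator,
GEMM analysis) exists for robustness experiments but is not part of the
standard checks.

What the generator does **not** emulate: spatial autocorrelation between
adjacent districts, within-year seasonality, migration or cohort aging,
exposure-measurement error, and any real covariance between age structure
and exposure. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic is faithful to its own model — not that the model, or
the transcribed coefficients, describe any particular city.

## Numerical choices and degenerate inputs

- Machine-precision identities (Eq-form equivalence, transform oracle) are
  asserted at 1e-12 relative error with an ulp-scale absolute floor of
  1e-15: near RR = 1 the subtraction `1 − 1/RR` cancels below one rounding
  error of 1.0, where a purely relative comparison is meaningless.
- Endpoint bounds are sorted per element (`min`/`max` of the two endpoint
  evaluations), so a negative θ − 1.96·SE cannot produce an inverted
  interval.
- Counts are accepted as integers only; deaths ≤ population, all 12 bands
  per district-year, and unique keys are enforced at read time with
  row-numbered diagnostics. Rates are never inputs.
- Zero-population strata are legal (they carry zero deaths); rate columns
  are only defined for reporting groups with positive population.
- The avoidable mortality rate is undefined (error) at zero observed
  deaths; zero avoided deaths is reported as 0%.
- Recovery checks use 200 replicates of the default 1,500-stratum
  configuration, giving a Monte-Carlo standard error small enough to detect
  a bias of a few deaths against totals near 900.

## Known limitations

Single pollutant, single cause, crude (not age-standardized) rates, no
years-of-life-lost or economic valuation. Confidence intervals ignore count
noise and exposure error. The transcribed coefficient table — particularly
its standard errors — should be re-verified against the original supplement
before any substantive application, and the parameter-file format exists
precisely to make that substitution trivial.
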