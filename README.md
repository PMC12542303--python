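# pm-hia

Health impact assessment of ambient fine particulate matter (PM2.5) on
ischemic heart disease (IHD, ICD-10 I20–I25) mortality, for
epidemiologists and air-quality analysts who need attributable-burden and
policy-scenario numbers from district-level panels of exposure, population
and death counts.

## The model

Relative risk comes from the Global Exposure Mortality Model (GEMM), a
supra-linear hazard-ratio curve with age-group-specific coefficients. For an
annual-mean concentration *c* and counterfactual concentration *c₀* (default
2.4 µg/m³, below which no excess risk is assigned):

```
z     = max(0, c − c₀)
T(z)  = log(1 + z/α) · ω(z),   ω(z) = 1 / (1 + exp(−(z − µ)/ν))
RR_a  = exp(θ_a · T(z))
```

with shape constants α, µ, ν shared across the twelve 5-year adult age bands
(25–29 … 80+) and a log-risk coefficient θ_a (with standard error) per band.
The packaged IHD parameter table (`pm_hia/data/gemm_ihd.csv`) is a
transcription of the published GEMM fit and can be replaced by any file in
the same format.

Burden and benefit follow the population-attributable-fraction algebra with
exposure prevalence p = 1 (ambient exposure is ubiquitous):

```
PAF_burden  = p(RR − 1) / (1 + p(RR − 1))  =  1 − 1/RR_baseline   (at p = 1)
AD          = deaths × PAF_burden                     (attributable deaths)
PAF_benefit = 1 − RR_reference / RR_baseline
HB          = deaths × PAF_benefit                    (avoided deaths)
```

evaluated per stratum (district × year × age band) and summed into the
reporting groups 25+, 45+ and 65+. The avoidable mortality rate is avoided
deaths divided by observed IHD deaths, as a percentage. Reference scenarios
of 15 µg/m³ (Korean annual standard), 10 µg/m³ (2005 WHO guideline) and
5 µg/m³ (2021 WHO guideline) are built in; 95% bounds are propagated either
by pushing θ ± 1.96·SE through every formula or by Monte-Carlo sampling of
the coefficients.

## Worked example

No external data are needed: the `simulate_panels` generator draws a
Seoul-like panel — 25 districts over 2016–2020, city-mean PM2.5 tracking the
observed annual values (25.9 … 20.3 µg/m³), an elderly-heavy age structure —
with the same exposure-response curve embedded, so every estimate has a
known analytic expectation.

```python
import pm_hia as p

params = p.load_gemm_parameters()           # packaged GEMM IHD table
est = p.relative_risk(23.5, "70-74", params)
# RR(23.5, 70-74) = 1.1023 (95% CI 1.0883, 1.1165)

exposure, demography, truth = p.simulate_panels(p.SimulationConfig(seed=1), params)
burden = p.propagate_uncertainty(exposure, demography, params)
print(burden.data[burden.data["year"] == "Total"])
#  year age_group  deaths  attributable  attributable_low  attributable_high
# Total       25+ 10931.0         924.8             802.3             1045.7
# Total       45+ 10693.0         878.2             760.8              994.0
# Total       65+  9117.0         667.1             574.5              758.6

benefit = p.propagate_uncertainty(exposure, demography, params,
                                  scenario=p.ScenarioSpec("kmoe-15", 15.0))
# Total 25+: 248.4 avoided deaths, avoidable mortality rate 2.27%

truth.expected_attributable_total()   # 935.2 — generator's analytic expectation
```

Reading: of the 10,931 simulated IHD deaths among adults 25+, about 925
(95% CI 802–1046) are attributable to PM2.5 above the 2.4 µg/m³
counterfactual, statistically consistent with the generating model's
analytic expectation of 935. Meeting the 15 µg/m³ standard would have
avoided about 248 of them (2.3% of all IHD deaths).

The same run from a shell:

```sh
pm-hia simulate --out data/ --seed 1
pm-hia burden  --exposure data/exposure.csv --demography data/demography.csv --out results/
pm-hia benefit --exposure data/exposure.csv --demography data/demography.csv \
               --reference 15 --reference 10 --reference 5 --out results/
```

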