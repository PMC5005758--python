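# cpdid

Bayesian changepoint and difference-in-differences analysis of quarterly
injury count series, built for evaluating when a built-environment safety
intervention (such as a Safe Routes to School program) changed a
population's injury risk, and by how much.

The intended user is an injury epidemiologist or policy analyst with
event-level crash records (timestamp, victim age, area label) or
pre-aggregated quarterly counts with population denominators. The package
covers the full pipeline: inclusion-rule filtering and quarterly
aggregation, a hand-built MCMC sampler for two Poisson changepoint models,
Gelman–Rubin convergence diagnostics, a quasi-Poisson
difference-in-differences regression, and a synthetic-data generator that
reproduces the statistical structure of the problem so everything is
testable without access to a proprietary crash database.

## The models

Quarterly counts `y_t` (t = 1..N) with population offset `O_t` are Poisson,
`y_t ~ Poi(μ_t)`, with an unknown changepoint τ:

**Model 1** (level and slope shift):

    log μ_t = β₀ + β₁·t + β₂·δ(t−τ) + β₃·δ(t−τ)·(t−τ) + log O_t

**Model 2** (level shift only, the β₁ = β₃ = 0 special case):

    log μ_t = β₀ + β₂·δ(t−τ) + log O_t

where δ(u) = 1 iff u ≥ 0. β₀ and β₁ are the pre-change intercept and slope;
β₀+β₂ and β₁+β₃ the post-change ones. Priors are τ ~ U(1, N) (continuous)
and β ~ N(0, 10⁶). Posterior sampling is component-wise random-walk
Metropolis within Gibbs — three lockstep chains, proposal scales adapted
during burn-in, with a shear-coupled τ proposal that preserves post-change
means while the break location moves.

The intervention effect around the changepoint is then quantified by an
overdispersed Poisson regression on two groups' series,

    log μ = β₀ + β₁·Period + β₂·Group + β₃·Period·Group + log O,

where `exp(β₃)` is the difference-in-differences incidence rate ratio and
`1 − exp(β₃)` the risk reduction; standard errors carry the Pearson
dispersion inflation `√φ`.

## Worked example

`examples/changepoint_fit.py` simulates 40 quarters of school-travel
injury counts for an intervention area — rates rising ≈3% per quarter,
then dropping sharply at quarter 30.5 (the regime's true coefficients are
β = (1.25, 0.03, −1.68, 0.04)) — and refits them:

```
posterior summary (means and 95% credible intervals, log scale):
               mean  ci_low  ci_high
parameter
tau          30.544  30.015   31.518
beta0         1.124   0.820    1.411
beta1         0.031   0.016    0.046
beta2        -1.594  -2.379   -0.848
beta3         0.054  -0.063    0.174
beta0+beta2  -0.470  -1.335    0.360
beta1+beta3   0.085  -0.030    0.201

pre-changepoint rate change per quarter: 3.1% (95% CrI 1.6%, 4.7%)
```

The τ posterior pins the break to the quarter-30/31 boundary; β₁ says the
injury rate was growing ≈3% per quarter before the break, and β₂ a drop of
1 − exp(−1.59) ≈ 80% in level at it. Every parameter's 95% CrI covers the
generating truth, and all R-hat values are below 1.01 (three chains
agree). `examples/did_analysis.py` continues to the
difference-in-differences stage and prints the incidence rate ratios and
the implied risk reduction; `examples/records_pipeline.py` shows the
event-record path: raw timestamps and ages in, filtered quarterly rates
per 10,000 population out.

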