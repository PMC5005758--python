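# Methods

## Problem and data model

The package analyses quarterly counts of pedestrian (and bicyclist)
injuries among school-age children during school-travel hours, stratified
by whether the surrounding area received a safety intervention. The unit of
observation is the quarter × group cell: an integer count `y_t` and a
positive population offset `O_t`. Counts are modelled as independent
Poisson draws whose log mean is piecewise log-linear in time with a single
unknown changepoint τ, the moment the mean structure shifts.

Two nested mean structures are used. The full model (Model 1) lets both the
intercept and the slope shift at τ; the reduced model (Model 2) allows only
a level shift and is the β₁ = β₃ = 0 special case. The reduced model exists
because a level-and-slope model can fail to converge on series with no
discernible time trend, where slope and changepoint compete to explain the
same variation; a comparison (non-intervention) group is typically fit with
Model 2 for exactly that reason.

The step indicator δ(t−τ) is 1 when its argument is non-negative, i.e. the
quarter containing τ already belongs to the post-change regime; with a
continuous τ between integers k and k+1, quarter k+1 is the first
post-change quarter. Because the likelihood depends on τ only through the
set of quarters whose indicator is on, the posterior for τ is piecewise
constant between integer quarters; a posterior concentrated on (30, 31]
therefore has mean ≈ 30.5 — reporting a mid-quarter changepoint is the
natural outcome, not an artefact.

## Inclusion rules and preprocessing

School-age is 5–19 years inclusive. School-travel hours are weekdays
during September–June in the half-open bands [7,9) and [14,16) local time;
the half-open convention avoids double-counting events logged at exactly
9:00 or 16:00, which is a choice this package fixes rather than a fact of
the source data. No school-holiday calendar is applied. Calendar quarters
are Q1 = Jan–Mar, and quarter t = 1 is the first quarter of the configured
start year.

Population denominators come from two decennial census anchors and are
linearly interpolated per quarter, anchored at Q1 of the two census years
(so a 2001 start sits 4 quarters past the 2000 anchor). The anchor-at-Q1
convention is ours; any consistent within-year anchoring changes offsets
by well under the census' own error. Rates are reported per 10,000
population.

## Priors

τ ~ U(1, N) continuous, and every β ~ N(0, 10⁶) — the `beta_sd = 1000`
default is the standard deviation (variance 10⁶). "N(0, 10⁶)" is
conventionally ambiguous between variance and precision parameterisations;
we read it as a diffuse variance, and `PriorSpec` makes the value
configurable for anyone who wants the other reading.

## Sampler

`sample_posterior` is a component-wise random-walk Metropolis-within-Gibbs
sampler written directly against the log posterior. Design points:

- **Chains in lockstep.** All chains (default 3) are advanced as one
  vectorised batch, so a 3-chain, 20,000-iteration fit of a 40-quarter
  series takes a few seconds. Chains are statistically independent; only
  their bookkeeping is shared.
- **Initial values** are overdispersed in τ (evenly spread over the prior
  support: 10/20/30 for three chains on [1,40]) while the coefficients
  start near a flat no-changepoint profile — the intercept at the marginal
  log rate log(Σy/ΣO) with sd-0.5 jitter, slopes and shifts near 0 with
  small jitter. Starting slopes at unit scale instead reliably trapped
  chains in spurious steep-slope local modes (a log-scale slope of 1 per
  quarter implies astronomically large means); flat starts let τ wander
  freely early, which is what finds the break.
- **τ proposals** are a mixture: 90% standard-width, 10% five-times-wider
  steps (mode hopping), and independently 50% of moves are shear-coupled —
  τ moves by ε while β₂ absorbs β₃·ε, which leaves every post-change mean
  invariant except at quarters whose indicator flips. The shear is
  volume-preserving and each mixture component is symmetric, so the plain
  Metropolis acceptance ratio is exact throughout.
- **Adaptation.** During burn-in each proposal scale is multiplied by 0.7
  or 1.4 whenever its acceptance rate over the last 100 iterations leaves
  [0.2, 0.5], capped at half the τ prior span (τ) or twice the prior sd
  (βs) — without the cap, near-certain acceptance in very flat posteriors
  (e.g. prior-only runs) grows the scale without bound and stalls the
  chain. Scales are frozen after burn-in, so the retained draws come from
  a fixed, valid Markov kernel. Reported acceptance rates are post-burn-in.
- **Defaults**: 3 chains × 20,000 iterations, 5,000 burn-in, no thinning.
  The defaults are package choices; the upstream analysis this mirrors did
  not publish its sampler settings.
- **Degenerate inputs**: an all-zero count series is legal (the likelihood
  is well-defined) but emits a warning that τ is weakly identified;
  an empty series or non-positive offsets are errors. Out-of-support τ
  contributes −∞, and overflowing means propagate to −∞ log posteriors and
  are simply rejected.

Model 2 shares all machinery with Model 1; it simply samples (τ, β₀, β₂).
Its posterior equals the β₁ = β₃ = 0 constrained Model 1 posterior up to
the two dropped prior constants, which tests verify.

## Posterior summaries

Draws are pooled across chains after burn-in. Summaries are the posterior
mean and equal-tailed 95% credible interval (2.5th/97.5th percentiles).
Derived quantities — the post-change intercept β₀+β₂, the post-change
slope β₁+β₃, exponentials such as exp(β₀+β₂), and the per-quarter percent
change exp(β₁)−1 — are always computed per draw and then summarised. The
per-draw order is the statistically correct one for nonlinear transforms
(the transform of a mean is not the mean of transforms); whether the
original analysis summed summaries instead is not documented, so the
standard choice is used and stated here.

## Convergence diagnostics

`gelman_rubin` implements the classic potential scale reduction factor:
W the mean within-chain sample variance, B = n·var(chain means),
pooled = ((n−1)/n)W + B/n, R-hat = √(pooled/W). The split variant (each
chain halved first, catching within-chain drift) is available via
`split=True`. Convergence is reported against the conventional 1.1
threshold. Internally constant but disagreeing chains yield an infinite
R-hat sentinel rather than an error. Effective sample size and other
diagnostics are out of scope.

## Difference-in-differences regression

`build_design` turns two quarterly series into the Period × Group design,
with Period = 1 for t ≥ ⌈τ⌉ (a mid-quarter changepoint of 30.5 makes
quarter 31 the first post-period quarter). The observation unit is
quarter × group by default; `collapse="cell"` aggregates to the four
period × group totals — the upstream analysis did not state which unit it
used, so both are provided and the default is declared. A changepoint
outside the window degenerates the design (no post period) and is flagged
as unidentifiable.

Point estimates are Poisson maximum likelihood with offset, computed by
statsmodels' IRLS to tolerance 1e-10. Overdispersion is quasi-Poisson:
φ = Pearson X²/(n−p), covariance = φ × inverse Fisher information, 95%
Wald intervals β ± 1.96·se. The Pearson (not deviance) estimator is the
conventional quasi-Poisson choice. A saturated 2×2 cell fit leaves no
residual degrees of freedom; φ is then set to 1 with a warning rather than
reported as 0/0. The sensitivity comparison (completed interventions vs
partially-completed ones) is the same machinery with a different
comparison-group label; there is no separate code path.

## Synthetic data

The generator produces the study conditions, not a dial to turn. Defaults
emulate the intervention group of the motivating analysis: 40 quarters
from 2001, changepoint 30.5, log-scale coefficients
(1.25, 0.03, −1.68, 0.04) — the posterior means the original analysis
reported — and census anchors (17,000 → 15,400; a ≈9% decade decline in
school-age population, as the study setting had) scaled by
`offset_scale = 10,000` so O_t ≈ 1.6 and pre-change expected counts
average ≈10 per quarter, rising from ≈6 to ≈14 and dropping to ≈3 after
the break. The comparison-group regime used in examples and the acceptance
script is Model 2 with (4.79, −0.29), τ = 10.5, and offsets near 1, giving
≈120 injuries per quarter falling to ≈90.

Event-level records are generated one layer below the counts: per quarter,
a total number of events is drawn as Poisson(μ_t/q_t), where q_t is the
probability a single event survives the school-travel and school-age
filters given an hour-of-day × weekday × month weight profile; each
event's timestamp and age are drawn independently from that profile, so by
Poisson thinning the filtered subtotal is exactly Poisson(μ_t). The
default profile concentrates mass in daytime/after-school hours with a
summer peak, mirroring the empirical pattern that only about a tenth of
school-age pedestrian injuries fall inside the school-travel window. The
within-quarter timing profile and the uniform age draws are modelling
conveniences — no event-time or age distribution is implied by the
quarterly model — and real crash data would add features the generator
does not emulate: secular trends, serial dependence, seasonal count
cycles within the school year, reporting artefacts, and spatial structure.
Passing tests therefore demonstrate correctness of the machinery under the
stated model, not robustness to those violations.

Reproducibility: one user seed feeds a `SeedSequence` whose spawn key
hashes the group label (and purpose), so each group's stream is
deterministic and adding a group never perturbs another's draws.

## Verification strategy and problem sizes

Core numerics are tested against independent oracles: the vectorised log
posterior against a term-by-term scipy evaluation (1e-10 on 100 random
instances), the IRLS DiD fit against the closed-form saturated 2×2
solution (1e-8 on 100 random tables), quantiles against a sort-based
formula, and aggregation against a brute-force re-filter/re-count. The
parameter-recovery study runs 50 seeded replicates of the default regime
at the full 3 × 20,000 sampler settings (about four minutes on one CPU),
checking that the τ posterior mean lands in (29, 32) in ≥90% of runs and
that each coefficient's 95% CrI covers its truth in ≥85% — a joint test of
generator, likelihood, sampler and summaries. Monte-Carlo checks of the
generator use 400–500 replicate series; diagnostics are validated at
n = 10,000 draws per chain.

## Known limitations

- Single changepoint per series; no hierarchical (per-tract) changepoints
  and no model comparison between Models 1 and 2.
- Quarters are treated as exchangeable Poisson observations: no serial
  correlation, no within-school-year seasonality term.
- The DiD inference is quasi-likelihood Wald; no sandwich or
  autocorrelation-robust variance.
- Geocoding of coordinates to areas is out of scope; group membership must
  arrive as a label on each record.
- Whether events logged at exactly 9:00/16:00 were counted by the original
  study is unknown; this package fixes the half-open convention.
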