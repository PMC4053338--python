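# Methods

`carrion` implements the statistical machinery of a camera-trap study of
carnivore scavenging: carcasses are placed on a transect design, every
carnivore visit is recorded with species, time, duration and behaviour,
and the remaining edible biomass is inspected roughly every 14 days.  This
note documents the models, the generating assumptions of the synthetic
studies, the numerical choices, and what the test suite does and does not
establish.

## Study design and data preparation

The design is six transects of five carcasses at 0.05, 1, 2, 3 and 4 km
from the farm–forest boundary, half the transects deployed in winter and
half in spring.  Monitoring of a carcass ends when its mean edible biomass
falls to ≤10% (or prematurely, e.g. stolen cameras; such sites are flagged
`censored` and truncated).

* **Biomass** is recorded per carcass half, to the nearest 5%, and always
  analysed as the mean of the two halves, on the proportion scale [0, 1].
* **Daily series.** The presence models operate on 24-h periods.  The day
  boundary is configurable (`boundary_hour`); the default is midnight
  (calendar days), which keeps series aligned with deployment dates.  The
  *activity clock* is anchored at midday instead, the field convention for
  nocturnal/crepuscular species.  An event spanning a day boundary sets the
  presence flag on every day it intersects.
* **Daily biomass** is linearly interpolated between inspections, exact at
  inspection dates, with no extrapolation outside the inspected window.

## Days to first visit (right-censored discrete-time Weibull)

For carcass *j* on transect *i*, the latent continuous first-visit time has
survivor function S(t) = exp(−λ_ij t^k) with

    log λ_ij = α_season + β · Dtf_ij + u_i,   u_i ~ N(0, σ²_T),

where Dtf is distance to farm in km (carcass 1 enters as 0.05 km by
default; 0 is also supported).  The observable is the day index (deployment
day = 0, first possible visit day = 1), giving interval masses
P(T = t) = S(t−1) − S(t); carcasses never visited contribute S(censor day).
With this parameterisation β > 0 means the visit hazard — and hence the
chance of an early first visit — *increases* with distance to farm.

Priors (configurable): Normal(0, 10²) on intercepts and slope, Gamma(1, 1)
on k, Half-Normal(0, 5²) on σ_T.  k and σ_T are sampled on the log scale
with the Jacobian included.  The per-draw summary of days-to-first-visit
uses the Weibull median (ln 2 / λ)^{1/k}; marginalising the log-normal
transect effect multiplies it by exp(σ²_T / 2k²).

## Daily presence (hierarchical two-state Markov model)

For a focal species, presence on day *t* is Bernoulli with

    logit p_t = a[s, season] + b_d dz + b_d2 dz² + b_b bz + b_b2 bz²
                + c[s] · other_prev + u_transect + v_carcass,

where s ∈ {absent, present} is the species' own previous-day state,
`other_prev` is the *other* species' previous-day state (fox for the dog
model, wild dog for the fox model; one coefficient per previous state,
shared across seasons), and the random intercepts are
u ~ N(0, σ²_T), v ~ N(0, σ²_C).  Chains start in the absent state at
deployment (carcasses begin unvisited).  Both transition-matrix rows are
proper distributions by construction.

Covariates are centred and scaled: distance at 2 km (the design midpoint)
with a 2-km scale, biomass at 0.5 with a 0.5 scale, so both span roughly
[−1, 1] over the design.  Published coefficient tables for this model
family do not state their original centring, so printed coefficients serve
as generating truths and sign/ratio anchors under this package's scaling,
not as reproduction targets.  `exp(coefficient)` converts any coefficient
to an odds multiplier; the two cross-species anchors are exp(0.869) ≈ 2.4
(fox model, previous state absent) and exp(1.361) ≈ 3.9 ≈ 4 (dog model,
previous state present).

The two species are fitted separately with lagged cross terms, as in the
source analysis; the coupled four-state chain exists only in the simulator.

## Biomass decay (penalized-spline mixed model with AR(1) errors)

Observed mean biomass proportions are clamped to [0.001, 0.999] and logit
transformed.  The mean structure is a smooth baseline in days available
plus an *additional* deviation smooth for winter (matching a shared-trend +
winter-deviation formulation), plus cumulative wild-dog and fox
feeding-minute covariates; transect is a random intercept and within-
carcass residuals follow an AR(1) across successive inspections.

The smooth uses a low-rank truncated-cubic radial basis (8 knots at day
quantiles) with a linear null space and a ridge penalty on the radial
coefficients.  Estimation is maximum likelihood in the penalized form:
random coefficients are ridge terms, the AR(1) is handled by whitening each
carcass series (with the |1−ρ²| Jacobian in the likelihood), and the outer
parameters (ρ, two smoothing parameters, transect variance ratio) are
optimised by a coarse ρ grid followed by Nelder–Mead on the profiled
marginal likelihood.  Feeding covariates are z-scored by default; an
explicit (centre, scale) can be fixed — recovery tests fix scale = 100
minutes in both generator and fitter so coefficients are directly
comparable.  R² is the squared correlation of observed and fitted logit
biomass.  Standard errors come from the penalized information matrix
σ̂²(XᵀX + P)⁻¹, the standard Bayesian-style covariance for penalized
splines.

## MCMC engine

An adaptive random-walk Metropolis-within-Gibbs sampler over user-declared
blocks: scalar blocks target 44% acceptance, jointly-proposed vector blocks
23%.  Vector blocks additionally shape their proposals with the empirical
covariance accumulated during burn-in (classic 2.38/√d scaling).  All
adaptation is frozen after burn-in so kept draws satisfy detailed balance.
Two engine features matter for the hierarchical models:

* **Factorized blocks.**  Transect and carcass effects are conditionally
  independent given the rest (the likelihood factorises over groups), so
  all effects in a block are proposed at once and accepted element-wise
  from per-coordinate full-conditional contributions — a valid
  Metropolis-within-Gibbs scan at a fraction of the cost.
* **Block-restricted posteriors.**  A block may supply only the
  log-posterior terms involving its own coordinates; constants cancel in
  the MH ratio.  The daily-presence model partitions its likelihood rows by
  (previous state, season) this way.

Defaults mirror common practice for these models: 3 chains with
over-dispersed starts, 10 000 burn-in, 10 000 further iterations thinned by
10.  Reduced settings (3 chains × 2000 kept) are used in the test suites;
the problem sizes there (24 transects — four times the 30-carcass design —
for the recovery suites, the original six for calibration) were chosen so
each suite completes in minutes while keeping interval coverage at its
nominal level.

Diagnostics: the Gelman–Rubin statistic is computed in the classic
pooled/within form R = √((W + B/n)/W), which is ≥ 1 and exactly 1 for
identical chains (the finite-sample (n−1)/n term of some presentations is
omitted as negligible at these chain lengths); split-R̂ is available as an
option and the convergence gate is max R < 1.05.  DIC = D̄ + p_D with
p_D = D̄ − D(θ̄).  HPD intervals are the shortest sample interval holding
the stated mass.  Posterior-predictive p-values use 5000 replicates by
default, counting ties as ≥.

The discrepancy statistics are package choices (the originals are
unnamed): for the survival models, squared Pearson residuals of the counts
of carcasses visited by days 7, 28 and the horizon; for the Markov models,
squared Pearson residuals of per-carcass presence-day totals.

## Synthetic data generator

The generator is first-class, tested code; its defaults *are* the study
conditions: the 6 × 5 design above, the published posterior-median
parameter sets (`carrion.reference`) as generating truths, logit-linear
seasonal decay reaching 10% near day 77 (spring) and beyond day 98
(winter), AR(1) inspection noise (ρ = 0.4, σ = 0.45) rounded to 5%,
log-normal visit durations moment-matched to the published bout statistics
(wild dog feeding 26.1 ± 33.1 min; fox 22.5 ± 53.6 min), behaviour
frequencies matched to the published feeding shares (57.6% / 48.8%), and
wrapped-normal diel mixtures (dog: dusk-dominant with a dawn shoulder; fox:
nocturnal unimodal).  Event counts per present-day are 1 + Poisson(0.5), a
declared convention — only presence, not event counts, feeds the models.
Events are truncated at the day boundary so event days equal presence days
exactly.  Biomass is generated in two passes: a feeding-free latent curve
drives the presence chains, then final inspections include the feeding
minutes of the simulated events.  Everything is deterministic in the seed
(child streams via `SeedSequence`).

What the generator does **not** emulate: animal movement and spatial
autocorrelation beyond transect/carcass intercepts, weather and elevation
effects on decay, camera failure and imperfect detection, multi-individual
bout structure (pups), and season-by-year differences.  Passing recovery
tests therefore demonstrate that the estimators are correct under the
models' own assumptions — not that the models are adequate for any
particular field dataset.

## Numerical choices and degenerate inputs

* Survival likelihood evaluated in log space:
  log(S(t−1) − S(t)) = −λ(t−1)^k + log(1 − e^{−λΔ}), which stays finite for
  extreme hazards; a truly zero-probability datum returns −∞ and is logged.
* Bernoulli log-likelihoods use `logaddexp`; logits are never exponentiated
  bare.
* All-equal bootstrap samples short-circuit to a zero-width interval
  (the BCa machinery is undefined there).
* HPD on < 20 samples is refused; ties in the minimal window resolve to the
  first (leftmost) window.
* ρ is optimised through arctanh with |ρ| capped at 0.99; the fixture's
  noise-free biomass series drives ρ̂ to that cap, which is expected for
  degenerate deterministic input.
* The 5%-rounding of biomass observations is reproduced by the generator
  but deliberately not modelled by the fitter (it is ~1/10 of the residual
  SD on the logit scale).

## Design choices on genuinely open points

* **Day boundary** for the Markov model: calendar days by default (the
  activity clock's midday anchor applies only to clocks); both are
  supported via `boundary_hour`.
* **Dtf for carcass 1**: 0.05 km by default; 0 km supported.
* **Visit definition** for bout statistics: events separated by < 5 min
  (configurable) merge into one visit; a bout is a visit's total minutes of
  the behaviour.
* **Winter smooth**: shared baseline + winter deviation smooth rather than
  two independent smooths.
* **Interval type in recovery tests**: central (equal-tailed) credible
  intervals, the standard choice for simulation-based calibration; HPD
  intervals are used for reporting summaries.
* **Multi-individual visits** are one event with `n_individuals`; duration
  is camera time, not multiplied by individuals.

## Known limitations

* The frequentist biomass fit profiles smoothing parameters by ML rather
  than REML, which can shrink slightly toward smoother fits at small n.
* The biomass feeding-effect standard errors use the penalized information
  with a REML-style (n − edf) variance but condition on the estimated
  AR(1) correlation, smoothing parameters and transect variance ratio;
  simulation shows they run roughly 10% narrow (Wald coverage ≈ 90%
  rather than 95%).  Point estimates are unbiased (mean errors under 10%
  of truth in the recovery suite).
* The Markov model's intercepts and random-effect variances mix slowly at
  small data volumes (R̂ up to ~1.2 at the reduced test settings); the
  cross-species coefficients, the quantity of scientific interest, mix
  well.  Production analyses should use the full default chain lengths.
* DIC is reported for season-vs-no-season comparison of the survival model;
  broader model selection across the Markov variants is out of scope.
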