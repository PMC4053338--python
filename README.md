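# carrion

Bayesian analysis of carnivore scavenging dynamics at monitored carcasses.

Camera-trap studies of scavenging place large-ungulate carcasses on a
landscape design (here: six transects of five carcasses at 0.05–4 km from
the farm–forest boundary, deployed in winter and spring), record every
carnivore visit with species, time, duration and behaviour, and inspect
the remaining edible biomass at ~14-day intervals.  The scientific
questions are how a carnivore guild — wild dogs/dingoes, red foxes, feral
cats — partitions such an unpredictable food source in space and time, and
how much carnivory, versus decomposition, drives the loss of edible
biomass.

`carrion` implements the full analysis chain for such studies:

* **`carrion.first_visit`** — days to the first visit, a right-censored
  discrete-time Weibull regression:
  S(t) = exp(−λ t^k), log λ = α_season + β·Dtf + u_transect,
  fitted by MCMC; β > 0 means carcasses farther from farms are found
  sooner.
* **`carrion.daily_presence`** — a hierarchical two-state Markov model of
  daily presence: logit P(present_t) is state- and season-specific in
  distance (linear + quadratic), edible biomass (linear + quadratic), and
  whether the *other* species was present the previous day, with transect
  and carcass random intercepts.  `exp(coefficient)` gives odds
  multipliers for the cross-species interactions.
* **`carrion.biomass`** — decay of logit edible biomass: penalized-spline
  season smooths, cumulative dog/fox feeding-time effects, transect random
  intercept and AR(1) within-carcass errors, fitted by penalized maximum
  likelihood.
* **`carrion.activity`** — carcass-use summaries, midday-anchored 24-h
  activity clocks, feeding-bout statistics, BCa bootstrap intervals, and
  interspecific departure–arrival intervals.
* **`carrion.mcmc`** — the shared engine: adaptive random-walk
  Metropolis-within-Gibbs with factorized random-effect blocks,
  Gelman–Rubin diagnostics, DIC, HPD intervals and posterior-predictive
  p-values.
* **`carrion.simulate`** — a synthetic-study generator with known ground
  truth (design, Weibull first visits, coupled presence chains, diel-timed
  events, rounded biomass inspections), so every estimator is verifiable
  by parameter recovery, plus a packaged deterministic 30-carcass study.

A thin CLI (`carrion simulate | fit-first-visit | fit-daily | fit-biomass
| summarize | report`) wraps the same library calls; `examples/` holds one
short narrative script per capability.  See `docs/methods.md` for the
models, assumptions and numerical choices.

## Worked example

Carcass use in the packaged study (`examples/01_carcass_use_summary.py`):

```
  species  n_sites  visited  fed  visited_pct  fed_pct
 wild_dog       30       26   21    86.666667     70.0
      fox       30       29   18    96.666667     60.0
feral_cat       30       13    3    43.333333     10.0

closest interspecific interval: fox -> wild_dog, 10 minutes
```

Wild dogs fed at 70% of the 30 carcasses, foxes at 60%, feral cats at only
10%; the closest the two canids ever came to co-occurring was a fox leaving
ten minutes before wild dogs arrived.

Fitting the first-visit model to a synthetic study generated from the
published wild-dog parameters (`examples/03_first_visit_model.py`, 24
transects):

```
           k  1.586037  ...  hpd 1.348657  1.876223
alpha_spring -5.077767  ...      -6.310911 -3.860584
alpha_winter -6.380817  ...      -7.628811 -5.168429
        beta  0.284611  ...       0.127853  0.411665
spring: median days to first visit at 2 km = 18.7 (9.3-36.2 HPD)
winter: median days to first visit at 2 km = 43.1 (23.7-75.2 HPD)
```

The posterior recovers the generating truth (k = 1.61, β = 0.38 inside the
95% intervals), and spring carcasses are found weeks earlier than winter
ones — the season effect the survival model exists to quantify.

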