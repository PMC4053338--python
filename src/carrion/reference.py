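"""Published reference estimates from a six-transect, 30-carcass field study
of carnivore scavenging at sambar deer carcasses in south-eastern Australia.

These parameter sets serve two roles: as worked examples for the model
surfaces (e.g. converting a cross-species coefficient to an odds
multiplier), and as realistic generating truths for the synthetic-data
module and the parameter-recovery test suites.  The Markov coefficients
are reported without their original covariate centring, which is not
recoverable; under this package they are interpreted on the package's own
default scaling, so they are design anchors for signs, magnitudes and
curve shapes rather than exact reproductions.
"""
from __future__ import annotations

from .daily_presence import MarkovParams
from .first_visit import FirstVisitParams

#: Days-to-first-visit model, wild dogs (posterior medians).
FIRST_VISIT_DOG = FirstVisitParams(
    k=1.61, alpha_spring=-5.38, alpha_winter=-6.60, beta=0.38,
    sigma2_transect=1.74,
)

#: Days-to-first-visit model, red foxes (posterior medians).
FIRST_VISIT_FOX = FirstVisitParams(
    k=1.75, alpha_spring=-6.20, alpha_winter=-5.35, beta=0.08,
    sigma2_transect=1.93,
)

#: Daily-presence Markov model, wild dogs (posterior medians).
#: coefs[(prev_state, season)] = (intercept, dist, dist^2, biomass, biomass^2)
MARKOV_DOG = MarkovParams(
    coefs={
        (0, "spring"): (-2.231, 0.162, -0.137, -0.032, -1.077),
        (0, "winter"): (-0.650, 0.076, -1.067, -1.574, -2.220),
        (1, "spring"): (-2.894, 0.527, -0.445, -0.588, -0.268),
        (1, "winter"): (-0.375, 0.106, -0.127, -1.121, -1.681),
    },
    cross={0: -0.025, 1: 1.361},  # fox present previous day
    sigma2_transect=2.547,
    sigma2_carcass=0.137,
)

#: Daily-presence Markov model, red foxes (posterior medians).
MARKOV_FOX = MarkovParams(
    coefs={
        (0, "spring"): (-3.321, -0.295, 0.235, 0.041, -0.363),
        (0, "winter"): (-3.271, 0.180, 0.181, -0.093, -0.015),
        (1, "spring"): (-3.526, -0.869, 0.352, 0.937, 0.449),
        (1, "winter"): (-1.173, 0.257, 0.126, -0.735, -0.506),
    },
    cross={0: 0.869, 1: -0.061},  # wild dog present previous day
    sigma2_transect=0.372,
    sigma2_carcass=0.856,
)

#: Biomass-decay model anchors (logit scale): feeding-time coefficients are
#: negative (feeding removes biomass); variance on the logit scale.
BIOMASS_REFERENCE = {
    "intercept": -0.521,
    "theta_dog": -0.530,
    "theta_fox": -0.326,
    "within_transect_variance": 0.842,
    "r_squared": 0.736,
}

#: Descriptive study outcomes used by the packaged fixture: of 30 carcasses,
#: counts visited and fed at per species, plus bout statistics (minutes).
USE_SUMMARY_REFERENCE = {
    "wild_dog": {"visited": 26, "fed": 21},
    "fox": {"visited": 29, "fed": 18},
    "feral_cat": {"visited": 13, "fed": 3},
}

BOUT_REFERENCE = {
    "wild_dog": {"feed_mean_min": 26.1, "feed_sd_min": 33.1, "feed_share": 0.576,
                 "total_feed_mean_min": 136.1, "total_feed_ci": (78.5, 242.9)},
    "fox": {"feed_mean_min": 22.5, "feed_sd_min": 53.6, "feed_share": 0.488,
            "total_feed_mean_min": 153.7, "total_feed_ci": (38.9, 594.8)},
}
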