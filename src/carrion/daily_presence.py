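"""Hierarchical two-state Markov model of daily carnivore presence.

For one focal species, the presence state of a carcass on day ``t`` is a
Bernoulli draw whose probability depends on the previous day's state
(separate coefficient sets for previous-absent and previous-present), the
season, centred distance-to-farm (linear + quadratic), centred edible
biomass (linear + quadratic), whether the *other* species was present the
previous day (one coefficient per previous state, shared across seasons),
and transect plus carcass random intercepts:

    logit P(present_t) = a[s, season] + b_d * dz + b_d2 * dz^2
                         + b_b * bz + b_b2 * bz^2
                         + cross[s] * other_prev + u_transect + v_carcass

where ``s`` is the previous-day state.  The two rows of the transition
matrix are proper distributions by construction (P(absent) = 1 - P(present)).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mcmc

log = logging.getLogger(__name__)

PREV_STATES = (0, 1)  # absent, present
_SEASONS = ("spring", "winter")
COEF_NAMES = ("intercept", "b_dist", "b_dist2", "b_bio", "b_bio2")


@dataclass
class CovariateScaling:
    """Centring/scaling for distance (km) and biomass (proportion).

    Defaults centre distance at the 2-km design midpoint with a 2-km scale
    and biomass at 0.5 with a 0.5 scale, so both scaled covariates span
    roughly [-1, 1] over the design.
    """

    distance_center: float = 2.0
    distance_scale: float = 2.0
    biomass_center: float = 0.5
    biomass_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.distance_scale <= 0 or self.biomass_scale <= 0:
            raise ValueError("scales must be > 0")

    def dz(self, distance):
        return (np.asarray(distance, dtype=float) - self.distance_center) / self.distance_scale

    def bz(self, biomass):
        return (np.asarray(biomass, dtype=float) - self.biomass_center) / self.biomass_scale


@dataclass
class MarkovParams:
    """Coefficients of the transition model for one focal species.

    ``coefs[(prev_state, season)]`` holds (intercept, b_dist, b_dist2,
    b_bio, b_bio2); ``cross[prev_state]`` is the other-species-yesterday
    coefficient (shared across seasons).
    """

    coefs: dict[tuple[int, str], tuple[float, float, float, float, float]]
    cross: dict[int, float]
    sigma2_transect: float = 0.0
    sigma2_carcass: float = 0.0
    transect_effects: dict[int, float] | None = None
    carcass_effects: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma2_transect < 0 or self.sigma2_carcass < 0:
            raise ValueError("variances must be >= 0")
        for s in PREV_STATES:
            for season in _SEASONS:
                if (s, season) not in self.coefs:
                    raise ValueError(f"missing coefficient set for {(s, season)}")


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def transition_prob(
    prev_state: int,
    season: str,
    distance: float,
    biomass: float,
    other_prev: int,
    params: MarkovParams,
    scaling: CovariateScaling | None = None,
    transect_id: int | None = None,
    carcass_id: str | None = None,
) -> float:
    """P(present today | yesterday's states and covariates)."""
    if not (0.0 <= biomass <= 1.0):
        raise ValueError("biomass must be in [0, 1]")
    scaling = scaling or CovariateScaling()
    a, bd, bd2, bb, bb2 = params.coefs[(prev_state, season)]
    dz = scaling.dz(distance)
    bz = scaling.bz(biomass)
    eta = a + bd * dz + bd2 * dz**2 + bb * bz + bb2 * bz**2
    eta += params.cross[prev_state] * other_prev
    if params.transect_effects is not None and transect_id is not None:
        eta += params.transect_effects.get(transect_id, 0.0)
    if params.carcass_effects is not None and carcass_id is not None:
        eta += params.carcass_effects.get(carcass_id, 0.0)
    return float(_invlogit(eta))


def odds_multiplier(params: MarkovParams, prev_state: int,
                    which: str = "cross_species", season: str | None = None) -> float:
    """Multiplicative change in the odds of presence per unit of a covariate.

    ``which="cross_species"`` gives the factor associated with the other
    species having been present the previous day.
    """
    if which == "cross_species":
        return float(np.exp(params.cross[prev_state]))
    if season is None:
        raise ValueError("season required for per-season coefficients")
    i = COEF_NAMES.index(which)
    return float(np.exp(params.coefs[(prev_state, season)][i]))


def chain_log_likelihood(
    series: pd.DataFrame,
    params: MarkovParams,
    scaling: CovariateScaling | None = None,
    species: str = "wild_dog",
) -> float:
    """Log-likelihood of the daily presence chains of one or more carcasses.

    ``series`` is a tidy daily frame (columns carcass_id, day_index,
    dog_present, fox_present, biomass, season, distance_to_farm,
    transect_id).  The first row of each carcass is conditioned on an
    initial absent state (carcasses start unvisited).  Gaps in day_index
    raise an error.
    """
    scaling = scaling or CovariateScaling()
    own = "dog_present" if species == "wild_dog" else "fox_present"
    other = "fox_present" if species == "wild_dog" else "dog_present"
    total = 0.0
    for cid, g in series.groupby("carcass_id", sort=True):
        g = g.sort_values("day_index")
        days = g["day_index"].to_numpy()
        if len(days) > 1 and np.any(np.diff(days) != 1):
            raise ValueError(f"gap in day_index for carcass {cid}")
        y = g[own].to_numpy()
        o = g[other].to_numpy()
        prev = np.concatenate([[0], y[:-1]])
        other_prev = np.concatenate([[0], o[:-1]])
        for t in range(len(y)):
            p = transition_prob(
                int(prev[t]),
                str(g["season"].iloc[0]),
                float(g["distance_to_farm"].iloc[0]),
                float(g["biomass"].iloc[t]),
                int(other_prev[t]),
                params,
                scaling,
                transect_id=int(g["transect_id"].iloc[0]),
                carcass_id=str(cid),
            )
            total += np.log(p if y[t] == 1 else 1.0 - p)
    return float(total)


# ---------------------------------------------------------------------------
# MCMC fit


@dataclass
class Priors:
    coef_sd: float = 10.0
    sigma_halfnormal_sd: float = 5.0


def _design(series: pd.DataFrame, scaling: CovariateScaling, species: str):
    """Flatten the chains into per-transition arrays."""
    own = "dog_present" if species == "wild_dog" else "fox_present"
    other = "fox_present" if species == "wild_dog" else "dog_present"
    rows = {k: [] for k in ("y", "g", "other_prev", "tidx", "cidx")}
    X = []
    transects = sorted(series["transect_id"].unique())
    carcasses = sorted(series["carcass_id"].unique())
    t_index = {t: i for i, t in enumerate(transects)}
    c_index = {c: i for i, c in enumerate(carcasses)}
    group_index = {
        (s, season): 2 * s + _SEASONS.index(season)
        for s in PREV_STATES
        for season in _SEASONS
    }
    for cid, g in series.groupby("carcass_id", sort=True):
        g = g.sort_values("day_index")
        days = g["day_index"].to_numpy()
        if len(days) > 1 and np.any(np.diff(days) != 1):
            raise ValueError(f"gap in day_index for carcass {cid}")
        y = g[own].to_numpy(dtype=int)
        o = g[other].to_numpy(dtype=int)
        prev = np.concatenate([[0], y[:-1]])
        oprev = np.concatenate([[0], o[:-1]])
        season = str(g["season"].iloc[0])
        dz = float(scaling.dz(g["distance_to_farm"].iloc[0]))
        bz = scaling.bz(g["biomass"].to_numpy())
        for t in range(len(y)):
            rows["y"].append(y[t])
            rows["g"].append(group_index[(int(prev[t]), season)])
            rows["other_prev"].append(oprev[t])
            rows["tidx"].append(t_index[int(g["transect_id"].iloc[0])])
            rows["cidx"].append(c_index[cid])
            X.append([1.0, dz, dz**2, bz[t], bz[t] ** 2])
    return {
        "y": np.array(rows["y"], dtype=float),
        "g": np.array(rows["g"]),
        "prev": np.array(rows["g"]) // 2,
        "other_prev": np.array(rows["other_prev"], dtype=float),
        "tidx": np.array(rows["tidx"]),
        "cidx": np.array(rows["cidx"]),
        "X": np.array(X),
        "transects": transects,
        "carcasses": carcasses,
        "group_index": group_index,
    }


def _eta(theta, d, n_t, n_c):
    coefs = theta[:20].reshape(4, 5)
    cross = theta[20:22]
    u = theta[22 : 22 + n_t]
    v = theta[22 + n_t : 22 + n_t + n_c]
    eta = np.einsum("ij,ij->i", d["X"], coefs[d["g"]])
    eta += cross[d["prev"]] * d["other_prev"]
    eta += u[d["tidx"]] + v[d["cidx"]]
    return eta


def _bernoulli_ll(y, eta):
    # log p = y*eta - log(1 + exp(eta)), stable via logaddexp
    return y * eta - np.logaddexp(0.0, eta)


def fit(
    series: pd.DataFrame,
    species: str = "wild_dog",
    priors: Priors | None = None,
    scaling: CovariateScaling | None = None,
    config: mcmc.McmcConfig | None = None,
) -> mcmc.PosteriorFit:
    """Fit the hierarchical Markov presence model by MCMC.

    Parameter vector: 4 coefficient sets of 5 (previous-state x season),
    2 cross-species coefficients, transect effects, carcass effects,
    log transect sd, log carcass sd.
    """
    priors = priors or Priors()
    scaling = scaling or CovariateScaling()
    config = config or mcmc.McmcConfig()
    d = _design(series, scaling, species)
    n_t, n_c = len(d["transects"]), len(d["carcasses"])
    if n_t < 2:
        raise ValueError("need >= 2 transects")
    n_params = 22 + n_t + n_c + 2

    # the coefficient/cross part of eta depends on theta[:22] only; the
    # random-effect updates dominate the schedule, so cache it
    _base = {"key": None, "eta": None}

    def base_eta(theta):
        key = theta[:22].tobytes()
        if _base["key"] != key:
            coefs = theta[:20].reshape(4, 5)
            be = np.einsum("ij,ij->i", d["X"], coefs[d["g"]])
            be = be + theta[20:22][d["prev"]] * d["other_prev"]
            _base["key"], _base["eta"] = key, be
        return _base["eta"]

    def full_eta(theta):
        u = theta[22 : 22 + n_t]
        v = theta[22 + n_t : 22 + n_t + n_c]
        return base_eta(theta) + u[d["tidx"]] + v[d["cidx"]]

    def log_posterior(theta):
        eta = full_eta(theta)
        ll = _bernoulli_ll(d["y"], eta).sum()
        sig_t = np.exp(theta[-2])
        sig_c = np.exp(theta[-1])
        u = theta[22 : 22 + n_t]
        v = theta[22 + n_t : 22 + n_t + n_c]
        lp = -0.5 * np.sum((theta[:22] / priors.coef_sd) ** 2)
        lp += -0.5 * (sig_t / priors.sigma_halfnormal_sd) ** 2 + theta[-2]
        lp += -0.5 * (sig_c / priors.sigma_halfnormal_sd) ** 2 + theta[-1]
        lp += -n_t * theta[-2] - 0.5 * np.sum(u**2) / sig_t**2
        lp += -n_c * theta[-1] - 0.5 * np.sum(v**2) / sig_c**2
        return ll + lp

    def component_logp(theta, block_name):
        eta = full_eta(theta)
        ll = _bernoulli_ll(d["y"], eta)
        if block_name == "u":
            per = np.bincount(d["tidx"], weights=ll, minlength=n_t)
            sig = np.exp(theta[-2])
            x = theta[22 : 22 + n_t]
        else:
            per = np.bincount(d["cidx"], weights=ll, minlength=n_c)
            sig = np.exp(theta[-1])
            x = theta[22 + n_t : 22 + n_t + n_c]
        return per - 0.5 * x**2 / sig**2

    # row partitions so each block's MH ratio touches only its own rows
    rows_g = [np.flatnonzero(d["g"] == gi) for gi in range(4)]
    part_g = [
        {k: d[k][rows] for k in ("y", "other_prev", "tidx", "cidx", "prev")}
        | {"X": d["X"][rows]}
        for rows in (rows_g[gi] for gi in range(4))
    ]
    rows_cross = [
        np.flatnonzero((d["prev"] == s) & (d["other_prev"] > 0)) for s in (0, 1)
    ]
    part_cross = [
        {k: d[k][rows] for k in ("y", "g", "tidx", "cidx")} | {"X": d["X"][rows]}
        for rows in rows_cross
    ]
    name_to_gi = {}

    def block_logp(theta, name):
        coefs = theta[:20].reshape(4, 5)
        u = theta[22 : 22 + n_t]
        v = theta[22 + n_t : 22 + n_t + n_c]
        if name.startswith("coefs_"):
            gi = name_to_gi[name]
            p = part_g[gi]
            eta = p["X"] @ coefs[gi]
            eta += theta[20 + gi // 2] * p["other_prev"]
            eta += u[p["tidx"]] + v[p["cidx"]]
            ll = _bernoulli_ll(p["y"], eta).sum()
            return ll - 0.5 * np.sum((coefs[gi] / priors.coef_sd) ** 2)
        if name in ("cross_absent", "cross_present"):
            s = 0 if name == "cross_absent" else 1
            p = part_cross[s]
            eta = np.einsum("ij,ij->i", p["X"], coefs[p["g"]])
            eta += theta[20 + s] + u[p["tidx"]] + v[p["cidx"]]
            ll = _bernoulli_ll(p["y"], eta).sum()
            return ll - 0.5 * (theta[20 + s] / priors.coef_sd) ** 2
        if name == "log_sigma_t":
            sig = np.exp(theta[-2])
            return (
                -0.5 * (sig / priors.sigma_halfnormal_sd) ** 2
                + theta[-2]
                - n_t * theta[-2]
                - 0.5 * np.sum(u**2) / sig**2
            )
        if name == "log_sigma_c":
            sig = np.exp(theta[-1])
            return (
                -0.5 * (sig / priors.sigma_halfnormal_sd) ** 2
                + theta[-1]
                - n_c * theta[-1]
                - 0.5 * np.sum(v**2) / sig**2
            )
        return None

    blocks = []
    for s in PREV_STATES:
        for season in _SEASONS:
            gi = d["group_index"][(s, season)]
            bname = f"coefs_prev{s}_{season}"
            name_to_gi[bname] = gi
            blocks.append(
                mcmc.Block(bname, np.arange(5 * gi, 5 * gi + 5), kind="vector")
            )
    blocks += [
        mcmc.Block("cross_absent", [20]),
        mcmc.Block("cross_present", [21]),
        mcmc.Block("u", np.arange(22, 22 + n_t), kind="factorized"),
        mcmc.Block("v", np.arange(22 + n_t, 22 + n_t + n_c), kind="factorized"),
        mcmc.Block("log_sigma_t", [n_params - 2]),
        mcmc.Block("log_sigma_c", [n_params - 1]),
    ]

    names = []
    for s in PREV_STATES:
        for season in _SEASONS:
            gi = d["group_index"][(s, season)]
            assert gi == len(names) // 5
            names += [f"{c}_prev{s}_{season}" for c in COEF_NAMES]
    names += ["cross_absent", "cross_present"]
    names += [f"u_transect_{t}" for t in d["transects"]]
    names += [f"v_carcass_{c}" for c in d["carcasses"]]
    names += ["sigma2_transect", "sigma2_carcass"]

    def transform(theta):
        out = theta.copy()
        out[-2] = np.exp(2 * theta[-2])
        out[-1] = np.exp(2 * theta[-1])
        return out

    def deviance_fn(nat):
        theta = nat.copy()
        theta[-2] = 0.5 * np.log(max(nat[-2], 1e-300))
        theta[-1] = 0.5 * np.log(max(nat[-1], 1e-300))
        eta = _eta(theta, d, n_t, n_c)
        return -2.0 * _bernoulli_ll(d["y"], eta).sum()

    rng = np.random.default_rng(config.seed + 202)
    inits = []
    for _ in range(config.n_chains):
        th = 0.3 * rng.standard_normal(n_params)
        th[:20:5] = -2.0 + rng.standard_normal(4)  # intercepts
        th[-2:] = np.log(0.7) + 0.3 * rng.standard_normal(2)
        inits.append(th)

    fit_ = mcmc.sample(
        log_posterior,
        np.array(inits),
        config,
        blocks=blocks,
        component_logp=component_logp,
        block_logp=block_logp,
        deviance_fn=deviance_fn,
        names=names,
        transform=transform,
    )
    fit_.meta.update(
        {
            "model": "daily_presence",
            "species": species,
            "transects": [int(t) for t in d["transects"]],
            "carcasses": [str(c) for c in d["carcasses"]],
            "scaling": {
                "distance_center": scaling.distance_center,
                "distance_scale": scaling.distance_scale,
                "biomass_center": scaling.biomass_center,
                "biomass_scale": scaling.biomass_scale,
            },
        }
    )
    if not fit_.converged:
        log.warning("daily-presence fit: max rhat %.3f >= 1.05", float(fit_.rhat.max()))
    return fit_


def params_from_draw(fit: mcmc.PosteriorFit, draw: np.ndarray) -> MarkovParams:
    g = dict(zip(fit.names, draw))
    coefs = {}
    for s in PREV_STATES:
        for season in _SEASONS:
            coefs[(s, season)] = tuple(
                g[f"{c}_prev{s}_{season}"] for c in COEF_NAMES
            )
    return MarkovParams(
        coefs=coefs,
        cross={0: g["cross_absent"], 1: g["cross_present"]},
        sigma2_transect=g["sigma2_transect"],
        sigma2_carcass=g["sigma2_carcass"],
    )


def visit_probability_curve(
    fit: mcmc.PosteriorFit,
    season: str,
    prev_state: int,
    other_prev: int,
    grid: np.ndarray,
    vary: str = "distance",
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior-median transition probability along a covariate grid.

    The other covariate is held at its centre and random effects at zero,
    matching how expected visit-probability curves are usually displayed.
    """
    sc = fit.meta["scaling"]
    scaling = CovariateScaling(**sc)
    pooled = fit.flat()
    g = {n: pooled[:, j] for j, n in enumerate(fit.names)}
    a = g[f"intercept_prev{prev_state}_{season}"]
    bd = g[f"b_dist_prev{prev_state}_{season}"]
    bd2 = g[f"b_dist2_prev{prev_state}_{season}"]
    bb = g[f"b_bio_prev{prev_state}_{season}"]
    bb2 = g[f"b_bio2_prev{prev_state}_{season}"]
    cross = g["cross_absent" if prev_state == 0 else "cross_present"]
    rows = []
    for x in np.asarray(grid, dtype=float):
        if vary == "distance":
            dz, bz = float(scaling.dz(x)), 0.0
        elif vary == "biomass":
            dz, bz = 0.0, float(scaling.bz(x))
        else:
            raise ValueError("vary must be 'distance' or 'biomass'")
        eta = a + bd * dz + bd2 * dz**2 + bb * bz + bb2 * bz**2 + cross * other_prev
        p = _invlogit(eta)
        lo, hi = mcmc.hpd_interval(p, level)
        rows.append({"grid": x, "median": float(np.median(p)), "hpd_lo": lo, "hpd_hi": hi})
    return pd.DataFrame(rows)
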