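"""Markov-model transition probabilities, likelihood oracle, and small fits."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from carrion import daily_presence, mcmc, reference, simulate
from carrion.daily_presence import (
    CovariateScaling,
    MarkovParams,
    chain_log_likelihood,
    odds_multiplier,
    transition_prob,
)


def flat_params(**kw):
    base = dict(
        coefs={(s, sea): (0.0, 0, 0, 0, 0)
               for s in (0, 1) for sea in ("spring", "winter")},
        cross={0: 0.0, 1: 0.0},
        sigma2_transect=0.0, sigma2_carcass=0.0,
        transect_effects={}, carcass_effects={},
    )
    base.update(kw)
    return MarkovParams(**base)


class TestTransitionProb:
    def test_all_zero_gives_half(self):
        p = transition_prob(0, "spring", 2.0, 0.5, 0, flat_params())
        assert p == pytest.approx(0.5)

    def test_published_intercept_arithmetic(self):
        # inverse-logit of the published spring not-present intercept
        params = reference.MARKOV_DOG
        p = transition_prob(0, "spring", 2.0, 0.5, 0, params,
                            CovariateScaling())
        assert p == pytest.approx(1.0 / (1.0 + math.exp(2.231)), rel=1e-12)
        assert round(p, 3) == 0.097

    def test_cross_coefficient_monotone(self):
        last = -1.0
        for c in (0.0, 0.5, 1.0, 2.0):
            p = transition_prob(
                0, "spring", 2.0, 0.5, 1, flat_params(cross={0: c, 1: 0.0})
            )
            assert p > last
            last = p

    def test_rows_sum_to_one_by_construction(self):
        p1 = transition_prob(1, "winter", 3.0, 0.8, 1, reference.MARKOV_FOX)
        assert 0.0 < p1 < 1.0
        assert p1 + (1.0 - p1) == 1.0

    def test_biomass_out_of_range(self):
        with pytest.raises(ValueError):
            transition_prob(0, "spring", 2.0, 1.2, 0, flat_params())


class TestOddsMultiplier:
    def test_zero_coefficient_is_unity(self):
        assert odds_multiplier(flat_params(), 0) == 1.0

    def test_published_fox_multiplier(self):
        # dog-yesterday coefficient 0.869 for foxes not present previous day
        m = odds_multiplier(reference.MARKOV_FOX, 0)
        assert m == pytest.approx(math.exp(0.869), rel=1e-12)
        assert round(m, 1) == 2.4

    def test_published_dog_multiplier(self):
        # fox-yesterday coefficient 1.361 for dogs present previous day
        m = odds_multiplier(reference.MARKOV_DOG, 1)
        assert m == pytest.approx(math.exp(1.361), rel=1e-12)
        assert round(m) == 4


def toy_series(states, other=None, biomass=None, season="spring"):
    n = len(states)
    return pd.DataFrame(
        {
            "carcass_id": "c1",
            "day_index": np.arange(1, n + 1),
            "dog_present": states,
            "fox_present": other if other is not None else [0] * n,
            "biomass": biomass if biomass is not None else [0.5] * n,
            "transect_id": 1,
            "season": season,
            "distance_to_farm": 2.0,
        }
    )


class TestChainLogLikelihood:
    def test_single_day_half(self):
        assert chain_log_likelihood(toy_series([1]), flat_params()) == (
            pytest.approx(math.log(0.5))
        )

    def test_product_of_transitions_oracle(self):
        params = MarkovParams(
            coefs={
                (0, "spring"): (-1.0, 0.3, -0.2, 0.5, -0.4),
                (1, "spring"): (0.5, -0.1, 0.0, 1.0, 0.2),
                (0, "winter"): (0.0, 0, 0, 0, 0),
                (1, "winter"): (0.0, 0, 0, 0, 0),
            },
            cross={0: 0.8, 1: -0.3},
            sigma2_transect=0.2, sigma2_carcass=0.1,
            transect_effects={1: 0.15}, carcass_effects={"c1": -0.25},
        )
        states = [0, 1, 1, 0, 1, 0]
        other = [1, 0, 1, 1, 0, 0]
        biomass = [1.0, 0.9, 0.7, 0.55, 0.4, 0.3]
        series = toy_series(states, other, biomass)
        # direct product oracle
        expected = 0.0
        prev, oprev = 0, 0
        for t in range(6):
            p = transition_prob(prev, "spring", 2.0, biomass[t], oprev, params,
                                transect_id=1, carcass_id="c1")
            expected += math.log(p if states[t] else 1 - p)
            prev, oprev = states[t], other[t]
        assert chain_log_likelihood(series, params) == pytest.approx(
            expected, abs=1e-12
        )

    def test_total_probability_over_all_sequences(self):
        # enumeration: probabilities of all 2^6 dog sequences sum to 1
        params = MarkovParams(
            coefs={
                (0, "spring"): (-0.7, 0.2, -0.1, 0.4, -0.3),
                (1, "spring"): (0.3, 0.1, 0.0, -0.5, 0.1),
                (0, "winter"): (0.0, 0, 0, 0, 0),
                (1, "winter"): (0.0, 0, 0, 0, 0),
            },
            cross={0: 0.5, 1: -0.2},
            sigma2_transect=0.0, sigma2_carcass=0.0,
            transect_effects={}, carcass_effects={},
        )
        other = [1, 0, 0, 1, 0, 1]
        biomass = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        total = 0.0
        for states in itertools.product([0, 1], repeat=6):
            ll = chain_log_likelihood(
                toy_series(list(states), other, biomass), params
            )
            total += math.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_carcass_order_invariance(self):
        params = flat_params(cross={0: 0.4, 1: 0.1})
        s1 = toy_series([0, 1, 1])
        s2 = toy_series([1, 0, 1]).assign(carcass_id="c2")
        a = chain_log_likelihood(pd.concat([s1, s2]), params)
        b = chain_log_likelihood(pd.concat([s2, s1]), params)
        assert a == pytest.approx(b, abs=1e-12)

    def test_gap_rejected(self):
        s = toy_series([0, 1, 1])
        s.loc[2, "day_index"] = 5
        with pytest.raises(ValueError, match="gap"):
            chain_log_likelihood(s, flat_params())


class TestFit:
    def make_series(self, truth_markov, n_transects=4, n_days=50, seed=0):
        truth = simulate.SimTruth()
        truth.markov = {"wild_dog": truth_markov, "fox": flat_params(
            coefs={(s, sea): (-1.5, 0, 0, 0, 0)
                   for s in (0, 1) for sea in ("spring", "winter")}
        )}
        sites = simulate.generate_design(n_transects=n_transects, seed=seed)
        traj = {s.carcass_id: np.linspace(0.95, 0.2, n_days) for s in sites}
        return simulate.simulate_daily_presence(truth, sites, traj, seed=seed + 1)

    def test_seed_reproducible(self):
        series = self.make_series(flat_params(), n_transects=2, n_days=20)
        cfg = mcmc.McmcConfig(n_chains=2, n_burnin=80, n_keep=60, thin=1, seed=4)
        f1 = daily_presence.fit(series, config=cfg)
        f2 = daily_presence.fit(series, config=cfg)
        assert np.array_equal(f1.draws, f2.draws)

    def test_null_covariate_effects_covered(self):
        truth = flat_params(
            coefs={(s, sea): (-1.0, 0, 0, 0, 0)
                   for s in (0, 1) for sea in ("spring", "winter")},
            sigma2_transect=0.05, sigma2_carcass=0.05,
            transect_effects=None, carcass_effects=None,
        )
        series = self.make_series(truth, n_transects=6, n_days=60, seed=2)
        cfg = mcmc.McmcConfig(n_chains=3, n_burnin=600, n_keep=800, thin=1, seed=5)
        fit = daily_presence.fit(series, species="wild_dog", config=cfg)
        for name in ("b_dist_prev0_spring", "b_bio_prev0_spring",
                     "cross_absent", "cross_present"):
            lo, hi = mcmc.hpd_interval(fit.flat(name), 0.95)
            assert lo <= 0.0 <= hi, name


class TestCurve:
    def point_mass_fit(self, coefs, cross=(0.0, 0.0)):
        params = flat_params()
        names, row = [], []
        for s in (0, 1):
            for sea in ("spring", "winter"):
                cc = coefs.get((s, sea), (0, 0, 0, 0, 0))
                for cname, v in zip(daily_presence.COEF_NAMES, cc):
                    names.append(f"{cname}_prev{s}_{sea}")
                    row.append(v)
        names += ["cross_absent", "cross_present", "sigma2_transect",
                  "sigma2_carcass"]
        row += [cross[0], cross[1], 0.0, 0.0]
        draws = np.tile(np.array(row, dtype=float), (2, 30, 1))
        fit = mcmc.PosteriorFit(names=names, draws=draws,
                                rhat=np.ones(len(names)), acceptance={})
        fit.meta["scaling"] = dict(distance_center=2.0, distance_scale=2.0,
                                   biomass_center=0.5, biomass_scale=0.5)
        return fit

    def test_point_mass_curve_equals_transition_prob(self):
        coefs = {(0, "spring"): (-1.2, 0.4, -0.3, 0.2, -0.1)}
        fit = self.point_mass_fit(coefs, cross=(0.6, 0.0))
        grid = np.array([0.05, 1.0, 2.0, 3.0, 4.0])
        curve = daily_presence.visit_probability_curve(fit, "spring", 0, 1, grid)
        params = flat_params(coefs={(s, sea): coefs.get((s, sea), (0,) * 5)
                                    for s in (0, 1)
                                    for sea in ("spring", "winter")},
                             cross={0: 0.6, 1: 0.0})
        for x, med in zip(grid, curve["median"]):
            assert med == pytest.approx(
                transition_prob(0, "spring", x, 0.5, 1, params), rel=1e-12
            )

    def test_symmetric_quadratic_peaks_at_center(self):
        fit = self.point_mass_fit({(0, "spring"): (-1.0, 0.0, -0.8, 0, 0)})
        grid = np.linspace(0.05, 3.95, 40)
        curve = daily_presence.visit_probability_curve(fit, "spring", 0, 0, grid)
        peak = grid[np.argmax(curve["median"].to_numpy())]
        assert abs(peak - 2.0) < 0.1
        # concave response with an interior maximum
        assert curve["median"].iloc[0] < curve["median"].max()
        assert curve["median"].iloc[-1] < curve["median"].max()
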