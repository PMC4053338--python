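"""Generator properties: determinism, design structure, and agreement of the
simulated processes with their generating laws."""
import dataclasses
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from carrion import simulate
from carrion.daily_presence import MarkovParams
from carrion.first_visit import FirstVisitParams
from carrion.simulate import BiomassTruth, SimTruth


def flat_params(intercept, cross0=0.0, cross1=0.0):
    return MarkovParams(
        coefs={(s, sea): (intercept, 0, 0, 0, 0)
               for s in (0, 1) for sea in ("spring", "winter")},
        cross={0: cross0, 1: cross1},
        sigma2_transect=0.0,
        sigma2_carcass=0.0,
        transect_effects={},
        carcass_effects={},
    )


class TestDesign:
    def test_default_design_is_thirty_sites(self):
        sites = simulate.generate_design()
        assert len(sites) == 30
        assert len({s.transect_id for s in sites}) == 6
        for t in range(1, 7):
            dists = sorted(
                s.distance_to_farm for s in sites if s.transect_id == t
            )
            assert dists == [0.05, 1.0, 2.0, 3.0, 4.0]
        assert {s.season for s in sites} == {"winter", "spring"}

    def test_single_transect(self):
        assert len(simulate.generate_design(n_transects=1)) == 5

    def test_seed_determinism(self):
        assert simulate.generate_design(seed=7) == simulate.generate_design(seed=7)


class TestFirstVisits:
    def test_vanishing_rate_censors_everything(self):
        truth = FirstVisitParams(k=1.0, alpha_spring=-30, alpha_winter=-30,
                                 beta=0.0, sigma2_transect=0.0)
        sites = simulate.generate_design(n_transects=2, seed=0)
        fv = simulate.simulate_first_visits(truth, sites, horizon_days=50, seed=1)
        assert not fv["observed"].any()
        assert (fv["day"] == 50).all()

    def test_exponential_mean_closed_form(self):
        # k = 1 reduces to an exponential with mean 1/lambda
        lam = 0.2
        truth = FirstVisitParams(k=1.0, alpha_spring=np.log(lam),
                                 alpha_winter=np.log(lam), beta=0.0,
                                 sigma2_transect=0.0)
        sites = simulate.generate_design(n_transects=600, seed=2)
        fv = simulate.simulate_first_visits(truth, sites, horizon_days=10_000, seed=3)
        # discretised day = ceil(T), so E[day] ~ 1/lam + 0.5
        assert fv["day"].mean() == pytest.approx(1 / lam + 0.5, rel=0.05)

    def test_positive_distance_slope_means_earlier_visits_far_from_farm(self):
        from carrion import reference

        truth = dataclasses.replace(reference.FIRST_VISIT_DOG, sigma2_transect=0.0)
        sites = simulate.generate_design(n_transects=800, seed=4)
        spring = [s for s in sites if s.season == "spring"]
        fv = simulate.simulate_first_visits(truth, spring, horizon_days=10_000, seed=5)
        near = fv[fv["distance"] == 0.05]["day"].mean()
        far = fv[fv["distance"] == 4.0]["day"].mean()
        assert far < near


class TestDailyPresence:
    def _run(self, truth, n_transects=4, n_days=60, seed=0, biomass=0.5):
        sites = simulate.generate_design(n_transects=n_transects, seed=11)
        traj = {s.carcass_id: np.full(n_days, biomass) for s in sites}
        return simulate.simulate_daily_presence(truth, sites, traj, seed=seed)

    def test_huge_negative_intercept_gives_all_absent(self):
        truth = SimTruth()
        truth.markov = {"wild_dog": flat_params(-20.0), "fox": flat_params(-20.0)}
        pres = self._run(truth)
        assert pres["dog_present"].sum() == 0
        assert pres["fox_present"].sum() == 0

    def test_zero_coefficients_give_half_occupancy(self):
        truth = SimTruth()
        truth.markov = {"wild_dog": flat_params(0.0), "fox": flat_params(0.0)}
        pres = self._run(truth, n_transects=10, n_days=200, seed=1)
        assert pres["dog_present"].mean() == pytest.approx(0.5, abs=0.03)
        assert pres["fox_present"].mean() == pytest.approx(0.5, abs=0.03)

    def test_positive_dog_to_fox_cross_effect(self):
        truth = SimTruth()
        truth.markov = {
            "wild_dog": flat_params(0.0),
            "fox": flat_params(-1.0, cross0=1.5, cross1=1.5),
        }
        pres = self._run(truth, n_transects=10, n_days=300, seed=2)
        g = pres.sort_values(["carcass_id", "day_index"])
        dog_prev = g.groupby("carcass_id")["dog_present"].shift(1)
        m = dog_prev.notna()
        p1 = g["fox_present"][m & (dog_prev == 1)].mean()
        p0 = g["fox_present"][m & (dog_prev == 0)].mean()
        assert p1 > p0

    def test_transition_frequencies_match_generating_probabilities(self):
        # oracle: direct counting against the known transition matrix
        truth = SimTruth()
        p_stay_abs, p_gain = 0.2, 0.6  # P(present | absent), P(present | present)
        from scipy.special import logit

        truth.markov = {
            "wild_dog": flat_params(0.0),
            "fox": MarkovParams(
                coefs={(0, sea): (logit(p_stay_abs), 0, 0, 0, 0)
                       for sea in ("spring", "winter")}
                | {(1, sea): (logit(p_gain), 0, 0, 0, 0)
                   for sea in ("spring", "winter")},
                cross={0: 0.0, 1: 0.0},
                sigma2_transect=0.0, sigma2_carcass=0.0,
                transect_effects={}, carcass_effects={},
            ),
        }
        pres = self._run(truth, n_transects=10, n_days=400, seed=3)
        g = pres.sort_values(["carcass_id", "day_index"])
        prev = g.groupby("carcass_id")["fox_present"].shift(1)
        m = prev.notna()
        for prev_state, p_true in ((0, p_stay_abs), (1, p_gain)):
            sel = g["fox_present"][m & (prev == prev_state)]
            se = np.sqrt(p_true * (1 - p_true) / len(sel))
            assert abs(sel.mean() - p_true) < 3 * se


class TestBiomass:
    def test_zero_noise_zero_feeding_deterministic_curve(self, small_site):
        truth = BiomassTruth(sigma=0.0)
        a = simulate.simulate_biomass(truth, small_site, seed=1, round_to=None)
        b = simulate.simulate_biomass(truth, small_site, seed=99, round_to=None)
        assert a == b
        means = [x.mean_biomass for x in a]
        assert all(np.diff(means) < 0)

    def test_winter_decays_slower_than_spring(self, small_site):
        truth = BiomassTruth(sigma=0.0)
        winter = small_site
        spring = dataclasses.replace(small_site, season="spring",
                                     carcass_id="x2")
        w = simulate.simulate_biomass(truth, winter, seed=0, round_to=None,
                                      horizon_days=70)
        s = simulate.simulate_biomass(truth, spring, seed=0, round_to=None,
                                      horizon_days=70)
        for wi, si in zip(w[1:], s[1:]):
            assert wi.mean_biomass > si.mean_biomass

    def test_ar1_autocorrelation_recovered(self, small_site):
        truth = BiomassTruth(rho=0.6, sigma=0.5)
        resid_pairs = []
        from carrion.biomass import logit_clamped

        for r in range(400):
            insp = simulate.simulate_biomass(
                truth, small_site, seed=r, round_to=None, horizon_days=140
            )
            days = np.array([(b.date - small_site.deploy_date).days for b in insp])
            mean = truth.mean_logit(days, small_site.season)
            e = logit_clamped([b.mean_biomass for b in insp]) - mean
            resid_pairs.extend(zip(e[1:-1], e[2:]))  # skip forced day-0 value
        e0, e1 = np.array(resid_pairs).T
        assert np.corrcoef(e0, e1)[0, 1] == pytest.approx(truth.rho, abs=0.08)

    def test_rounded_to_five_percent_grid(self, small_site):
        insp = simulate.simulate_biomass(BiomassTruth(), small_site, seed=5)
        for b in insp:
            assert (b.front_half * 20) == pytest.approx(round(b.front_half * 20))


class TestEvents:
    def test_empty_presence_no_events(self):
        truth = SimTruth()
        pres = pd.DataFrame(
            columns=["carcass_id", "day_index", "dog_present", "fox_present"]
        )
        assert simulate.simulate_events(pres, truth, [], seed=0) == []

    def test_event_days_equal_presence_days(self):
        sites, events, _, truth = simulate.simulate_study(seed=3, n_transects=2)
        by_id = {s.carcass_id: s for s in sites}
        traj_days = {}
        for e in events:
            if e.species == "feral_cat":
                continue
            d = (e.start_time.date() - by_id[e.carcass_id].deploy_date).days
            traj_days.setdefault((e.carcass_id, e.species), set()).add(d)
        # rebuild the presence chain the generator used
        root = np.random.SeedSequence(truth.seed)
        seeds = [int(ss.generate_state(1)[0] % (2**31)) for ss in root.spawn(5)]
        design = simulate.generate_design(n_transects=2, seed=seeds[0], horizon_days=98)
        from carrion.biomass import inv_logit

        traj = {
            s.carcass_id: np.asarray(
                inv_logit(truth.biomass.mean_logit(
                    np.arange(1, s.n_monitored_days), s.season))
            )
            for s in design
        }
        pres = simulate.simulate_daily_presence(truth, design, traj, seed=seeds[2])
        for sp, col in (("wild_dog", "dog_present"), ("fox", "fox_present")):
            for cid, g in pres.groupby("carcass_id"):
                # monitoring (and hence the event table) is truncated at the
                # inspection where biomass reached 10%
                site = by_id[cid]
                last = (site.removal_date - site.deploy_date).days
                expected = set(g[(g[col] == 1) & (g["day_index"] <= last)]["day_index"])
                assert traj_days.get((cid, sp), set()) == expected

    def test_dog_activity_concentrated_dusk(self):
        from carrion import activity

        sites, events, _, _ = simulate.simulate_study(seed=4, n_transects=6)
        clock = activity.activity_clock(events, "wild_dog", monitored_days=1)
        total = clock.bins.sum()
        window = sum(clock.bins[(16 - 12 + i) % 24] for i in range(6))  # 16:00-22:00
        assert window / total >= 0.5


class TestStudyDeterminism:
    def test_same_seed_identical_distinct_seeds_differ(self):
        a = simulate.simulate_study(seed=11, n_transects=2)
        b = simulate.simulate_study(seed=11, n_transects=2)
        c = simulate.simulate_study(seed=12, n_transects=2)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]
        assert a[1] != c[1]

    def test_generated_tables_pass_validators(self, tmp_path):
        from carrion import data

        sites, events, inspections, _ = simulate.simulate_study(seed=13, n_transects=2)
        data.write_sites(sites, tmp_path / "s.csv")
        data.write_events(events, tmp_path / "e.csv")
        data.write_inspections(inspections, tmp_path / "i.csv")
        assert data.read_sites(tmp_path / "s.csv") == sites
        assert len(data.read_events(tmp_path / "e.csv")) == len(events)
        assert len(data.read_inspections(tmp_path / "i.csv")) == len(inspections)


class TestPackagedFixture:
    def test_headline_counts(self, fixture_study):
        from carrion import activity

        sites, events, _ = fixture_study
        use = activity.carcass_use_summary(events, sites).set_index("species")
        assert use.loc["wild_dog", "visited"] == 26
        assert use.loc["wild_dog", "fed"] == 21
        assert use.loc["wild_dog", "fed_pct"] == pytest.approx(70.0)
        assert use.loc["fox", "visited"] == 29
        assert use.loc["fox", "fed"] == 18
        assert use.loc["feral_cat", "visited"] == 13
        assert use.loc["feral_cat", "fed"] == 3

    def test_deterministic(self, fixture_study):
        again = simulate.packaged_fixture()
        assert again[0] == fixture_study[0]
        assert again[1] == fixture_study[1]

    def test_one_censored_site(self, fixture_study):
        sites, _, _ = fixture_study
        stolen = [s for s in sites if s.censored]
        assert len(stolen) == 1
        assert stolen[0].n_monitored_days == 14
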