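"""End-to-end pipeline: data in, fitted models and a JSON report out.

``run_pipeline`` wires the stages — load or simulate a study, build daily
series, fit the first-visit survival model, the daily-presence Markov
model and the biomass smooth, and compute the descriptive summaries —
collecting convergence diagnostics, Bayesian p-values, DIC deltas, odds
multipliers and the carcass-use table into one report dictionary.  Every
output carries the seed and a hash of the configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, biomass, daily_presence, data, first_visit, mcmc, simulate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one pipeline run (YAML-serialisable)."""

    seed: int = 0
    data_dir: str | None = None  # read events/sites/inspections CSVs here
    use_fixture: bool = False  # use the packaged deterministic study
    out_dir: str | None = None
    species: tuple[str, ...] = ("wild_dog", "fox")
    n_chains: int = 3
    n_burnin: int = 1000
    n_keep: int = 2000
    thin: int = 1
    n_ppc: int = 500  # posterior-predictive replicates
    n_boot: int = 2000
    fit_survival: bool = True
    fit_presence: bool = True
    fit_biomass: bool = True
    compare_season_dic: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_study(config: RunConfig):
    if config.use_fixture:
        return simulate.packaged_fixture()
    if config.data_dir is not None:
        d = Path(config.data_dir)
        return (
            data.read_sites(d / "sites.csv"),
            data.read_events(d / "events.csv"),
            data.read_inspections(d / "inspections.csv"),
        )
    sites, events, inspections, _ = simulate.simulate_study(seed=config.seed)
    return sites, events, inspections


def first_visit_table(events, sites) -> pd.DataFrame:
    """Per-species first-visit days with censor flags from raw tables."""
    frames = {}
    for sp in ("wild_dog", "fox"):
        rows = []
        for s in sites:
            times = [
                e.start_time for e in events
                if e.carcass_id == s.carcass_id and e.species == sp
            ]
            n_days = s.n_monitored_days or 1
            if times:
                day = max((min(times).date() - s.deploy_date).days, 1)
                rows.append((s, day, True))
            else:
                rows.append((s, max(n_days - 1, 1), False))
        frames[sp] = pd.DataFrame(
            {
                "carcass_id": [r[0].carcass_id for r in rows],
                "transect_id": [r[0].transect_id for r in rows],
                "distance": [r[0].distance_to_farm for r in rows],
                "season": [r[0].season for r in rows],
                "day": [r[1] for r in rows],
                "observed": [r[2] for r in rows],
            }
        )
    return frames


def daily_series_table(events, inspections, sites) -> pd.DataFrame:
    insp_by_site: dict[str, list] = {}
    for b in inspections:
        insp_by_site.setdefault(b.carcass_id, []).append(b)
    frames = []
    for s in sites:
        recs = data.build_daily_series(
            [e for e in events if e.carcass_id == s.carcass_id],
            insp_by_site.get(s.carcass_id, []),
            s,
        )
        frames.append(data.daily_series_frame(recs, s))
    return pd.concat(frames, ignore_index=True)


def _survival_ppc(fit, table, seed, n_rep):
    """Bayesian p-value: squared Pearson residuals of the counts of
    carcasses visited by days 7, 28 and the horizon."""
    horizon = int(table["day"].max())
    checkpoints = [7, 28, horizon]

    def counts(tbl):
        return np.array(
            [int(((tbl["observed"]) & (tbl["day"] <= c)).sum()) for c in checkpoints]
        )

    def expected(theta):
        params = first_visit.params_from_draw(fit, theta)
        exp_c = np.zeros(len(checkpoints))
        for row in table.itertuples(index=False):
            s = [
                1.0
                - first_visit.survival(
                    min(c, row.day if not row.observed else c),
                    params, row.distance, row.season, row.transect_id,
                )
                for c in checkpoints
            ]
            exp_c += np.array(s)
        return np.maximum(exp_c, 1e-8)

    def discrepancy(tbl, theta):
        e = expected(theta)
        return float(np.sum((counts(tbl) - e) ** 2 / e))

    def replicate(theta, rng):
        params = first_visit.params_from_draw(fit, theta)
        rows = []
        for row in table.itertuples(index=False):
            lam = params.rate(row.distance, row.season, row.transect_id)
            t_cont = (rng.exponential() / lam) ** (1.0 / params.k)
            day = max(int(np.ceil(t_cont)), 1)
            observed = day <= horizon
            rows.append(
                {
                    "day": day if observed else horizon,
                    "observed": observed,
                    "distance": row.distance,
                    "season": row.season,
                    "transect_id": row.transect_id,
                }
            )
        return pd.DataFrame(rows)

    return mcmc.posterior_predictive_pvalue(
        fit, replicate, discrepancy, table, n_rep=n_rep, seed=seed
    )


def _presence_ppc(fit, series, species, seed, n_rep):
    """Bayesian p-value: squared Pearson residuals of per-carcass
    presence-day totals."""
    own = "dog_present" if species == "wild_dog" else "fox_present"
    scaling = daily_presence.CovariateScaling(**fit.meta["scaling"])

    def per_carcass_totals(df):
        return df.groupby("carcass_id", sort=True)[own].sum().to_numpy(dtype=float)

    def expected(theta):
        params = daily_presence.params_from_draw(fit, theta)
        out = []
        for cid, g in series.groupby("carcass_id", sort=True):
            g = g.sort_values("day_index")
            other = "fox_present" if species == "wild_dog" else "dog_present"
            y = g[own].to_numpy()
            o = g[other].to_numpy()
            prev = np.concatenate([[0], y[:-1]])
            oprev = np.concatenate([[0], o[:-1]])
            tot = 0.0
            for t in range(len(y)):
                tot += daily_presence.transition_prob(
                    int(prev[t]), str(g["season"].iloc[0]),
                    float(g["distance_to_farm"].iloc[0]),
                    float(g["biomass"].iloc[t]), int(oprev[t]), params, scaling,
                )
            out.append(tot)
        return np.maximum(np.array(out), 1e-8)

    def discrepancy(df, theta):
        e = expected(theta)
        return float(np.sum((per_carcass_totals(df) - e) ** 2 / e))

    def replicate(theta, rng):
        params = daily_presence.params_from_draw(fit, theta)
        frames = []
        for cid, g in series.groupby("carcass_id", sort=True):
            g = g.sort_values("day_index").copy()
            other = "fox_present" if species == "wild_dog" else "dog_present"
            o = g[other].to_numpy()
            oprev = np.concatenate([[0], o[:-1]])
            bio = g["biomass"].to_numpy()
            season = str(g["season"].iloc[0])
            dist = float(g["distance_to_farm"].iloc[0])
            y = np.zeros(len(g), dtype=int)
            prev = 0
            for t in range(len(g)):
                p = daily_presence.transition_prob(
                    prev, season, dist, float(bio[t]), int(oprev[t]), params, scaling
                )
                y[t] = rng.random() < p
                prev = y[t]
            g[own] = y
            frames.append(g)
        return pd.concat(frames, ignore_index=True)

    return mcmc.posterior_predictive_pvalue(
        fit, replicate, discrepancy, series, n_rep=n_rep, seed=seed
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and optionally write) the report."""
    sites, events, inspections = load_study(config)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_sites": len(sites),
    }

    use = activity.carcass_use_summary(events, sites)
    report["use_summary"] = use.to_dict(orient="records")
    monitored_days = int(sum(s.n_monitored_days or 0 for s in sites))
    report["bout_stats"] = [
        activity.bout_stats(events, sp) for sp in ("wild_dog", "fox")
    ]
    report["activity_clock_total_minutes"] = {
        sp: float(
            activity.activity_clock(events, sp, monitored_days).bins.sum()
            * monitored_days
        )
        for sp in ("wild_dog", "fox")
    }
    iv = activity.interspecies_intervals(events)
    report["closest_interval_minutes"] = (
        float(iv[iv["gap_minutes"] > 0]["gap_minutes"].min()) if len(iv) else None
    )

    mcfg = mcmc.McmcConfig(
        n_chains=config.n_chains, n_burnin=config.n_burnin,
        n_keep=config.n_keep, thin=config.thin, seed=config.seed,
    )

    if config.fit_survival:
        tables = first_visit_table(events, sites)
        report["first_visit"] = {}
        for sp in config.species:
            fit = first_visit.fit(tables[sp], config=mcfg)
            entry = {
                "max_rhat": float(fit.rhat.max()),
                "converged": fit.converged,
                "posterior_median": {
                    n: float(np.median(fit.flat(n)))
                    for n in ("k", "alpha_spring", "alpha_winter", "beta",
                              "sigma2_transect")
                },
                "bayesian_p": _survival_ppc(fit, tables[sp], config.seed,
                                            config.n_ppc),
                "dic": fit.dic(),
            }
            if config.compare_season_dic:
                fit0 = first_visit.fit(tables[sp], config=mcfg, season_effect=False)
                entry["dic_no_season"] = fit0.dic()
                entry["delta_dic_season"] = entry["dic_no_season"] - entry["dic"]
            report["first_visit"][sp] = entry

    series = daily_series_table(events, inspections, sites)
    if config.fit_presence:
        report["daily_presence"] = {}
        for sp in config.species:
            fit = daily_presence.fit(series, species=sp, config=mcfg)
            cross = "cross_absent" if sp == "fox" else "cross_present"
            report["daily_presence"][sp] = {
                "max_rhat": float(fit.rhat.max()),
                "converged": fit.converged,
                "odds_multiplier_other_prev": {
                    "absent": float(np.exp(np.median(fit.flat("cross_absent")))),
                    "present": float(np.exp(np.median(fit.flat("cross_present")))),
                },
                "bayesian_p": _presence_ppc(fit, series, sp, config.seed,
                                            max(config.n_ppc // 5, 50)),
            }

    if config.fit_biomass:
        btable = biomass_table(events, inspections, sites)
        bfit = biomass.fit_biomass(btable)
        report["biomass"] = {
            "theta_dog": bfit.theta_dog,
            "theta_fox": bfit.theta_fox,
            "rho": bfit.rho,
            "r_squared": bfit.r2,
            "sigma2": bfit.sigma2,
        }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def biomass_table(events, inspections, sites) -> pd.DataFrame:
    """Per-inspection modelling table with cumulative feeding minutes."""
    rows = []
    for s in sites:
        insp = sorted(
            (b for b in inspections if b.carcass_id == s.carcass_id),
            key=lambda b: b.date,
        )
        for b in insp:
            day = (b.date - s.deploy_date).days
            cutoff = s.deploy_date + timedelta(days=day + 1)
            dog = sum(
                e.duration / 60.0 for e in events
                if e.carcass_id == s.carcass_id and e.species == "wild_dog"
                and e.behaviour == "feeding"
                and e.start_time.date() < cutoff
            )
            fox = sum(
                e.duration / 60.0 for e in events
                if e.carcass_id == s.carcass_id and e.species == "fox"
                and e.behaviour == "feeding"
                and e.start_time.date() < cutoff
            )
            rows.append(
                {
                    "carcass_id": s.carcass_id,
                    "transect_id": s.transect_id,
                    "season": s.season,
                    "day": day,
                    "biomass": b.mean_biomass,
                    "dog_minutes": dog,
                    "fox_minutes": fox,
                }
            )
    return pd.DataFrame(rows)
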