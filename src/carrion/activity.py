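"""Descriptive layer: carcass-use summaries, 24-h activity clocks, feeding
bout statistics, BCa bootstrap intervals, and interspecific time intervals.

The activity clock follows field convention for crepuscular/nocturnal
carnivores: the 24-h cycle starts and ends at midday, so a night's activity
is not split across two clock faces.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .data import BEHAVIOURS, SPECIES, CarcassSite, VisitEvent


def carcass_use_summary(
    events: list[VisitEvent], sites: list[CarcassSite]
) -> pd.DataFrame:
    """Per-species counts and percentages of carcasses visited and fed at."""
    n_sites = len(sites)
    rows = []
    for sp in SPECIES:
        visited = {e.carcass_id for e in events if e.species == sp}
        fed = {
            e.carcass_id
            for e in events
            if e.species == sp and e.behaviour == "feeding"
        }
        rows.append(
            {
                "species": sp,
                "n_sites": n_sites,
                "visited": len(visited),
                "fed": len(fed),
                "visited_pct": 100.0 * len(visited) / n_sites if n_sites else 0.0,
                "fed_pct": 100.0 * len(fed) / n_sites if n_sites else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ActivityClock:
    """Mean minutes of activity per 24-h clock bin per monitored day."""

    species: str
    behaviour: str | None
    bin_minutes: int
    anchor_hour: int
    bins: np.ndarray  # mean minutes per bin per day

    @property
    def bin_labels(self) -> list[str]:
        out = []
        for i in range(len(self.bins)):
            m = (self.anchor_hour * 60 + i * self.bin_minutes) % 1440
            out.append(f"{m // 60:02d}:{m % 60:02d}")
        return out

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start": self.bin_labels, "mean_minutes": self.bins}
        )


def activity_clock(
    events: list[VisitEvent],
    species: str,
    monitored_days: int,
    behaviour_filter: str | None = None,
    bin_minutes: int = 60,
    anchor_hour: int = 12,
) -> ActivityClock:
    """Apportion event durations pro-rata into 24-h clock bins.

    Bins tile the cycle starting at ``anchor_hour`` (midday by default);
    totals are divided by ``monitored_days`` (carcass-days of monitoring),
    so total minutes are conserved exactly.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    n_bins = 1440 // bin_minutes
    totals = np.zeros(n_bins)
    for e in events:
        if e.species != species:
            continue
        if behaviour_filter is not None and e.behaviour != behaviour_filter:
            continue
        # clock-minute of the event start relative to the anchor
        start_min = (
            e.start_time.hour * 60
            + e.start_time.minute
            + e.start_time.second / 60.0
            - anchor_hour * 60
        ) % 1440
        remaining = e.duration / 60.0
        pos = start_min
        while remaining > 1e-12:
            b = int(pos // bin_minutes) % n_bins
            take = min(remaining, ((pos // bin_minutes + 1) * bin_minutes) - pos)
            totals[b] += take
            remaining -= take
            pos = (pos + take) % 1440
    if monitored_days < 1:
        raise ValueError("monitored_days must be >= 1")
    return ActivityClock(
        species=species,
        behaviour=behaviour_filter,
        bin_minutes=bin_minutes,
        anchor_hour=anchor_hour,
        bins=totals / monitored_days,
    )


def merge_visits(
    events: list[VisitEvent], merge_gap_minutes: float = 5.0
) -> list[list[VisitEvent]]:
    """Group events of one species at one carcass into visits.

    Events separated by less than the merge gap belong to the same visit
    (camera-trigger bursts are not independent visits).
    """
    groups: dict[tuple[str, str], list[VisitEvent]] = {}
    for e in events:
        groups.setdefault((e.carcass_id, e.species), []).append(e)
    visits = []
    for key in sorted(groups):
        evs = sorted(groups[key], key=lambda e: e.start_time)
        cur = [evs[0]]
        for e in evs[1:]:
            gap = (e.start_time - cur[-1].end_time).total_seconds() / 60.0
            if gap < merge_gap_minutes:
                cur.append(e)
            else:
                visits.append(cur)
                cur = [e]
        visits.append(cur)
    return visits


def bout_stats(
    events: list[VisitEvent],
    species: str,
    behaviour: str = "feeding",
    merge_gap_minutes: float = 5.0,
) -> dict:
    """Mean/SD of behaviour bout durations and the share of visits with it.

    A visit is a merged cluster of events (gap < ``merge_gap_minutes``); a
    bout's duration is the visit's total minutes of the behaviour.
    """
    sel = [e for e in events if e.species == species]
    if not sel:
        return {
            "species": species, "behaviour": behaviour, "n_visits": 0,
            "n_bouts": 0, "mean_min": np.nan, "sd_min": np.nan,
            "share_of_visits": np.nan,
        }
    visits = merge_visits(sel, merge_gap_minutes)
    bouts = []
    for v in visits:
        mins = sum(e.duration / 60.0 for e in v if e.behaviour == behaviour)
        if mins > 0:
            bouts.append(mins)
    return {
        "species": species,
        "behaviour": behaviour,
        "n_visits": len(visits),
        "n_bouts": len(bouts),
        "mean_min": float(np.mean(bouts)) if bouts else np.nan,
        "sd_min": float(np.std(bouts, ddof=1)) if len(bouts) > 1 else 0.0 if bouts else np.nan,
        "share_of_visits": len(bouts) / len(visits),
    }


def bca_bootstrap_ci(
    values,
    statistic=np.mean,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Bias-corrected and accelerated bootstrap interval for a statistic.

    Returns (estimate, lo, hi); acceleration is estimated by jackknife.
    Degenerate all-equal inputs give a zero-width interval.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    est = float(statistic(values))
    if np.ptp(values) == 0.0:
        return est, est, est
    res = stats.bootstrap(
        (values,),
        statistic,
        n_resamples=n_boot,
        confidence_level=level,
        method="BCa",
        vectorized=False,
        random_state=np.random.default_rng(seed),
    )
    return est, float(res.confidence_interval.low), float(res.confidence_interval.high)


def total_feeding_time_ci(
    events: list[VisitEvent],
    sites: list[CarcassSite],
    species: str,
    exclude_censored: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Mean total feeding minutes per carcass with a BCa interval.

    Sites with prematurely ended monitoring (stolen cameras) are excluded
    by default, so the per-carcass totals are comparable.
    """
    use = [s for s in sites if not (exclude_censored and s.censored)]
    totals = []
    for s in use:
        mins = sum(
            e.duration / 60.0
            for e in events
            if e.carcass_id == s.carcass_id
            and e.species == species
            and e.behaviour == "feeding"
        )
        totals.append(mins)
    est, lo, hi = bca_bootstrap_ci(np.array(totals), n_boot=n_boot, seed=seed)
    return {"species": species, "n_carcasses": len(use), "mean_min": est,
            "ci_lo": lo, "ci_hi": hi}


def interspecies_intervals(events: list[VisitEvent]) -> pd.DataFrame:
    """Gaps between one species' departure and another's arrival per carcass.

    Consecutive events of different species are paired in time order; a
    non-positive gap means the species overlapped (co-presence).  Sorted by
    gap, smallest first.
    """
    rows = []
    by_carcass: dict[str, list[VisitEvent]] = {}
    for e in events:
        by_carcass.setdefault(e.carcass_id, []).append(e)
    for cid in sorted(by_carcass):
        evs = sorted(by_carcass[cid], key=lambda e: e.start_time)
        for a, b in zip(evs, evs[1:]):
            if a.species == b.species:
                continue
            gap = (b.start_time - a.end_time).total_seconds() / 60.0
            rows.append(
                {
                    "carcass_id": cid,
                    "from_species": a.species,
                    "to_species": b.species,
                    "gap_minutes": gap,
                    "co_presence": gap <= 0.0,
                }
            )
    df = pd.DataFrame(
        rows, columns=["carcass_id", "from_species", "to_species",
                       "gap_minutes", "co_presence"]
    )
    return df.sort_values("gap_minutes", ignore_index=True) if not df.empty else df


def plot_activity_clock(clock: ActivityClock, ax=None):
    """Polar plot of an activity clock (presentation helper, not tested for
    aesthetics)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = len(clock.bins)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ax.bar(theta, clock.bins, width=2 * np.pi / n, align="edge")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    labels = [clock.bin_labels[int(i * n / 8)] for i in range(8)]
    ax.set_xticklabels(labels)
    ax.set_title(f"{clock.species} {clock.behaviour or 'all behaviours'}")
    return ax
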