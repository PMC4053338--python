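"""Domain types, CSV readers/writers and deterministic data preparation.

The observational unit of the study design is a carcass site monitored by
camera traps.  Three tables describe a study:

* ``sites.csv`` — one row per carcass (design metadata),
* ``events.csv`` — one row per carnivore visit (species, time, duration,
  behaviour),
* ``inspections.csv`` — one row per ~14-day biomass inspection with the
  proportion of edible biomass remaining on each carcass half.

All proportions are handled on [0, 1]; percentages belong to the
presentation layer only.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import pandas as pd

SPECIES = ("wild_dog", "fox", "feral_cat")
BEHAVIOURS = ("feeding", "investigating", "scent_marking", "moving_through")
SEASONS = ("winter", "spring")
#: distances (km) from the farm-forest boundary used by the transect design
DESIGN_DISTANCES = (0.05, 1.0, 2.0, 3.0, 4.0)


class ValidationError(ValueError):
    """Raised when a table row or domain value violates an invariant."""


@dataclass(frozen=True)
class CarcassSite:
    """Design metadata for one monitored carcass.

    ``censored`` marks a site whose monitoring ended prematurely (e.g.
    cameras stolen); its series is truncated at ``removal_date``.
    """

    carcass_id: str
    transect_id: int
    distance_to_farm: float
    season: str
    deploy_date: date
    removal_date: date | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(
                f"season {self.season!r} not in {SEASONS} for {self.carcass_id}"
            )
        if self.distance_to_farm < 0:
            raise ValidationError("distance_to_farm must be >= 0")
        if self.removal_date is not None and self.removal_date < self.deploy_date:
            raise ValidationError(
                f"removal_date < deploy_date for {self.carcass_id}"
            )

    @property
    def n_monitored_days(self) -> int | None:
        if self.removal_date is None:
            return None
        return (self.removal_date - self.deploy_date).days + 1


@dataclass(frozen=True)
class VisitEvent:
    """One visit by one species to one carcass."""

    carcass_id: str
    species: str
    start_time: datetime
    duration: float  # seconds
    behaviour: str
    n_individuals: int = 1

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"unknown species {self.species!r}; allowed: {SPECIES}"
            )
        if self.behaviour not in BEHAVIOURS:
            raise ValidationError(
                f"unknown behaviour {self.behaviour!r}; allowed: {BEHAVIOURS}"
            )
        if self.duration < 0:
            raise ValidationError("duration must be >= 0 seconds")
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration)


@dataclass(frozen=True)
class BiomassInspection:
    """Proportion of edible biomass per carcass half at one inspection."""

    carcass_id: str
    date: date
    front_half: float
    rear_half: float

    def __post_init__(self) -> None:
        for name in ("front_half", "rear_half"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")

    @property
    def mean_biomass(self) -> float:
        return mean_halves(self.front_half, self.rear_half)


@dataclass(frozen=True)
class DailyRecord:
    """One monitored day at one carcass: presence flags + interpolated biomass."""

    carcass_id: str
    day_index: int
    dog_present: int
    fox_present: int
    biomass: float


# ---------------------------------------------------------------------------
# CSV IO


def _read_table(path, row_parser, table_name):
    df = pd.read_csv(path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(row_parser(row))
        except (ValidationError, ValueError, KeyError) as exc:
            raise ValidationError(f"{table_name} row {i}: {exc}") from exc
    return out


def read_events(path) -> list[VisitEvent]:
    """Read ``events.csv`` (ISO-8601 start times, durations in seconds)."""

    def parse(row):
        return VisitEvent(
            carcass_id=str(row.carcass_id),
            species=str(row.species),
            start_time=datetime.fromisoformat(str(row.start_time)),
            duration=float(row.duration),
            behaviour=str(row.behaviour),
            n_individuals=int(getattr(row, "n_individuals", 1)),
        )

    return _read_table(path, parse, "events")


def write_events(events: list[VisitEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "carcass_id": e.carcass_id,
                "species": e.species,
                "start_time": e.start_time.isoformat(),
                "duration": e.duration,
                "behaviour": e.behaviour,
                "n_individuals": e.n_individuals,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def read_sites(path) -> list[CarcassSite]:
    def parse(row):
        removal = getattr(row, "removal_date", "")
        removal_date = (
            None if pd.isna(removal) or removal == "" else date.fromisoformat(str(removal))
        )
        return CarcassSite(
            carcass_id=str(row.carcass_id),
            transect_id=int(row.transect_id),
            distance_to_farm=float(row.distance_to_farm),
            season=str(row.season),
            deploy_date=date.fromisoformat(str(row.deploy_date)),
            removal_date=removal_date,
            censored=bool(getattr(row, "censored", False)),
        )

    return _read_table(path, parse, "sites")


def write_sites(sites: list[CarcassSite], path) -> None:
    pd.DataFrame(
        [
            {
                "carcass_id": s.carcass_id,
                "transect_id": s.transect_id,
                "distance_to_farm": s.distance_to_farm,
                "season": s.season,
                "deploy_date": s.deploy_date.isoformat(),
                "removal_date": "" if s.removal_date is None else s.removal_date.isoformat(),
                "censored": s.censored,
            }
            for s in sites
        ]
    ).to_csv(path, index=False)


def read_inspections(path) -> list[BiomassInspection]:
    def parse(row):
        return BiomassInspection(
            carcass_id=str(row.carcass_id),
            date=date.fromisoformat(str(row.date)),
            front_half=float(row.front_half),
            rear_half=float(row.rear_half),
        )

    return _read_table(path, parse, "inspections")


def write_inspections(inspections: list[BiomassInspection], path) -> None:
    pd.DataFrame(
        [
            {
                "carcass_id": b.carcass_id,
                "date": b.date.isoformat(),
                "front_half": b.front_half,
                "rear_half": b.rear_half,
            }
            for b in inspections
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Deterministic preparation rules


def mean_halves(front: float, rear: float) -> float:
    """Mean proportion of edible biomass over the two carcass halves."""
    for name, v in (("front", front), ("rear", rear)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} half proportion {v} outside [0, 1]")
    return 0.5 * (front + rear)


def interpolate_daily_biomass(
    inspections: list[BiomassInspection], day: date
) -> float:
    """Linearly interpolate half-averaged biomass at ``day``.

    Biomass is assumed to decline linearly between the ~14-day inspections;
    no extrapolation outside the inspected window.
    """
    if not inspections:
        raise ValidationError("no inspections supplied")
    insp = sorted(inspections, key=lambda b: b.date)
    if day < insp[0].date or day > insp[-1].date:
        raise ValidationError(
            f"day {day} outside inspected window [{insp[0].date}, {insp[-1].date}]"
        )
    for lo, hi in zip(insp, insp[1:]):
        if lo.date <= day <= hi.date:
            if lo.date == hi.date:
                return lo.mean_biomass
            frac = (day - lo.date).days / (hi.date - lo.date).days
            return lo.mean_biomass + frac * (hi.mean_biomass - lo.mean_biomass)
    # day equals the single inspection date
    return insp[0].mean_biomass


def build_daily_series(
    events: list[VisitEvent],
    inspections: list[BiomassInspection],
    site: CarcassSite,
    boundary_hour: int = 0,
) -> list[DailyRecord]:
    """One record per monitored 24-h period with presence flags and biomass.

    A day ``k`` covers ``[deploy + k days + boundary_hour, +24 h)``; the
    default ``boundary_hour=0`` is the calendar-day convention.  A presence
    flag is set on every day the event interval intersects.
    """
    if site.removal_date is None:
        raise ValidationError(f"site {site.carcass_id} has no removal_date")
    n_days = site.n_monitored_days
    start0 = datetime.combine(site.deploy_date, datetime.min.time()) + timedelta(
        hours=boundary_hour
    )
    window_end = start0 + timedelta(days=n_days)

    dog = [0] * n_days
    fox = [0] * n_days
    for e in events:
        if e.carcass_id != site.carcass_id:
            continue
        if e.start_time < start0 or e.start_time >= window_end:
            raise ValidationError(
                f"event at {e.start_time} outside monitored window of "
                f"{site.carcass_id} [{start0}, {window_end})"
            )
        k0 = (e.start_time - start0) // timedelta(days=1)
        # an event intersects every day from its start day to its end day
        end = min(e.end_time, window_end - timedelta(microseconds=1))
        k1 = (end - start0) // timedelta(days=1)
        for k in range(int(k0), int(k1) + 1):
            if e.species == "wild_dog":
                dog[k] = 1
            elif e.species == "fox":
                fox[k] = 1

    out = []
    for k in range(n_days):
        day = site.deploy_date + timedelta(days=k)
        bio = interpolate_daily_biomass(inspections, day)
        out.append(
            DailyRecord(
                carcass_id=site.carcass_id,
                day_index=k,
                dog_present=dog[k],
                fox_present=fox[k],
                biomass=bio,
            )
        )
    return out


def daily_series_frame(
    records: list[DailyRecord], site: CarcassSite | None = None
) -> pd.DataFrame:
    """Tidy frame of daily records, optionally annotated with site covariates."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if site is not None and not df.empty:
        df["transect_id"] = site.transect_id
        df["season"] = site.season
        df["distance_to_farm"] = site.distance_to_farm
    return df
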