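"""Read occurrence CSVs, filter records, convert to binned solar hours, assign seasons.

The ingest stage turns raw research-grade occurrence exports (one row per
time-stamped, georeferenced species observation) into `SolarObservation`
rows on a common solar-time axis. Solar time places the sun's zenith at
12:00 regardless of longitude or time zone, which is what makes hourly
activity comparable across a continent.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from ._sun import equation_of_time_min, fractional_year

SEASONS = ("winter", "spring", "summer", "fall")

#: Rough conterminous-USA bounding polygon (lon, lat); region is config, not
#: hard-coded geography — pass any polygon to FilterConfig to override.
CONUS_BBOX = ((-124.8, 24.4), (-66.9, 24.4), (-66.9, 49.4), (-124.8, 49.4))

DEFAULT_COLUMNS = {
    "record_id": "id",
    "species": "species",
    "timestamp": "eventDateTime",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "life_stage": "lifeStage",
    "project": "project",
}


@dataclasses.dataclass(frozen=True)
class ObservationRecord:
    record_id: str
    species: str
    timestamp: dt.datetime  # timezone-aware
    latitude: float
    longitude: float
    life_stage: str | None = None
    project: str | None = None


@dataclasses.dataclass(frozen=True)
class SolarObservation:
    record_id: str
    species: str
    solar_hour_raw: float
    solar_hour: int
    date: dt.date
    season: str
    season_year: int
    latitude: float
    longitude: float


@dataclasses.dataclass
class FilterReport:
    """Per-rule removal tallies; removed + retained always equals input size."""

    n_input: int = 0
    no_timestamp: int = 0
    outside_region: int = 0
    year_cutoff: int = 0
    life_stage: int = 0
    species_excluded: int = 0
    project_excluded: int = 0
    outside_hour_window: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return (
            self.no_timestamp
            + self.outside_region
            + self.year_cutoff
            + self.life_stage
            + self.species_excluded
            + self.project_excluded
            + self.outside_hour_window
        )

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class FilterConfig:
    """Record filters mirroring a typical citizen-science cleaning pipeline.

    ``min_year`` is the first retained year ("after 2015" read literally as
    year >= 2016). Life stages in ``excluded_life_stages`` are dropped;
    missing or unknown stages are kept.
    """

    region: Sequence[tuple[float, float]] = CONUS_BBOX
    min_year: int = 2016
    excluded_life_stages: frozenset[str] = frozenset({"larva", "pupa", "egg"})
    excluded_species: tuple[str, ...] = ("Danaus plexippus",)
    excluded_projects: tuple[str, ...] = ("Caterpillars of Eastern North America",)
    hour_window: tuple[int, int] = (8, 20)
    columns: dict[str, str] = dataclasses.field(default_factory=lambda: dict(DEFAULT_COLUMNS))


def solar_hour(timestamp: dt.datetime, longitude: float) -> float:
    """Apparent solar hour of day in [0, 24) at the given longitude.

    Mean solar time (UTC hour + longitude/15) plus the equation-of-time
    correction. The correction is evaluated at the UTC instant, so the
    difference between two longitudes at the same instant is exactly
    (L2 - L1)/15 hours.
    """
    if timestamp.tzinfo is None:
        raise ValueError("timestamp has no UTC offset; cannot compute solar time")
    utc = timestamp.astimezone(dt.timezone.utc)
    hour_utc = utc.hour + utc.minute / 60.0 + utc.second / 3600.0 + utc.microsecond / 3.6e9
    eot = equation_of_time_min(fractional_year(utc.replace(tzinfo=None)))
    return (hour_utc + longitude / 15.0 + eot / 60.0) % 24.0


def bin_and_window(
    solar_hour_raw: float, window: tuple[int, int] = (8, 20)
) -> int | None:
    """Nearest-integer solar hour, or None when the binned hour leaves the window.

    Ties (x.5) round up; the window is applied after binning, so e.g. 20.4
    bins to 20 and is retained while 7.49 bins to 7 and is discarded.
    """
    binned = math.floor(solar_hour_raw + 0.5)
    lo, hi = window
    if binned < lo or binned > hi:
        return None
    return binned


def season_center(season: str, season_year: int) -> dt.date:
    """Center date of a 91-day season; winter is centered on Dec 21."""
    k = SEASONS.index(season)
    if k == 0:
        return dt.date(season_year, 12, 21)
    return dt.date(season_year - 1, 12, 21) + dt.timedelta(days=91 * k)


def assign_season(date: dt.date) -> tuple[str, int]:
    """Map a date to its 91-day season and that season's year.

    Seasons are consecutive 91-day windows whose centers sit 91 days apart
    starting from the Dec 21 winter center; the day(s) a calendar year has
    beyond 4x91 go to the season with the nearest center. season_year is
    the calendar year containing the season's center date, so a January
    date belongs to the previous year's winter.
    """
    best: tuple[int, dt.date, str, int] | None = None
    for year in (date.year - 1, date.year, date.year + 1):
        for season in SEASONS:
            center = season_center(season, year)
            gap = abs((date - center).days)
            if best is None or (gap, center) < (best[0], best[1]):
                best = (gap, center, season, year)
    assert best is not None
    return best[2], best[3]


def parse_timestamp(value: object) -> dt.datetime | None:
    """ISO-8601 date-time with UTC offset, or None when unusable."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        ts = dt.datetime.fromisoformat(text)
    except ValueError:
        return None
    if ts.tzinfo is None:
        return None
    return ts


def read_and_filter(
    path: str, config: FilterConfig | None = None
) -> tuple[list[ObservationRecord], FilterReport]:
    """Read an occurrence CSV and apply the record filters in fixed order.

    Rules are applied in the order: missing/unparseable timestamp, outside
    region (malformed coordinates count here), year before cutoff, excluded
    life stage, excluded species, excluded project. The first matching rule
    claims the record, so the report's tallies sum to the input size.
    """
    config = config or FilterConfig()
    frame = pd.read_csv(path, dtype=str)
    cols = config.columns
    for role in ("species", "timestamp", "latitude", "longitude"):
        if cols[role] not in frame.columns:
            raise ValueError(f"occurrence CSV lacks required column {cols[role]!r}")

    region = prep(Polygon(config.region))
    excluded_species = set(config.excluded_species)
    excluded_projects = set(config.excluded_projects)
    report = FilterReport(n_input=len(frame))
    records: list[ObservationRecord] = []

    for i, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        ts = parse_timestamp(row_d.get(cols["timestamp"]))
        if ts is None:
            report.no_timestamp += 1
            continue
        try:
            lat = float(row_d[cols["latitude"]])
            lon = float(row_d[cols["longitude"]])
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError
        except (TypeError, ValueError):
            report.outside_region += 1
            continue
        if not region.contains(Point(lon, lat)):
            report.outside_region += 1
            continue
        if ts.year < config.min_year:
            report.year_cutoff += 1
            continue
        stage = _clean_str(row_d.get(cols["life_stage"]))
        if stage is not None and stage.lower() in config.excluded_life_stages:
            report.life_stage += 1
            continue
        species = _clean_str(row_d.get(cols["species"])) or ""
        if species in excluded_species:
            report.species_excluded += 1
            continue
        project = _clean_str(row_d.get(cols["project"]))
        if project in excluded_projects:
            report.project_excluded += 1
            continue
        record_id = _clean_str(row_d.get(cols["record_id"])) or str(i)
        records.append(
            ObservationRecord(record_id, species, ts, lat, lon, stage, project)
        )
        report.retained += 1
    return records, report


def _clean_str(value: object) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def to_solar(
    records: Iterable[ObservationRecord],
    report: FilterReport | None = None,
    window: tuple[int, int] = (8, 20),
) -> list[SolarObservation]:
    """Convert retained records to binned solar observations.

    Records whose binned solar hour falls outside the window are dropped;
    when a report is supplied its window tally (and retained count) are
    updated so the filter accounting stays exact.
    """
    out: list[SolarObservation] = []
    for rec in records:
        raw = solar_hour(rec.timestamp, rec.longitude)
        binned = bin_and_window(raw, window)
        if binned is None:
            if report is not None:
                report.outside_hour_window += 1
                report.retained -= 1
            continue
        local_date = rec.timestamp.date()
        season, season_year = assign_season(local_date)
        out.append(
            SolarObservation(
                record_id=rec.record_id,
                species=rec.species,
                solar_hour_raw=raw,
                solar_hour=binned,
                date=local_date,
                season=season,
                season_year=season_year,
                latitude=rec.latitude,
                longitude=rec.longitude,
            )
        )
    return out


def solar_frame(observations: Iterable[SolarObservation]) -> pd.DataFrame:
    """Tabular view of solar observations for downstream grouping."""
    return pd.DataFrame([dataclasses.asdict(o) for o in observations])
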