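"""Climate, daylength and trait covariates for each SSCY, plus z-scaling.

Each SSCY row gets: the cell's mean (or max) monthly temperature over the
season's three months in that year, the daylength at the cell center on the
season's center date, the species' wingspan, and the observation count.
Non-categorical predictors are z-scaled so effect sizes are comparable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._sun import solar_declination_rad
from .activity import ActivityMetrics
from .grid import Grid
from .ingest import SEASONS, assign_season, season_center

__all__ = [
    "day_length",
    "season_center",
    "season_months",
    "seasonal_mean_temperature",
    "build_model_frame",
    "ScalingInfo",
]

PREDICTORS = ("temp_c", "daylength_h", "wingspan", "n_obs")
RESPONSES = ("onset", "median", "offset", "duration")


def day_length(latitude: float, date: dt.date, sun_altitude: float = -0.833) -> float:
    """Hours between sunrise and sunset via the sunrise equation.

    ``sun_altitude`` is the sun elevation defining rise/set; the default
    -0.833 deg mimics refraction-aware calculators (set it to 0 for the
    geometric horizon). The hour-angle cosine is clamped, so polar day
    returns 24 h and polar night 0 h.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    phi = math.radians(latitude)
    delta = solar_declination_rad(date)
    alt = math.radians(sun_altitude)
    cos_h = (math.sin(alt) - math.sin(phi) * math.sin(delta)) / (
        math.cos(phi) * math.cos(delta)
    )
    cos_h = min(1.0, max(-1.0, cos_h))
    return 2.0 * math.degrees(math.acos(cos_h)) / 15.0


def season_months(season: str, season_year: int) -> list[tuple[int, int]]:
    """The three (year, month) pairs whose mid-dates fall inside a season.

    Winter spans two calendar years (Nov-Jan under the default season
    windows); membership is decided by assigning each month's 15th to a
    season, which resolves the cross-year span without special cases.
    """
    center = season_center(season, season_year)
    months = []
    probe = dt.date(center.year, center.month, 15)
    for offset in range(-3, 4):
        m = probe.month - 1 + offset
        y = probe.year + m // 12
        m = m % 12 + 1
        if assign_season(dt.date(y, m, 15)) == (season, season_year):
            months.append((y, m))
    if len(months) != 3:  # pragma: no cover - guards the window arithmetic
        raise RuntimeError(f"expected 3 months for {season} {season_year}, got {months}")
    return months


def seasonal_mean_temperature(
    temps: pd.DataFrame,
    cell_id: tuple[int, int],
    season: str,
    season_year: int,
    grid: Grid | None = None,
    statistic: str = "mean",
) -> float:
    """Cell temperature over a season's three months; NaN when no data.

    ``temps`` is a monthly table with columns (cell_row, cell_col, year,
    month, value_c) or (lat, lon, year, month, value_c); with the latter a
    grid must be supplied to map pixels to cells. ``statistic`` aggregates
    the three monthly values per pixel: 'mean' or 'max' (monthly products
    often ship maximum temperature; which one to use is a modelling choice,
    so both are supported).
    """
    if statistic not in ("mean", "max"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if {"cell_row", "cell_col"}.issubset(temps.columns):
        sub = temps[(temps.cell_row == cell_id[0]) & (temps.cell_col == cell_id[1])]
        pixel_cols = ["cell_row", "cell_col"]
    elif {"lat", "lon"}.issubset(temps.columns):
        if grid is None:
            raise ValueError("lat/lon temperature table requires a grid")
        from .grid import assign_cell

        cells = [
            assign_cell(la, lo, grid) for la, lo in zip(temps["lat"], temps["lon"])
        ]
        sub = temps[[c == cell_id for c in cells]]
        pixel_cols = ["lat", "lon"]
    else:
        raise ValueError("temperature table needs cell_row/cell_col or lat/lon columns")

    months = season_months(season, season_year)
    parts = []
    for y, m in months:
        parts.append(sub[(sub.year == y) & (sub.month == m)])
    sub = pd.concat(parts) if parts else sub.iloc[:0]
    if sub.empty:
        return float("nan")
    per_pixel = sub.groupby(pixel_cols)["value_c"].agg(statistic)
    return float(per_pixel.mean())


@dataclasses.dataclass(frozen=True)
class ScalingInfo:
    """Means and SDs used for z-scaling, kept for back-transformation."""

    means: dict[str, float]
    sds: dict[str, float]

    def unscale(self, column: str, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) * self.sds[column] + self.means[column]


def attach_covariates(
    metrics: Sequence[ActivityMetrics],
    temps: pd.DataFrame,
    traits: Mapping[str, float],
    grid: Grid | None = None,
    sun_altitude: float = -0.833,
    temp_statistic: str = "mean",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join temperature, daylength and wingspan onto an SSCY metrics table.

    Returns the joined frame plus drop counters (missing temperature,
    missing wingspan). Daylength uses the cell center and the season center
    date, so it varies by cell and season but not by year.
    """
    if grid is None and not {"cell_row", "cell_col"}.issubset(temps.columns):
        raise ValueError("need a grid when temperatures are not per-cell")
    rows = []
    dropped = {"missing_temperature": 0, "missing_wingspan": 0}
    daylength_cache: dict[tuple[tuple[int, int], str], float] = {}
    for m in metrics:
        if m.species not in traits:
            dropped["missing_wingspan"] += 1
            continue
        t = seasonal_mean_temperature(
            temps, m.cell_id, m.season, m.year, grid, temp_statistic
        )
        if math.isnan(t):
            dropped["missing_temperature"] += 1
            continue
        dl_key = (m.cell_id, m.season)
        if dl_key not in daylength_cache:
            if grid is not None:
                lat, _ = grid.cell_center_lonlat(m.cell_id)
            else:
                raise ValueError("grid required to locate cell centers for daylength")
            daylength_cache[dl_key] = day_length(
                lat, season_center(m.season, m.year), sun_altitude
            )
        rows.append(
            {
                "species": m.species,
                "season": m.season,
                "cell_row": m.cell_id[0],
                "cell_col": m.cell_id[1],
                "year": m.year,
                "onset": m.onset,
                "median": m.median,
                "offset": m.offset,
                "duration": m.duration,
                "temp_c": t,
                "daylength_h": daylength_cache[dl_key],
                "wingspan": float(traits[m.species]),
                "n_obs": m.n,
            }
        )
    return pd.DataFrame(rows), dropped


def build_model_frame(
    frame: pd.DataFrame,
    scale: bool = True,
    predictors: Sequence[str] = PREDICTORS,
) -> tuple[pd.DataFrame, ScalingInfo | None]:
    """Z-scale the non-categorical predictors of an assembled covariate frame.

    Scaled columns are added as ``<name>_z``; the returned ScalingInfo
    holds the means/SDs for exact back-transformation.
    """
    out = frame.copy()
    if not scale:
        return out, None
    means, sds = {}, {}
    for col in predictors:
        x = out[col].to_numpy(dtype=float)
        mu = float(x.mean())
        sd = float(x.std(ddof=0))
        if sd == 0:
            raise ValueError(f"predictor {col!r} is constant; cannot z-scale")
        means[col], sds[col] = mu, sd
        out[col + "_z"] = (x - mu) / sd
    return out, ScalingInfo(means, sds)


def load_traits(path: str) -> dict[str, float]:
    """Species -> wingspan (mm) from a trait CSV; duplicate species are an error."""
    table = pd.read_csv(path)
    if table["species"].duplicated().any():
        dupes = table.loc[table["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate trait rows for species: {dupes}")
    return dict(zip(table["species"], table["wingspan_mm"].astype(float)))
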