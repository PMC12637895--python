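"""Equal-area gridding of occurrence records and SSCY sample assembly.

An SSCY (species x season x cell x year) group is the unit at which diel
activity metrics are estimated. Cells come from an Albers equal-area conic
projection on the authalic sphere — equal-area by construction, with the
usual conterminous-USA standard parallels as defaults — laid out as a
regular grid of square cells in projected coordinates.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import SolarObservation

#: Authalic Earth radius in meters (sphere of equal surface area).
EARTH_RADIUS_M = 6_371_007.2


@dataclasses.dataclass(frozen=True)
class AlbersProjection:
    """Spherical Albers equal-area conic (Snyder 1987, eq. 14-1..14-7)."""

    lat_origin: float = 23.0
    lon_origin: float = -96.0
    std_parallel_1: float = 29.5
    std_parallel_2: float = 45.5
    radius: float = EARTH_RADIUS_M

    def _constants(self) -> tuple[float, float, float]:
        p1 = math.radians(self.std_parallel_1)
        p2 = math.radians(self.std_parallel_2)
        n = (math.sin(p1) + math.sin(p2)) / 2.0
        c = math.cos(p1) ** 2 + 2.0 * n * math.sin(p1)
        rho0 = self.radius * math.sqrt(c - 2.0 * n * math.sin(math.radians(self.lat_origin))) / n
        return n, c, rho0

    def forward(self, latitude, longitude):
        """(lat, lon) degrees -> projected (x, y) meters; accepts arrays."""
        n, c, rho0 = self._constants()
        lat = np.radians(np.asarray(latitude, dtype=float))
        lon = np.radians(np.asarray(longitude, dtype=float))
        lon0 = math.radians(self.lon_origin)
        rho = self.radius * np.sqrt(c - 2.0 * n * np.sin(lat)) / n
        theta = n * (lon - lon0)
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Projected (x, y) meters -> (lat, lon) degrees; accepts arrays."""
        n, c, rho0 = self._constants()
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        lat = np.arcsin((c - (rho * n / self.radius) ** 2) / (2.0 * n))
        lon = math.radians(self.lon_origin) + theta / n
        return np.degrees(lat), np.degrees(lon)


@dataclasses.dataclass(frozen=True)
class Grid:
    """Regular square grid in projected space with half-open cells.

    Cell (row, col) covers [origin_x + col*s, origin_x + (col+1)*s) by
    [origin_y + row*s, origin_y + (row+1)*s), so edge points belong to the
    higher-index cell and assignment is deterministic.
    """

    projection: AlbersProjection
    cell_size_m: float
    origin_x: float
    origin_y: float
    n_cols: int
    n_rows: int

    def cell_center_lonlat(self, cell_id: tuple[int, int]) -> tuple[float, float]:
        row, col = cell_id
        x = self.origin_x + (col + 0.5) * self.cell_size_m
        y = self.origin_y + (row + 0.5) * self.cell_size_m
        lat, lon = self.projection.inverse(x, y)
        return float(lat), float(lon)


@dataclasses.dataclass(frozen=True)
class SSCYSample:
    """Binned solar hours of one species x season x cell x year group."""

    species: str
    season: str
    cell_id: tuple[int, int]
    year: int
    hours: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.hours)

    @property
    def key(self) -> tuple[str, str, tuple[int, int], int]:
        return (self.species, self.season, self.cell_id, self.year)


def build_grid(
    region_extent: tuple[float, float, float, float],
    cell_km: float = 250.0,
    projection: AlbersProjection | None = None,
) -> Grid:
    """Grid covering a projected extent (xmin, ymin, xmax, ymax) in meters."""
    if cell_km <= 0:
        raise ValueError("cell size must be positive")
    xmin, ymin, xmax, ymax = region_extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("region extent is empty")
    size = cell_km * 1000.0
    return Grid(
        projection=projection or AlbersProjection(),
        cell_size_m=size,
        origin_x=xmin,
        origin_y=ymin,
        n_cols=math.ceil((xmax - xmin) / size),
        n_rows=math.ceil((ymax - ymin) / size),
    )


def grid_for_lonlat_bounds(
    lon_min: float, lat_min: float, lon_max: float, lat_max: float, cell_km: float = 250.0
) -> Grid:
    """Convenience: grid whose extent covers a geographic bounding box."""
    proj = AlbersProjection()
    lons = np.linspace(lon_min, lon_max, 25)
    lats = np.linspace(lat_min, lat_max, 25)
    gx, gy = np.meshgrid(lons, lats)
    x, y = proj.forward(gy, gx)
    return build_grid((x.min(), y.min(), x.max(), y.max()), cell_km, proj)


def assign_cell(
    latitude: float, longitude: float, grid: Grid
) -> tuple[int, int] | None:
    """Cell id of a point, or None when it falls outside the grid extent."""
    x, y = grid.projection.forward(latitude, longitude)
    col = math.floor((float(x) - grid.origin_x) / grid.cell_size_m)
    row = math.floor((float(y) - grid.origin_y) / grid.cell_size_m)
    if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
        return (row, col)
    return None


def assemble_sscy(
    observations: Iterable[tuple[SolarObservation, tuple[int, int]]],
    min_n: int = 30,
    min_n_level: str = "sscy",
) -> tuple[list[SSCYSample], int]:
    """Group cell-assigned observations into SSCY samples under the min-n rule.

    ``min_n_level`` selects where the threshold applies: per SSCY group
    (default) or per season-cell pooled over species and years. Returns the
    retained samples and the number of observations in dropped groups.
    """
    if min_n_level not in ("sscy", "season_cell"):
        raise ValueError(f"unknown min_n_level {min_n_level!r}")
    groups: dict[tuple, list[int]] = defaultdict(list)
    season_cell_totals: dict[tuple, int] = defaultdict(int)
    for obs, cell in observations:
        key = (obs.species, obs.season, cell, obs.season_year)
        groups[key].append(obs.solar_hour)
        season_cell_totals[(obs.season, cell)] += 1

    samples: list[SSCYSample] = []
    n_dropped = 0
    for key in sorted(groups):
        hours = groups[key]
        if min_n_level == "sscy":
            keep = len(hours) >= min_n
        else:
            keep = season_cell_totals[(key[1], key[2])] >= min_n
        if keep:
            samples.append(SSCYSample(key[0], key[1], key[2], key[3], tuple(hours)))
        else:
            n_dropped += len(hours)
    return samples, n_dropped


def sscy_frame(samples: Sequence[SSCYSample]) -> pd.DataFrame:
    """SSCY table with hours serialized as a '|'-delimited list."""
    return pd.DataFrame(
        {
            "species": [s.species for s in samples],
            "season": [s.season for s in samples],
            "cell_row": [s.cell_id[0] for s in samples],
            "cell_col": [s.cell_id[1] for s in samples],
            "year": [s.year for s in samples],
            "n": [s.n for s in samples],
            "hours": ["|".join(map(str, s.hours)) for s in samples],
        }
    )
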