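"""Low-level solar geometry: fractional year, equation of time, declination.

Uses the Spencer (1971) Fourier series, accurate to about a minute for
the equation of time and 0.01 rad for declination — more than enough for
hour-binned activity data and cell-level daylength.
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = ["fractional_year", "equation_of_time_min", "declination_rad", "solar_declination_rad"]


def fractional_year(when: dt.datetime | dt.date) -> float:
    """Fractional year gamma in radians for the Spencer series.

    For datetimes, the time of day contributes; naive datetimes are taken
    as already being in UTC.
    """
    if isinstance(when, dt.datetime):
        doy = when.timetuple().tm_yday
        hour = when.hour + when.minute / 60.0 + when.second / 3600.0
    else:
        doy = when.timetuple().tm_yday
        hour = 12.0
    days_in_year = 366.0 if _is_leap(when.year) else 365.0
    return 2.0 * math.pi / days_in_year * (doy - 1 + (hour - 12.0) / 24.0)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def equation_of_time_min(gamma: float) -> float:
    """Apparent minus mean solar time, in minutes."""
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )


def declination_rad(gamma: float) -> float:
    """Solar declination in radians (Spencer series, ~0.5 deg accuracy)."""
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )


def solar_declination_rad(date: dt.date) -> float:
    """Solar declination via the Astronomical Almanac low-precision solar
    position (~0.01 deg), evaluated at 12:00 UT.

    The Spencer series is fine for the equation of time at hour-binning
    resolution, but its declination error near the equinoxes moves
    high-latitude daylength by ~0.1 h, so daylength uses this instead.
    """
    n = date.toordinal() + 1721424.5 + 0.5 - 2451545.0
    L = math.radians((280.460 + 0.9856474 * n) % 360.0)
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = L + math.radians(1.915) * math.sin(g) + math.radians(0.020) * math.sin(2 * g)
    eps = math.radians(23.439 - 0.0000004 * n)
    return math.asin(math.sin(eps) * math.sin(lam))
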