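"""Independent oracles used by the tests.

These deliberately use different algorithms from the package: the solar
oracle follows the NOAA spreadsheet (Meeus-based) formulas rather than the
Spencer series, and the quantile oracle is a literal cumulative-weight
scan over merged tie groups.
"""

from __future__ import annotations

import datetime as dt
import math


def _julian_day(date: dt.date, hour_utc: float) -> float:
    return date.toordinal() + 1721424.5 + hour_utc / 24.0


def noaa_solar(date: dt.date, latitude: float, hour_utc: float = 12.0) -> dict:
    """NOAA solar-calculator quantities: declination (deg), equation of time
    (minutes) and daylength (hours, zenith 90.833 deg)."""
    jc = (_julian_day(date, hour_utc) - 2451545.0) / 36525.0
    gmls = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eoc = (
        math.sin(math.radians(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gmas)) * 0.000289
    )
    stl = gmls + eoc
    sal = stl - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    moe = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    oc = moe + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.degrees(math.asin(math.sin(math.radians(oc)) * math.sin(math.radians(sal))))
    vary = math.tan(math.radians(oc / 2.0)) ** 2
    eqtime = 4.0 * math.degrees(
        vary * math.sin(2.0 * math.radians(gmls))
        - 2.0 * eeo * math.sin(math.radians(gmas))
        + 4.0 * eeo * vary * math.sin(math.radians(gmas)) * math.cos(2.0 * math.radians(gmls))
        - 0.5 * vary * vary * math.sin(4.0 * math.radians(gmls))
        - 1.25 * eeo * eeo * math.sin(2.0 * math.radians(gmas))
    )
    cos_ha = (
        math.cos(math.radians(90.833)) / (math.cos(math.radians(latitude)) * math.cos(math.radians(decl)))
        - math.tan(math.radians(latitude)) * math.tan(math.radians(decl))
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha = math.degrees(math.acos(cos_ha))
    return {"declination": decl, "eqtime_min": eqtime, "daylength_h": 8.0 * ha / 60.0}


def brute_force_weighted_quantile(values, weights, q) -> float:
    """Left-continuous weighted inverse CDF by explicit scan over merged ties."""
    total = sum(weights)
    merged: dict[float, float] = {}
    for v, w in zip(values, weights):
        merged[v] = merged.get(v, 0.0) + w / total
    cum = 0.0
    for v in sorted(merged):
        cum += merged[v]
        if cum >= q - 1e-12:
            return v
    return max(values)
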