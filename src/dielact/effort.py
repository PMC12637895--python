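"""Observer-effort surfaces: hourly all-taxon counts smoothed per season-cell.

Citizen-science observation counts confound true animal activity with when
people happen to be out recording. The effort model treats the number of
observations of *all* species in a season-cell-hour as a proxy for observer
effort, smooths it over the hour axis with a penalized Poisson spline (a
GAM), and floors the prediction so inverse-effort weights stay finite.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .grid import SSCYSample
from .ingest import SolarObservation

HOURS = tuple(range(8, 21))


@dataclasses.dataclass(frozen=True)
class EffortCounts:
    season: str
    cell_id: tuple[int, int]
    counts: tuple[int, ...]  # one entry per hour 8..20

    def __post_init__(self):
        if len(self.counts) != len(HOURS):
            raise ValueError("expected one count per hour 8..20")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclasses.dataclass(frozen=True)
class EffortSurface:
    season: str
    cell_id: tuple[int, int]
    effort: tuple[float, ...]  # predicted effort per hour 8..20, >= floor
    basis_df: int
    penalized: bool
    floor_eps: float
    degenerate: bool = False  # all-zero counts fell back to a flat floor

    def at_hour(self, hour: int) -> float:
        return self.effort[HOURS.index(hour)]


def tabulate_effort(
    observations: Iterable[tuple[SolarObservation, tuple[int, int] | None]],
) -> list[EffortCounts]:
    """Exact per-hour observation counts for every season-cell present.

    Input pairs each observation with its grid cell; observations outside
    the grid (cell None) are ignored. Counts include every species — the
    effort proxy is deliberately taxon-blind.
    """
    table: dict[tuple[str, tuple[int, int]], np.ndarray] = defaultdict(
        lambda: np.zeros(len(HOURS), dtype=int)
    )
    for obs, cell in observations:
        if cell is None:
            continue
        table[(obs.season, cell)][obs.solar_hour - HOURS[0]] += 1
    return [
        EffortCounts(season, cell, tuple(int(c) for c in counts))
        for (season, cell), counts in sorted(table.items())
    ]


def fit_effort_curve(
    counts: EffortCounts,
    basis_df: int = 5,
    floor_eps: float = 0.5,
    penalized: bool = True,
) -> EffortSurface:
    """Smooth hourly counts into a strictly positive predicted effort curve.

    A Poisson (log-link) spline regression of count on hour, evaluated at
    hours 8..20. With ``penalized`` the smoothing amount is chosen by the
    GAM's penalized-likelihood criterion; otherwise a fixed-df unpenalized
    spline is used (with ``basis_df`` equal to the number of hours this is
    the saturated model and reproduces positive counts exactly). All-zero
    counts yield a flat surface at the floor, flagged as degenerate.
    """
    y = np.asarray(counts.counts, dtype=float)
    if y.sum() == 0:
        warnings.warn(
            f"all-zero effort counts for season={counts.season} cell={counts.cell_id};"
            " using flat floor surface"
        )
        return EffortSurface(
            counts.season, counts.cell_id, (floor_eps,) * len(HOURS),
            basis_df, penalized, floor_eps, degenerate=True,
        )
    pred = _fit_poisson_smooth(y, basis_df, penalized)
    pred = np.maximum(pred, floor_eps)
    return EffortSurface(
        counts.season, counts.cell_id, tuple(float(p) for p in pred),
        basis_df, penalized, floor_eps,
    )


def _fit_poisson_smooth(y: np.ndarray, basis_df: int, penalized: bool) -> np.ndarray:
    hours = np.asarray(HOURS, dtype=float)
    x = hours[:, None]
    if basis_df >= len(HOURS):
        # saturated: one indicator per hour, fitted values = observed counts
        X = np.eye(len(HOURS))
        model = sm.GLM(y, X, family=sm.families.Poisson())
        return np.asarray(model.fit(tol=1e-12, maxiter=200).fittedvalues)
    try:
        basis = BSplines(x, df=[basis_df], degree=[3], include_intercept=True)
        if penalized:
            gam = GLMGam(y, smoother=basis, family=sm.families.Poisson())
            try:
                alpha = gam.select_penweight(criterion="gcv")[0]
            except Exception:
                alpha = 1.0
            res = GLMGam(
                y, smoother=basis, alpha=alpha, family=sm.families.Poisson()
            ).fit(maxiter=200)
        else:
            res = GLMGam(
                y, smoother=basis, alpha=0.0, family=sm.families.Poisson()
            ).fit(maxiter=200)
        pred = np.asarray(res.predict(exog_smooth=x))
        if not np.all(np.isfinite(pred)):
            raise ValueError("non-finite GAM prediction")
        return pred
    except Exception:
        # degenerate data (e.g. a single nonzero hour): flat mean fallback
        return np.full(len(HOURS), y.mean())


def inverse_effort_weights(
    sample: SSCYSample, surface: EffortSurface
) -> np.ndarray:
    """Normalized inverse-effort weights for one SSCY sample's observations.

    w_i is proportional to 1/e(h_i): observations made at hours of low
    observer effort are upweighted because each one stands in for more true
    activity than an observation from a heavily sampled hour.
    """
    if (sample.season, sample.cell_id) != (surface.season, surface.cell_id):
        raise ValueError(
            f"sample season-cell {(sample.season, sample.cell_id)} does not match "
            f"surface {(surface.season, surface.cell_id)}"
        )
    effort = np.array([surface.at_hour(h) for h in sample.hours], dtype=float)
    w = 1.0 / effort
    return w / w.sum()


def uniform_weights(sample: SSCYSample) -> np.ndarray:
    """Uniform weights (the uncorrected estimator)."""
    return np.full(sample.n, 1.0 / sample.n)


def surfaces_frame(surfaces: Sequence[EffortSurface]) -> pd.DataFrame:
    """Long-format effort table (season, cell, hour, effort)."""
    rows = []
    for s in surfaces:
        for h, e in zip(HOURS, s.effort):
            rows.append(
                {
                    "season": s.season,
                    "cell_row": s.cell_id[0],
                    "cell_col": s.cell_id[1],
                    "hour": h,
                    "effort": e,
                }
            )
    return pd.DataFrame(rows)


def surface_lookup(
    surfaces: Iterable[EffortSurface],
) -> Mapping[tuple[str, tuple[int, int]], EffortSurface]:
    return {(s.season, s.cell_id): s for s in surfaces}
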