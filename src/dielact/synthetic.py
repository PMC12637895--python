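"""Synthetic study generator with known ground truth for every stage.

Emulates the moving parts of a continental citizen-science activity study:
a pure-birth phylogeny with Brownian wingspan evolution, per-cell seasonal
temperature and daylength, species/cell/residual variation in true activity
metrics with known fixed-effect coefficients, an afternoon-peaked observer
effort curve that thins true activity, and occurrence records whose
timestamps invert the solar-time conversion so the ingest stage is an
exact round trip.

True activity is a split (two-piece) normal on the solar-hour axis: the
mode sits at the true median and the two scale parameters are solved
numerically so the 10th and 90th percentiles hit the true onset and
offset. Observed hours are drawn with density proportional to
activity x effort; inverse-effort weighting downstream should undo
exactly that thinning.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import math
import random
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy import optimize, stats

from ._sun import equation_of_time_min, fractional_year
from .covariates import day_length
from .grid import Grid, SSCYSample, grid_for_lonlat_bounds
from .ingest import SEASONS, season_center
from .phylo import lambda_transform, phylo_vcv

logger = logging.getLogger(__name__)

RESPONSES = ("onset", "median", "offset")
COVARIATES = ("temp", "daylength", "wingspan", "n_obs")


def _default_betas() -> dict[str, dict[str, float]]:
    # scaled-covariate effects, in hours per SD; the median effects sit
    # between the onset and offset ones so the three metrics stay ordered
    return {
        "onset": {"daylength": -0.4},
        "median": {"daylength": -0.2, "temp": 0.2, "wingspan": 0.175},
        "offset": {"temp": 0.4, "wingspan": 0.35},
    }


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults are the reference setup."""

    n_species: int = 150
    n_cells: int = 20
    seasons: tuple[str, ...] = SEASONS
    years: tuple[int, ...] = (2021,)
    sscy_per_species_season: int = 1
    n_obs_mean: float = 100.0
    fixed_n_obs: bool = False
    intercepts: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"onset": 10.5, "median": 13.5, "offset": 16.5}
    )
    betas: dict[str, dict[str, float]] = dataclasses.field(default_factory=_default_betas)
    # optional curvature: adds coef * (temp_z^2 - 1) to a response's mean,
    # for studies of nonlinear temperature response
    betas_temp_quadratic: dict[str, float] = dataclasses.field(default_factory=dict)
    sigma_species: float = 0.3
    sigma_cell: float = 0.2
    sigma_resid: float = 0.3
    lambda_wingspan: float = 1.0
    sigma_trait: float = 1.0
    wingspan_base_mm: float = 35.0
    wingspan_scale_mm: float = 8.0
    effort_peak_hour: float = 15.5
    effort_width_h: float = 3.0
    effort_season_level: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"winter": 0.4, "spring": 1.0, "summer": 1.6, "fall": 1.0}
    )
    # recording is squeezed into the warm afternoon in the cold seasons and
    # spread across the day in summer
    effort_season_width: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"winter": 0.7, "spring": 1.0, "summer": 1.3, "fall": 0.85}
    )
    seed: int = 0

    def validate(self) -> None:
        i = self.intercepts
        if not i["onset"] < i["median"] < i["offset"]:
            raise ValueError("intercepts must satisfy onset < median < offset")
        if self.n_species < 3:
            raise ValueError("need at least 3 species")


@dataclasses.dataclass
class TruthTable:
    """Everything the generator knows: per-SSCY truth, traits, coefficients."""

    table: pd.DataFrame
    traits: dict[str, float]
    betas: dict[str, dict[str, float]]
    config: SyntheticConfig
    n_redraws: int
    seed: int


def simulate_phylogeny_and_traits(
    n_species: int,
    lambda_true: float = 1.0,
    sigma_trait: float = 1.0,
    seed: int = 0,
    base_mm: float = 35.0,
    scale_mm: float = 8.0,
) -> tuple[dendropy.Tree, dict[str, float]]:
    """Pure-birth tree scaled to unit height plus Brownian wingspans.

    The latent trait evolves under Brownian motion on the lambda-rescaled
    covariance; wingspan is an affine transform (base + scale * z) so the
    signal statistics, which are affine-invariant, see the same trait. A
    draw producing non-positive wingspans is redrawn.
    """
    rng_tree = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng_tree
    )
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"Species_{i + 1:03d}"
    # the tree process stops exactly at the n-th speciation, which leaves
    # one cherry with near-zero terminal branches; pad every terminal
    # branch by the same small amount (keeps the tree ultrametric) so the
    # covariance matrix is well conditioned, then rescale to unit height
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.01 * height
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height

    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    C = phylo_vcv(tree, taxa)
    L = np.linalg.cholesky(
        lambda_transform(C, lambda_true) + 1e-10 * np.eye(len(taxa))
    )
    rng = np.random.default_rng(seed)
    for _ in range(100):
        z = sigma_trait * (L @ rng.standard_normal(len(taxa)))
        wings = base_mm + scale_mm * z
        if wings.min() > 1.0:
            break
    else:
        raise RuntimeError("could not draw positive wingspans; widen base/scale")
    return tree, dict(zip(taxa, wings))


def _place_cells(n_cells: int, rng: np.random.Generator, grid: Grid) -> list[tuple[int, int]]:
    """Distinct grid cells whose full footprint stays inside the default
    region polygon, so no generated record is lost to the region filter."""
    from .ingest import CONUS_BBOX

    lon_lo = min(p[0] for p in CONUS_BBOX) + 0.2
    lon_hi = max(p[0] for p in CONUS_BBOX) - 0.2
    lat_lo = min(p[1] for p in CONUS_BBOX) + 0.2
    lat_hi = max(p[1] for p in CONUS_BBOX) - 0.2

    def inside(cell: tuple[int, int]) -> bool:
        row, col = cell
        xs = grid.origin_x + (col + np.array([0.0, 0.0, 1.0, 1.0])) * grid.cell_size_m
        ys = grid.origin_y + (row + np.array([0.0, 1.0, 0.0, 1.0])) * grid.cell_size_m
        lat, lon = grid.projection.inverse(xs, ys)
        return bool(
            (lat > lat_lo).all() and (lat < lat_hi).all()
            and (lon > lon_lo).all() and (lon < lon_hi).all()
        )

    cells: set[tuple[int, int]] = set()
    guard = 0
    while len(cells) < n_cells:
        row = int(rng.integers(0, grid.n_rows))
        col = int(rng.integers(0, grid.n_cols))
        if inside((row, col)):
            cells.add((row, col))
        guard += 1
        if guard > 1000 * n_cells:
            raise RuntimeError("grid too small for requested cell count")
    return sorted(cells)


def simulate_design_and_truth(
    config: SyntheticConfig,
    tree: dendropy.Tree,
    wingspan: Mapping[str, float],
    grid: Grid | None = None,
) -> TruthTable:
    """Assemble the SSCY design and the true activity metrics.

    Each species gets ``sscy_per_species_season`` random cells per season
    and year. True metrics are linear in the z-scaled covariates plus a
    phylogenetic species effect, a cell effect, and row noise; rows whose
    residuals break the onset < median < offset ordering are redrawn and
    counted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    if grid is None:
        grid = grid_for_lonlat_bounds(-122.0, 26.0, -70.0, 48.0)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    C = phylo_vcv(tree, taxa)
    cells = _place_cells(config.n_cells, rng, grid)
    cell_lat = {c: grid.cell_center_lonlat(c)[0] for c in cells}

    season_base_temp = {"winter": 4.0, "spring": 14.0, "summer": 25.0, "fall": 15.0}
    rows = []
    for year in config.years:
        for season in config.seasons:
            center = season_center(season, year)
            temp_by_cell = {}
            for c in cells:
                t = (
                    season_base_temp[season]
                    - 0.6 * (cell_lat[c] - 37.0)
                    + rng.normal(0.0, 2.5)
                )
                temp_by_cell[c] = float(np.clip(t, -5.0, 35.0))
            for sp in taxa:
                picks = rng.choice(len(cells), size=config.sscy_per_species_season, replace=False)
                for pick in picks:
                    c = cells[int(pick)]
                    n_obs = (
                        int(round(config.n_obs_mean))
                        if config.fixed_n_obs
                        else int(rng.poisson(config.n_obs_mean))
                    )
                    rows.append(
                        {
                            "species": sp,
                            "season": season,
                            "cell_row": c[0],
                            "cell_col": c[1],
                            "year": year,
                            "n_obs": max(n_obs, 1),
                            "temp_c": temp_by_cell[c],
                            "daylength_h": day_length(cell_lat[c], center),
                            "wingspan": float(wingspan[sp]),
                        }
                    )
    table = pd.DataFrame(rows)

    # z-scale covariates over the assembled design (the same operation the
    # pipeline applies when it builds its model frame)
    for col in ("temp_c", "daylength_h", "wingspan", "n_obs"):
        x = table[col].to_numpy(dtype=float)
        sd = x.std()
        table[col + "_z"] = (x - x.mean()) / sd if sd > 0 else 0.0
    z_column = {
        "temp": "temp_c_z",
        "daylength": "daylength_h_z",
        "wingspan": "wingspan_z",
        "n_obs": "n_obs_z",
    }

    # species effects are Brownian on the tree (one draw per response)
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(len(taxa)))
    sp_index = {s: i for i, s in enumerate(taxa)}
    sp_eff = {
        r: config.sigma_species * (Lc @ rng.standard_normal(len(taxa)))
        for r in RESPONSES
    }
    cell_eff = {
        r: {c: rng.normal(0.0, config.sigma_cell) for c in cells} for r in RESPONSES
    }

    n = len(table)
    mean_part = {}
    for r in RESPONSES:
        mu = np.full(n, config.intercepts[r])
        for cov, beta in config.betas.get(r, {}).items():
            mu = mu + beta * table[z_column[cov]].to_numpy()
        if r in config.betas_temp_quadratic:
            tz = table["temp_c_z"].to_numpy()
            mu = mu + config.betas_temp_quadratic[r] * (tz**2 - 1.0)
        mu += np.array([sp_eff[r][sp_index[s]] for s in table["species"]])
        mu += np.array(
            [cell_eff[r][(row, col)] for row, col in zip(table["cell_row"], table["cell_col"])]
        )
        mean_part[r] = mu
    if not (np.mean(mean_part["onset"]) < np.mean(mean_part["offset"])):
        raise ValueError("configuration implies onset >= offset in expectation")

    n_redraws = 0
    values = {r: np.empty(n) for r in RESPONSES}
    for i in range(n):
        for _ in range(200):
            draw = {r: mean_part[r][i] + rng.normal(0.0, config.sigma_resid) for r in RESPONSES}
            if draw["onset"] + 0.2 < draw["median"] < draw["offset"] - 0.2:
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw ordered metrics; check config variances")
        for r in RESPONSES:
            values[r][i] = draw[r]
    for r in RESPONSES:
        table[r] = values[r]
    table["duration"] = table["offset"] - table["onset"]
    return TruthTable(
        table=table,
        traits=dict(wingspan),
        betas={r: dict(b) for r, b in config.betas.items()},
        config=config,
        n_redraws=n_redraws,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# split-normal activity density


def split_normal_cdf(x: np.ndarray, mode: float, s_left: float, s_right: float) -> np.ndarray:
    """CDF of the two-piece normal with different scales left/right of the mode."""
    x = np.asarray(x, dtype=float)
    a = s_left / (s_left + s_right)
    left = 2.0 * a * stats.norm.cdf((x - mode) / s_left)
    right = a + 2.0 * (1.0 - a) * (stats.norm.cdf((x - mode) / s_right) - 0.5)
    return np.where(x < mode, left, right)


def split_normal_pdf(x: np.ndarray, mode: float, s_left: float, s_right: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    norm = math.sqrt(2.0 / math.pi) / (s_left + s_right)
    scale = np.where(x < mode, s_left, s_right)
    return norm * np.exp(-0.5 * ((x - mode) / scale) ** 2)


def solve_split_normal(onset: float, median: float, offset: float) -> tuple[float, float]:
    """Scales (s_left, s_right) placing the 10th/90th percentiles at onset/offset.

    The mode sits at the true median. Degenerate truth with onset at the
    mode falls back to fixing the left-tail mass at 0.10 (a near-half-
    normal left side), logged rather than failed.
    """
    if median - onset < 1e-6:
        logger.warning("degenerate truth onset==median; using half-normal-side fallback")
        # left mass pinned at 0.10 => s_left = s_right / 9
        def right_eq(log_sr: float) -> float:
            sr = math.exp(log_sr)
            return float(split_normal_cdf(np.array([offset]), median, sr / 9.0, sr)[0] - 0.9)

        sr = math.exp(optimize.brentq(right_eq, -8.0, 5.0))
        return sr / 9.0, sr

    # Reduce to one dimension: with left-tail mass A = sl/(sl+sr), each
    # percentile condition determines its scale in closed form,
    #   F(onset) = 2A phi((onset-m)/sl)        = 0.1   (onset < m)
    #   F(offset) = A + 2(1-A)(phi(.) - 1/2)   = 0.9   (offset > m)
    # and the implied sl/(sl+sr) must equal A again (a fixed point in
    # (0.1, 0.9)); solved by bracketed root finding, which cannot wander.
    def scales(a: float) -> tuple[float, float]:
        sl = (onset - median) / stats.norm.ppf(0.1 / (2.0 * a))
        sr = (offset - median) / stats.norm.ppf(0.5 + (0.9 - a) / (2.0 * (1.0 - a)))
        return sl, sr

    def gap(a: float) -> float:
        sl, sr = scales(a)
        return sl / (sl + sr) - a

    grid_a = np.linspace(0.101, 0.899, 400)
    vals = np.array([gap(a) for a in grid_a])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError(f"split-normal solve failed for ({onset}, {median}, {offset})")
    lo, hi = grid_a[sign_change[0]], grid_a[sign_change[0] + 1]
    a_star = optimize.brentq(gap, lo, hi, xtol=1e-13)
    sl, sr = scales(a_star)
    check = split_normal_cdf(np.array([onset, offset]), median, sl, sr)
    if abs(check[0] - 0.1) > 1e-8 or abs(check[1] - 0.9) > 1e-8:
        raise RuntimeError(f"split-normal solve failed for ({onset}, {median}, {offset})")
    return float(sl), float(sr)


def effort_function(config: SyntheticConfig, season: str) -> Callable[[np.ndarray], np.ndarray]:
    """The true (log-quadratic, afternoon-peaked) observer-effort curve."""
    level = config.effort_season_level.get(season, 1.0)
    peak = config.effort_peak_hour
    width = config.effort_width_h * config.effort_season_width.get(season, 1.0)

    def e(h: np.ndarray) -> np.ndarray:
        return level * np.exp(-0.5 * ((np.asarray(h, float) - peak) / width) ** 2)

    return e


def simulate_observations(
    onset: float,
    median: float,
    offset: float,
    effort: Callable[[np.ndarray], np.ndarray],
    n_obs: int,
    rng: np.random.Generator,
    support: tuple[float, float] = (7.5, 20.5),
    activity_support: tuple[float, float] | None = None,
) -> np.ndarray:
    """Continuous solar hours drawn with density activity(h) x effort(h).

    Sampling uses a fine-grid inverse-CDF (0.002 h resolution with uniform
    jitter inside each step); binning to integer hours is the ingest
    stage's job. ``activity_support`` optionally truncates the activity
    density to a sub-interval.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    sl, sr = solve_split_normal(onset, median, offset)
    step = 0.002
    xs = np.arange(support[0], support[1], step) + step / 2.0
    dens = split_normal_pdf(xs, median, sl, sr)
    if activity_support is not None:
        dens = np.where((xs >= activity_support[0]) & (xs <= activity_support[1]), dens, 0.0)
    p = dens * np.maximum(effort(xs), 0.0)
    total = p.sum()
    if total <= 0:
        raise ValueError("activity x effort density is zero on the support")
    idx = rng.choice(len(xs), size=n_obs, p=p / total)
    return xs[idx] + rng.uniform(-step / 2.0, step / 2.0, size=n_obs)


# ---------------------------------------------------------------------------
# bundle writing


def _utc_for_solar_hour(
    target_solar: float, date: dt.date, longitude: float
) -> dt.datetime:
    """UTC timestamp whose apparent solar hour at ``longitude`` is ``target_solar``.

    Inverts solar = utc + lon/15 + eot/60 by fixed-point iteration on the
    equation of time (which varies by < 0.1 min within a day).
    """
    utc_hour = (target_solar - longitude / 15.0) % 24.0
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    for _ in range(3):
        ts = base + dt.timedelta(hours=utc_hour)
        eot = equation_of_time_min(fractional_year(ts.replace(tzinfo=None)))
        utc_hour = (target_solar - longitude / 15.0 - eot / 60.0) % 24.0
    return base + dt.timedelta(hours=utc_hour)


def generate_study(
    config: SyntheticConfig, grid: Grid | None = None
) -> tuple[TruthTable, dendropy.Tree, Grid, pd.DataFrame, list[SSCYSample]]:
    """Run the full generator in memory.

    Returns the truth table, tree, grid, an occurrence table (one row per
    record, already carrying its continuous and binned solar hour for
    convenience) and the true SSCY hour multisets.
    """
    config.validate()
    tree, wings = simulate_phylogeny_and_traits(
        config.n_species,
        config.lambda_wingspan,
        config.sigma_trait,
        config.seed,
        config.wingspan_base_mm,
        config.wingspan_scale_mm,
    )
    if grid is None:
        grid = grid_for_lonlat_bounds(-122.0, 26.0, -70.0, 48.0)
    truth = simulate_design_and_truth(config, tree, wings, grid)
    rng = np.random.default_rng(config.seed + 2)

    occ_rows = []
    samples: list[SSCYSample] = []
    rec_id = 0
    for _, row in truth.table.iterrows():
        cell = (int(row.cell_row), int(row.cell_col))
        season, year = row.season, int(row.year)
        e = effort_function(config, season)
        hours = simulate_observations(
            row.onset, row["median"], row.offset, e, int(row.n_obs), rng
        )
        center = season_center(season, year)
        day_offsets = rng.integers(-44, 45, size=len(hours))
        # uniform position inside the cell, inverse-projected to lon/lat
        px = grid.origin_x + (cell[1] + rng.uniform(0.02, 0.98, len(hours))) * grid.cell_size_m
        py = grid.origin_y + (cell[0] + rng.uniform(0.02, 0.98, len(hours))) * grid.cell_size_m
        lats, lons = grid.projection.inverse(px, py)
        binned = np.floor(hours + 0.5).astype(int)
        for h, cont, d_off, la, lo in zip(binned, hours, day_offsets, lats, lons):
            ts = _utc_for_solar_hour(float(cont), center + dt.timedelta(days=int(d_off)), float(lo))
            occ_rows.append(
                {
                    "id": f"r{rec_id:07d}",
                    "species": row.species,
                    "eventDateTime": ts.isoformat(),
                    "decimalLatitude": round(float(la), 6),
                    "decimalLongitude": round(float(lo), 6),
                    "lifeStage": "adult",
                    "project": "",
                    "solar_hour_true": float(cont),
                    "solar_hour_binned": int(h),
                }
            )
            rec_id += 1
        samples.append(
            SSCYSample(row.species, season, cell, year, tuple(int(b) for b in binned))
        )
    occurrences = pd.DataFrame(occ_rows)
    return truth, tree, grid, occurrences, samples


def write_bundle(config: SyntheticConfig, outdir: str) -> TruthTable:
    """Write a complete, pipeline-consumable bundle of plain-text files.

    Files: occurrences.csv, temperature.csv, traits.csv, tree.nwk,
    truth.csv, sscy_truth.csv (true hour multisets). Deterministic for a
    given (config, seed).
    """
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth, tree, grid, occurrences, samples = generate_study(config)

    occurrences.drop(columns=["solar_hour_true", "solar_hour_binned"]).to_csv(
        out / "occurrences.csv", index=False
    )

    from .covariates import season_months

    temp_rows = []
    rng = np.random.default_rng(config.seed + 3)
    seen = set()
    for _, row in truth.table.iterrows():
        key = (int(row.cell_row), int(row.cell_col), row.season, int(row.year))
        if key in seen:
            continue
        seen.add(key)
        months = season_months(row.season, int(row.year))
        spread = float(rng.uniform(0.5, 3.0))
        for (y, m), delta in zip(months, (-spread, 0.0, spread)):
            temp_rows.append(
                {
                    "cell_row": key[0],
                    "cell_col": key[1],
                    "year": y,
                    "month": m,
                    "value_c": round(float(row.temp_c) + delta, 4),
                }
            )
    pd.DataFrame(temp_rows).to_csv(out / "temperature.csv", index=False)

    pd.DataFrame(
        {"species": list(truth.traits), "wingspan_mm": list(truth.traits.values())}
    ).to_csv(out / "traits.csv", index=False)
    tree.write(path=str(out / "tree.nwk"), schema="newick", suppress_rooting=True)
    truth.table.to_csv(out / "truth.csv", index=False)

    pd.DataFrame(
        {
            "species": [s.species for s in samples],
            "season": [s.season for s in samples],
            "cell_row": [s.cell_id[0] for s in samples],
            "cell_col": [s.cell_id[1] for s in samples],
            "year": [s.year for s in samples],
            "hours": ["|".join(map(str, sorted(s.hours))) for s in samples],
        }
    ).to_csv(out / "sscy_truth.csv", index=False)
    return truth
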