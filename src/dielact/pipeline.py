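"""Stage runners tying the modules into a file-based pipeline.

Each stage reads the previous stage's CSV artifacts from the work
directory, writes its own, and records a manifest entry (row counts,
seeds, parameters) so a run is auditable and any stage can be re-run or
tested in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import time
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .activity import bootstrap_metrics, correction_summary, metrics_frame
from .covariates import attach_covariates, build_model_frame, load_traits
from .effort import (
    fit_effort_curve,
    inverse_effort_weights,
    surface_lookup,
    surfaces_frame,
    tabulate_effort,
    uniform_weights,
    EffortSurface,
    HOURS,
)
from .grid import Grid, SSCYSample, assign_cell, assemble_sscy, grid_for_lonlat_bounds, sscy_frame
from .ingest import FilterConfig, read_and_filter, to_solar
from .models import ModelSpec, RandomSpec, compare_models, fit_response, species_residuals, vif, design_matrix
from .phylo import blomberg_k, pagel_lambda_ml, phylo_vcv, read_tree
from .synthetic import SyntheticConfig, write_bundle


@dataclasses.dataclass
class PipelineConfig:
    """Validated knobs for every stage; unknown keys are rejected on load."""

    workdir: str = "dielact_run"
    seed: int = 0
    min_n: int = 30
    min_n_level: str = "sscy"
    B: int = 50
    cell_km: float = 250.0
    lon_min: float = -122.0
    lat_min: float = 26.0
    lon_max: float = -70.0
    lat_max: float = 48.0
    spline_df: int = 4
    criterion: str = "loo"
    temp_statistic: str = "mean"
    sun_altitude: float = -0.833
    effort_basis_df: int = 5
    effort_floor: float = 0.5
    min_year: int = 2016
    n_perm: int = 999
    synthetic: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def path(self) -> pathlib.Path:
        return pathlib.Path(self.workdir)


def _require(cfg: PipelineConfig, *names: str) -> None:
    for name in names:
        if not (cfg.path / name).exists():
            raise FileNotFoundError(
                f"missing prerequisite artifact {cfg.path / name}; run the producing stage first"
            )


def _manifest(cfg: PipelineConfig, stage: str, info: dict[str, Any]) -> None:
    path = cfg.path / "manifest.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append(
        {
            "stage": stage,
            "version": __version__,
            "seed": cfg.seed,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **info,
        }
    )
    path.write_text(json.dumps(entries, indent=2))


def default_grid(cfg: PipelineConfig) -> Grid:
    return grid_for_lonlat_bounds(
        cfg.lon_min, cfg.lat_min, cfg.lon_max, cfg.lat_max, cfg.cell_km
    )


def run_simulate(cfg: PipelineConfig) -> None:
    cfg.path.mkdir(parents=True, exist_ok=True)
    syn = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
    truth = write_bundle(syn, str(cfg.path / "bundle"))
    _manifest(cfg, "simulate", {"n_sscy_truth": len(truth.table), "n_redraws": truth.n_redraws})


def run_ingest(cfg: PipelineConfig) -> None:
    _require(cfg, "bundle/occurrences.csv")
    grid = default_grid(cfg)
    records, report = read_and_filter(
        str(cfg.path / "bundle/occurrences.csv"), FilterConfig(min_year=cfg.min_year)
    )
    solar = to_solar(records, report)
    rows = []
    for obs in solar:
        cell = assign_cell(obs.latitude, obs.longitude, grid)
        rows.append(
            {
                "species": obs.species,
                "season": obs.season,
                "year": obs.season_year,
                "cell_row": -1 if cell is None else cell[0],
                "cell_col": -1 if cell is None else cell[1],
                "solar_hour": obs.solar_hour,
            }
        )
    pd.DataFrame(rows).to_csv(cfg.path / "solar.csv", index=False)

    paired = [
        (obs, (r["cell_row"], r["cell_col"]))
        for obs, r in zip(solar, rows)
        if r["cell_row"] >= 0
    ]
    samples, n_dropped = assemble_sscy(paired, cfg.min_n, cfg.min_n_level)
    sscy_frame(samples).to_csv(cfg.path / "sscy.csv", index=False)
    (cfg.path / "filter_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    _manifest(
        cfg,
        "ingest",
        {
            "n_records_retained": report.retained,
            "n_sscy": len(samples),
            "n_obs_below_min_n": n_dropped,
        },
    )


def run_effort(cfg: PipelineConfig) -> None:
    _require(cfg, "solar.csv")
    solar = pd.read_csv(cfg.path / "solar.csv")
    solar = solar[solar.cell_row >= 0]
    counts: dict[tuple[str, tuple[int, int]], np.ndarray] = {}
    for (season, row, col), sub in solar.groupby(["season", "cell_row", "cell_col"]):
        arr = np.zeros(len(HOURS), dtype=int)
        for h, k in sub["solar_hour"].value_counts().items():
            arr[int(h) - HOURS[0]] = int(k)
        counts[(season, (int(row), int(col)))] = arr

    from .effort import EffortCounts

    surfaces = [
        fit_effort_curve(
            EffortCounts(season, cell, tuple(int(x) for x in arr)),
            cfg.effort_basis_df,
            cfg.effort_floor,
        )
        for (season, cell), arr in sorted(counts.items())
    ]
    surfaces_frame(surfaces).to_csv(cfg.path / "effort.csv", index=False)
    _manifest(cfg, "effort", {"n_surfaces": len(surfaces)})


def load_sscy(path: pathlib.Path) -> list[SSCYSample]:
    table = pd.read_csv(path)
    return [
        SSCYSample(
            r.species,
            r.season,
            (int(r.cell_row), int(r.cell_col)),
            int(r.year),
            tuple(int(h) for h in str(r.hours).split("|")),
        )
        for r in table.itertuples()
    ]


def load_surfaces(path: pathlib.Path, floor: float) -> list[EffortSurface]:
    table = pd.read_csv(path)
    out = []
    for (season, row, col), sub in table.groupby(["season", "cell_row", "cell_col"]):
        effort = tuple(
            float(sub.loc[sub.hour == h, "effort"].iloc[0]) for h in HOURS
        )
        out.append(
            EffortSurface(season, (int(row), int(col)), effort, 0, True, floor)
        )
    return out


def run_metrics(cfg: PipelineConfig) -> None:
    _require(cfg, "sscy.csv", "effort.csv")
    samples = load_sscy(cfg.path / "sscy.csv")
    lookup = surface_lookup(load_surfaces(cfg.path / "effort.csv", cfg.effort_floor))
    corrected, raw = [], []
    for s in samples:
        surface = lookup[(s.season, s.cell_id)]
        w = inverse_effort_weights(s, surface)
        corrected.append(bootstrap_metrics(s, w, B=cfg.B, seed=cfg.seed))
        raw.append(bootstrap_metrics(s, uniform_weights(s), B=cfg.B, seed=cfg.seed + 1))
    metrics_frame(corrected).to_csv(cfg.path / "metrics.csv", index=False)
    metrics_frame(raw).to_csv(cfg.path / "metrics_raw.csv", index=False)
    summary = correction_summary(corrected, raw)
    (cfg.path / "correction_summary.json").write_text(
        json.dumps(dataclasses.asdict(summary), indent=2)
    )
    _manifest(cfg, "metrics", {"n_sscy": len(corrected)})


def run_covariates(cfg: PipelineConfig) -> None:
    _require(cfg, "metrics.csv", "bundle/temperature.csv", "bundle/traits.csv")
    from .activity import ActivityMetrics

    table = pd.read_csv(cfg.path / "metrics.csv")
    metrics = [
        ActivityMetrics(
            r.species, r.season, (int(r.cell_row), int(r.cell_col)), int(r.year),
            int(r.n), float(r.onset), float(r["median"]), float(r.offset),
            float(r.sd_onset), float(r.sd_median), float(r.sd_offset), int(r.B), int(r.seed),
        )
        for _, r in table.iterrows()
    ]
    temps = pd.read_csv(cfg.path / "bundle/temperature.csv")
    traits = load_traits(str(cfg.path / "bundle/traits.csv"))
    grid = default_grid(cfg)
    joined, dropped = attach_covariates(
        metrics, temps, traits, grid, cfg.sun_altitude, cfg.temp_statistic
    )
    frame, scaling = build_model_frame(joined)
    frame.to_csv(cfg.path / "model_frame.csv", index=False)
    if scaling is not None:
        (cfg.path / "scaling.json").write_text(
            json.dumps({"means": scaling.means, "sds": scaling.sds}, indent=2)
        )
    _manifest(cfg, "covariates", {"n_rows": len(frame), **dropped})


def run_model(cfg: PipelineConfig) -> None:
    _require(cfg, "model_frame.csv", "bundle/tree.nwk")
    frame = pd.read_csv(cfg.path / "model_frame.csv")
    tree = read_tree(str(cfg.path / "bundle/tree.nwk"))
    species_order = sorted(frame["species"].unique())
    C = phylo_vcv(tree, species_order)

    all_coefs, rankings, resid_rows = [], [], []
    for response in ("onset", "median", "offset", "duration"):
        base = ModelSpec(response=response, temperature="linear")
        candidates = [
            base,
            ModelSpec(response=response, temperature="spline", spline_df=cfg.spline_df),
            ModelSpec(response=response, temperature="linear", interaction=True),
            ModelSpec(response=response, temperature="linear", include_n_obs=True),
        ]
        ranking = compare_models(frame, candidates, C, species_order, criterion=cfg.criterion)
        ranking.insert(0, "response", response)
        rankings.append(ranking)
        winners = ranking[ranking.wins]
        top = (
            candidates[int(winners.index[0])]
            if len(winners)
            else base
        )
        fit = fit_response(frame, top, C, species_order)
        coefs = fit.coef.copy()
        coefs.insert(0, "response", response)
        coefs.insert(1, "spec", top.name)
        all_coefs.append(coefs)
        for sp, res in species_residuals(fit).items():
            resid_rows.append({"response": response, "species": sp, "residual": res})

        X, names = design_matrix(frame, base)
        vif_table = vif(X[:, 1:], names[1:])
        vif_table.insert(0, "response", response)
        (cfg.path / f"vif_{response}.csv").write_text(vif_table.to_csv(index=False))

    pd.concat(all_coefs).to_csv(cfg.path / "model_coefficients.csv", index=False)
    pd.concat(rankings).to_csv(cfg.path / "model_ranking.csv", index=False)
    pd.DataFrame(resid_rows).to_csv(cfg.path / "model_residuals.csv", index=False)
    _manifest(cfg, "model", {"n_rows": len(frame), "n_species": len(species_order)})


def run_physig(cfg: PipelineConfig) -> None:
    _require(cfg, "model_frame.csv", "model_residuals.csv", "bundle/tree.nwk")
    frame = pd.read_csv(cfg.path / "model_frame.csv")
    residuals = pd.read_csv(cfg.path / "model_residuals.csv")
    tree = read_tree(str(cfg.path / "bundle/tree.nwk"))

    rows = []
    for response in ("onset", "median", "offset", "duration"):
        raw_trait = frame.groupby("species")[response].mean().to_dict()
        for label, trait in (
            ("raw", raw_trait),
            (
                "residual",
                residuals[residuals.response == response]
                .set_index("species")["residual"]
                .to_dict(),
            ),
        ):
            if len(trait) < 3:
                continue
            k = blomberg_k(tree, trait, n_perm=cfg.n_perm, seed=cfg.seed)
            lam = pagel_lambda_ml(tree, trait)
            rows.append(
                {
                    "response": response,
                    "trait": label,
                    "K": k.estimate,
                    "K_p": k.p_value,
                    "lambda": lam.estimate,
                    "lambda_p": lam.p_value,
                }
            )
    pd.DataFrame(rows).to_csv(cfg.path / "phylo_signal.csv", index=False)
    _manifest(cfg, "physig", {"n_tests": len(rows)})


STAGES = {
    "simulate": run_simulate,
    "ingest": run_ingest,
    "effort": run_effort,
    "metrics": run_metrics,
    "covariates": run_covariates,
    "model": run_model,
    "physig": run_physig,
}


def run(stage: str, cfg: PipelineConfig) -> None:
    """Run one stage, or the whole chain with ``all``."""
    if stage == "all":
        for name in STAGES:
            STAGES[name](cfg)
    elif stage in STAGES:
        STAGES[stage](cfg)
    else:
        raise ValueError(f"unknown stage {stage!r}")
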