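import hashlib
import pathlib

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from dielact.grid import assemble_sscy, assign_cell, grid_for_lonlat_bounds
from dielact.ingest import FilterConfig, read_and_filter, to_solar
from dielact.phylo import pagel_lambda_ml, blomberg_k
from dielact.synthetic import (
    SyntheticConfig,
    effort_function,
    generate_study,
    simulate_design_and_truth,
    simulate_observations,
    simulate_phylogeny_and_traits,
    solve_split_normal,
    split_normal_pdf,
    write_bundle,
)


class TestPhylogenyAndTraits:
    def test_tree_shape_and_unit_height(self):
        tree, wings = simulate_phylogeny_and_traits(20, seed=3)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        assert len(labels) == 20 and len(set(labels)) == 20
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert np.allclose(depths, 1.0, atol=1e-9)
        assert set(wings) == set(labels)
        assert min(wings.values()) > 0

    def test_deterministic(self):
        t1, w1 = simulate_phylogeny_and_traits(15, seed=9)
        t2, w2 = simulate_phylogeny_and_traits(15, seed=9)
        assert w1 == w2
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_lambda_one_traits_carry_signal(self):
        tree, wings = simulate_phylogeny_and_traits(64, lambda_true=1.0, seed=4)
        res = pagel_lambda_ml(tree, wings)
        assert res.estimate >= 0.7


class TestDesignAndTruth:
    def test_zero_betas_and_variances_give_intercepts(self):
        cfg = SyntheticConfig(
            n_species=5, n_cells=3, seed=1,
            betas={}, sigma_species=0.0, sigma_cell=0.0, sigma_resid=0.0,
        )
        tree, wings = simulate_phylogeny_and_traits(5, seed=1)
        truth = simulate_design_and_truth(cfg, tree, wings)
        assert np.allclose(truth.table["onset"], 10.5)
        assert np.allclose(truth.table["offset"], 16.5)
        assert truth.n_redraws == 0

    def test_disordered_intercepts_rejected(self):
        cfg = SyntheticConfig(intercepts={"onset": 15.0, "median": 13.0, "offset": 12.0})
        with pytest.raises(ValueError, match="onset < median < offset"):
            cfg.validate()

    def test_ordering_holds_with_noise(self):
        cfg = SyntheticConfig(n_species=30, n_cells=5, seed=2, sigma_resid=0.8)
        tree, wings = simulate_phylogeny_and_traits(30, seed=2)
        truth = simulate_design_and_truth(cfg, tree, wings)
        t = truth.table
        assert (t["onset"] < t["median"]).all()
        assert (t["median"] < t["offset"]).all()
        assert (t["duration"] > 0).all()

    def test_species_effects_carry_phylo_signal(self):
        hits = 0
        for rep in range(6):
            cfg = SyntheticConfig(n_species=64, n_cells=8, seed=50 + rep,
                                  sigma_species=0.5, sigma_resid=0.15, sigma_cell=0.1)
            tree, wings = simulate_phylogeny_and_traits(64, seed=50 + rep)
            truth = simulate_design_and_truth(cfg, tree, wings)
            trait = truth.table.groupby("species")["onset"].mean().to_dict()
            res = blomberg_k(tree, trait, n_perm=199, seed=rep)
            hits += res.p_value < 0.05
        assert hits >= 4


class TestSplitNormal:
    @pytest.mark.parametrize("omf", [(10.0, 13.5, 16.5), (9.2, 11.0, 17.8), (11.0, 15.5, 17.0)])
    def test_solved_scales_place_the_percentiles(self, omf):
        onset, median, offset = omf
        sl, sr = solve_split_normal(onset, median, offset)
        # oracle: numeric integration of the density, independent of the CDF
        for target, q in ((onset, 0.1), (offset, 0.9)):
            mass, _ = integrate.quad(
                lambda x: split_normal_pdf(x, median, sl, sr), -50, target
            )
            assert mass == pytest.approx(q, abs=1e-6)

    def test_density_integrates_to_one(self):
        sl, sr = solve_split_normal(10.0, 13.5, 16.5)
        mass, _ = integrate.quad(lambda x: split_normal_pdf(x, 13.5, sl, sr), -50, 50)
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_onset_at_mode_falls_back(self, caplog):
        sl, sr = solve_split_normal(13.5, 13.5, 16.5)
        assert 0 < sl < sr


class TestSimulateObservations:
    def test_flat_effort_recovers_percentiles(self):
        rng = np.random.default_rng(13)
        hours = simulate_observations(
            10.0, 13.5, 16.5, lambda h: np.ones_like(np.asarray(h, float)), 5000, rng
        )
        assert np.quantile(hours, 0.1) == pytest.approx(10.0, abs=0.3)
        assert np.quantile(hours, 0.5) == pytest.approx(13.5, abs=0.3)
        assert np.quantile(hours, 0.9) == pytest.approx(16.5, abs=0.3)

    def test_truncated_support_respected(self):
        rng = np.random.default_rng(14)
        hours = simulate_observations(
            10.0, 12.0, 14.0, lambda h: np.ones_like(np.asarray(h, float)), 500, rng,
            activity_support=(10.0, 14.0),
        )
        assert hours.min() >= 10.0 - 0.01 and hours.max() <= 14.0 + 0.01

    def test_binned_distribution_matches_density(self):
        # chi-square goodness of fit of binned draws against the binned
        # activity x effort density
        from dielact.synthetic import split_normal_cdf

        rng = np.random.default_rng(0)
        onset, median, offset = 10.0, 13.5, 16.5
        hours = simulate_observations(
            onset, median, offset, lambda h: np.ones_like(np.asarray(h, float)), 5000, rng
        )
        binned = np.floor(hours + 0.5).astype(int)
        sl, sr = solve_split_normal(onset, median, offset)
        edges = np.arange(7.5, 21.0)
        p = np.diff(split_normal_cdf(edges, median, sl, sr))
        p /= p.sum()
        observed = np.array([(binned == h).sum() for h in range(8, 21)])
        res = stats.chisquare(observed, p * observed.sum())
        assert res.pvalue > 0.01

    def test_afternoon_effort_shifts_draws_late(self):
        rng = np.random.default_rng(16)
        cfg = SyntheticConfig()
        flat = simulate_observations(10.0, 13.5, 16.5, lambda h: np.ones_like(np.asarray(h, float)), 4000, rng)
        peaked = simulate_observations(10.0, 13.5, 16.5, effort_function(cfg, "summer"), 4000, rng)
        assert np.quantile(peaked, 0.1) > np.quantile(flat, 0.1) + 0.5

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="n_obs"):
            simulate_observations(10, 13, 16, lambda h: np.ones_like(np.asarray(h, float)), 0, rng)
        with pytest.raises(ValueError, match="zero"):
            simulate_observations(
                10, 13, 16, lambda h: np.zeros_like(np.asarray(h, float)), 5, rng
            )


class TestWriteBundle:
    def _digest(self, path: pathlib.Path) -> dict[str, str]:
        return {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(path.iterdir())
        }

    def test_round_trip_reproduces_hour_multisets(self, tmp_path):
        cfg = SyntheticConfig(n_species=8, n_cells=4, seed=6, n_obs_mean=40)
        write_bundle(cfg, str(tmp_path / "b"))
        records, report = read_and_filter(str(tmp_path / "b" / "occurrences.csv"), FilterConfig())
        solar = to_solar(records, report)
        assert report.removed == 0
        grid = grid_for_lonlat_bounds(-122.0, 26.0, -70.0, 48.0)
        paired = [(o, assign_cell(o.latitude, o.longitude, grid)) for o in solar]
        samples, _ = assemble_sscy(paired, min_n=1)
        got = {
            (s.species, s.season, s.cell_id, s.year): tuple(sorted(s.hours))
            for s in samples
        }
        truth = pd.read_csv(tmp_path / "b" / "sscy_truth.csv")
        want = {
            (r.species, r.season, (r.cell_row, r.cell_col), r.year): tuple(
                int(h) for h in r.hours.split("|")
            )
            for r in truth.itertuples()
        }
        assert got == want

    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = SyntheticConfig(n_species=5, n_cells=3, seed=7, n_obs_mean=25)
        write_bundle(cfg, str(tmp_path / "b1"))
        write_bundle(cfg, str(tmp_path / "b2"))
        assert self._digest(tmp_path / "b1") == self._digest(tmp_path / "b2")

    def test_below_threshold_groups_dropped_downstream(self, tmp_path):
        cfg = SyntheticConfig(n_species=6, n_cells=3, seed=8, n_obs_mean=25)
        truth = write_bundle(cfg, str(tmp_path / "b"))
        records, report = read_and_filter(str(tmp_path / "b" / "occurrences.csv"), FilterConfig())
        solar = to_solar(records, report)
        grid = grid_for_lonlat_bounds(-122.0, 26.0, -70.0, 48.0)
        paired = [(o, assign_cell(o.latitude, o.longitude, grid)) for o in solar]
        samples, dropped = assemble_sscy(paired, min_n=30)
        kept_keys = {(s.species, s.season, s.cell_id, s.year) for s in samples}
        for _, row in truth.table.iterrows():
            key = (row.species, row.season, (row.cell_row, row.cell_col), row.year)
            assert (key in kept_keys) == (row.n_obs >= 30)

    def test_temperature_csv_reproduces_truth_means(self, tmp_path):
        from dielact.covariates import seasonal_mean_temperature

        cfg = SyntheticConfig(n_species=5, n_cells=3, seed=9, n_obs_mean=20)
        truth = write_bundle(cfg, str(tmp_path / "b"))
        temps = pd.read_csv(tmp_path / "b" / "temperature.csv")
        for _, row in truth.table.head(10).iterrows():
            got = seasonal_mean_temperature(
                temps, (row.cell_row, row.cell_col), row.season, int(row.year)
            )
            assert got == pytest.approx(row.temp_c, abs=1e-3)
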