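import numpy as np
import pandas as pd
import pytest

from dielact.models import (
    ModelSpec,
    RandomSpec,
    compare_models,
    design_matrix,
    fit_phylo_lmm,
    fit_response,
    loo_pointwise,
    species_residuals,
    vif,
)
from dielact.phylo import phylo_vcv
from dielact.synthetic import (
    SyntheticConfig,
    simulate_design_and_truth,
    simulate_phylogeny_and_traits,
)

NO_RANDOM = RandomSpec(species_intercept=False, cell_intercept=False)


@pytest.fixture(scope="module")
def truth_frame():
    cfg = SyntheticConfig(n_species=40, n_cells=8, seed=21)
    tree, wings = simulate_phylogeny_and_traits(
        cfg.n_species, cfg.lambda_wingspan, cfg.sigma_trait, cfg.seed,
        cfg.wingspan_base_mm, cfg.wingspan_scale_mm,
    )
    truth = simulate_design_and_truth(cfg, tree, wings)
    order = sorted(truth.table["species"].unique())
    return truth.table, phylo_vcv(tree, order), order


class TestDesignMatrix:
    def test_linear_spec_columns(self, truth_frame):
        frame, _, _ = truth_frame
        X, names = design_matrix(frame, ModelSpec(response="onset"))
        assert names == ["intercept", "temp", "daylength", "wingspan"]
        assert X.shape == (len(frame), 4)

    def test_spline_replaces_linear_temperature(self, truth_frame):
        frame, _, _ = truth_frame
        X, names = design_matrix(frame, ModelSpec(response="onset", temperature="spline"))
        assert names[1:5] == [f"temp_spline_{j}" for j in (1, 2, 3, 4)]
        assert "temp" not in names
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_interaction_is_elementwise_product(self, truth_frame):
        frame, _, _ = truth_frame
        X, names = design_matrix(frame, ModelSpec(response="onset", interaction=True))
        j = names.index("temp:wingspan")
        prod = frame["temp_c_z"].to_numpy() * frame["wingspan_z"].to_numpy()
        assert np.allclose(X[:, j], prod, atol=1e-12)

    def test_rank_deficiency_names_columns(self, truth_frame):
        frame, _, _ = truth_frame
        frame = frame.copy()
        frame["dup"] = frame["daylength_h_z"]
        with pytest.raises(ValueError, match="dup"):
            design_matrix(frame, ModelSpec(response="onset", extra_columns=("dup",)))

    def test_spline_df_floor(self, truth_frame):
        frame, _, _ = truth_frame
        with pytest.raises(ValueError, match="spline_df"):
            design_matrix(frame, ModelSpec(response="onset", temperature="spline", spline_df=2))


class TestFitPhyloLMM:
    def test_collapses_to_ols_without_random_terms(self):
        rng = np.random.default_rng(0)
        x = np.arange(5, dtype=float)
        y = 2.0 * x
        X = np.column_stack([np.ones(5), x])
        fit = fit_phylo_lmm(y, X, None, ["s"] * 5, ["c"] * 5, NO_RANDOM, names=["b0", "b1"])
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-9)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-9)

    def test_gls_equals_ols_with_noise(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(60), rng.standard_normal((60, 2))])
        y = X @ np.array([1.0, -0.5, 2.0]) + rng.standard_normal(60)
        fit = fit_phylo_lmm(y, X, None, ["s"] * 60, ["c"] * 60, NO_RANDOM)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, beta_ols, atol=1e-9)

    def test_variance_components_nonnegative_and_intervals_ordered(self, truth_frame):
        frame, C, order = truth_frame
        fit = fit_response(frame, ModelSpec(response="offset"), C, order)
        assert all(v >= 0 for v in fit.varcomp.values())
        assert (fit.coef["ci_lower"] <= fit.coef["ci_upper"]).all()
        assert fit.converged

    def test_objective_history_monotone(self, truth_frame):
        frame, C, order = truth_frame
        fit = fit_response(frame, ModelSpec(response="onset"), C, order)
        h = np.array(fit.objective_history)
        assert (np.diff(h) <= 1e-6).all()

    def test_recovers_species_variance_structure(self, truth_frame):
        # species + cell + residual variances were 0.3^2, 0.2^2, 0.3^2
        frame, C, order = truth_frame
        fit = fit_response(frame, ModelSpec(response="offset"), C, order)
        total = sum(fit.varcomp.values())
        assert 0.5 * 0.22 < total < 2.0 * 0.22

    def test_non_psd_covariance_rejected(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        y = np.arange(4.0)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_phylo_lmm(y, X, bad, ["a", "a", "b", "b"], ["c"] * 4)

    def test_duplicate_predictor_rejected(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_phylo_lmm(np.arange(5.0), X, None, ["s"] * 5, ["c"] * 5, NO_RANDOM)

    def test_random_slopes_add_components(self, truth_frame):
        frame, C, order = truth_frame
        fit = fit_response(
            frame, ModelSpec(response="offset"), C, order,
            random_spec=RandomSpec(species_temp_slope=True, cell_temp_slope=True),
        )
        assert {"species", "cell", "species_slope", "cell_slope", "residual"} == set(fit.varcomp)


class TestModelComparison:
    def test_self_comparison_has_zero_difference(self, truth_frame):
        frame, C, order = truth_frame
        spec = ModelSpec(response="onset")
        table = compare_models(frame, [spec, spec], C, order)
        assert table["diff_vs_baseline"].iloc[1] == pytest.approx(0.0, abs=1e-6)
        assert not table["wins"].iloc[1]

    def test_loo_pointwise_matches_sum(self, truth_frame):
        frame, C, order = truth_frame
        fit = fit_response(frame, ModelSpec(response="onset"), C, order)
        pw = loo_pointwise(fit)
        assert len(pw) == len(frame)
        assert np.isfinite(pw).all()

    def test_aic_criterion_available(self, truth_frame):
        frame, C, order = truth_frame
        specs = [ModelSpec(response="onset"), ModelSpec(response="onset", temperature="spline")]
        table = compare_models(frame, specs, C, order, criterion="aic")
        assert set(table["criterion"]) == {"aic"}

    def test_loo_and_aic_usually_agree(self, truth_frame):
        # both criteria should prefer the same model on clearly nested fits
        frame, C, order = truth_frame
        rng = np.random.default_rng(3)
        agree = 0
        for rep in range(5):
            f = frame.copy()
            f["noise"] = rng.standard_normal(len(f))
            specs = [ModelSpec(response="offset"), ModelSpec(response="offset", extra_columns=("noise",))]
            loo = compare_models(f, specs, C, order, criterion="loo")
            aic = compare_models(f, specs, C, order, criterion="aic")
            loo_pref = loo["value"].iloc[1] > loo["value"].iloc[0]
            aic_pref = aic["value"].iloc[1] < aic["value"].iloc[0]
            agree += loo_pref == aic_pref
        assert agree >= 4

    def test_needs_two_candidates(self, truth_frame):
        frame, C, order = truth_frame
        with pytest.raises(ValueError, match="two candidate"):
            compare_models(frame, [ModelSpec(response="onset")], C, order)


class TestVIF:
    def test_orthogonal_columns_give_unity(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 3))])
        Q, _ = np.linalg.qr(X)
        table = vif(Q[:, 1:])  # mutually orthogonal and orthogonal to 1
        assert np.allclose(table["vif"], 1.0, atol=1e-9)

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(500)
        b = rng.standard_normal(500)
        # construct exact sample correlation 0.8 via Gram-Schmidt
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b = b - (b @ a) / (a @ a) * a
        b = 0.8 * a + np.sqrt(1 - 0.64) * b / b.std()
        table = vif(np.column_stack([a, b]))
        assert np.allclose(table["vif"], 1 / (1 - 0.64), atol=1e-3)

    def test_exact_collinearity_rejected(self):
        x = np.random.default_rng(6).standard_normal(50)
        with pytest.raises(ValueError, match="collinear"):
            vif(np.column_stack([x, 2 * x]))

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            vif(np.ones((10, 1)))


class TestSpeciesResiduals:
    def test_averages_per_species(self, truth_frame):
        frame, C, order = truth_frame
        fit = fit_response(frame, ModelSpec(response="onset"), C, order)
        res = species_residuals(fit)
        assert set(res) == set(frame["species"])
        sp = order[0]
        mask = fit.species == sp
        assert res[sp] == pytest.approx(fit.resid_marginal[mask].mean())

    def test_zero_residuals_map_to_zero(self):
        x = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), x])
        fit = fit_phylo_lmm(2 * x, X, None, ["a", "a", "a", "b", "b", "b"], ["c"] * 6, NO_RANDOM)
        res = species_residuals(fit)
        assert res["a"] == pytest.approx(0.0, abs=1e-8)
        assert res["b"] == pytest.approx(0.0, abs=1e-8)
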