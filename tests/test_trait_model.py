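import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from pemtrait.pem_core import build_pem
from pemtrait.phylo_graph import influence_matrix
from pemtrait.synthetic_data import SimulationConfig, simulate_dataset
from pemtrait.trait_model import (
    CandidateModel,
    FitError,
    aicc,
    fit_candidate_model,
    forward_select_eigenvectors,
    holm_sidak_adjust,
    model_comparison_table,
    candidate_model_grid,
)

from conftest import random_tree


@pytest.fixture(scope="module")
def dataset():
    config = SimulationConfig(seed=11, n_tips=24, fossil_fraction=0.25)
    tree, table, truth = simulate_dataset(config)
    training = table.loc[table["status"] == "extant", "taxon"].tolist()
    basis = build_pem(influence_matrix(tree, training))
    return table, basis


class TestHolmSidak:
    def test_single_test_unchanged(self):
        np.testing.assert_allclose(holm_sidak_adjust([0.05]), [0.05])

    def test_derived_pair(self):
        out = holm_sidak_adjust([0.01, 0.04])
        np.testing.assert_allclose(out, [1 - 0.99**2, 0.04])
        assert out[0] == pytest.approx(0.0199)

    def test_all_equal_inputs(self):
        p = 0.02
        out = holm_sidak_adjust([p] * 4)
        np.testing.assert_allclose(out, 1 - (1 - p) ** 4)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_properties_and_library_agreement(self, p):
        out = holm_sidak_adjust(p)
        assert (out >= np.asarray(p) - 1e-15).all()
        assert (out <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(out[order]) >= -1e-15).all()
        _, expected, _, _ = multipletests(p, method="holm-sidak")
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.2, 1.4])


class TestAicc:
    def test_infinite_when_underdetermined(self):
        assert aicc(1.0, n=5, n_params=3) == np.inf  # n - (k+1) - 1 = -1 <= 0

    def test_penalises_extra_parameters(self):
        assert aicc(1.0, n=30, n_params=4) > aicc(1.0, n=30, n_params=2)


class TestForwardSelection:
    def test_exact_signal_selects_matching_vector(self, dataset):
        _, basis = dataset
        y = 2.0 * basis.U[:, 3]
        selected = forward_select_eigenvectors(basis.U, y)
        assert selected[0] == 3
        design = np.column_stack([np.ones(len(y)), basis.U[:, selected]])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        assert resid @ resid == pytest.approx(0.0, abs=1e-20)

    def test_zero_budget(self, dataset):
        _, basis = dataset
        y = basis.U[:, 0] + 0.1
        assert forward_select_eigenvectors(basis.U, y, max_k=0) == []

    def test_first_pick_matches_exhaustive_search(self):
        # brute-force oracle: all single additions on a small instance
        tree = random_tree(21, 8)
        basis = build_pem(influence_matrix(tree))
        rng = np.random.default_rng(0)
        y = basis.U[:, :3] @ np.array([1.0, -0.6, 0.4]) + rng.normal(0, 0.1, 8)
        U = basis.U[:, :3]
        n = len(y)

        def sse(cols):
            design = np.column_stack([np.ones(n)] + [U[:, j] for j in cols])
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            r = y - design @ coef
            return float(r @ r)

        best_single = min(range(3), key=lambda j: (aicc(sse([j]), n, 2), j))
        selected = forward_select_eigenvectors(U, y, max_k=3)
        assert selected[0] == best_single

    def test_r2_nondecreasing_aicc_decreasing_along_path(self, dataset):
        table, basis = dataset
        y = np.log(
            table.set_index("taxon").loc[basis.tip_labels, "RBC_area"].to_numpy()
        )
        selected = forward_select_eigenvectors(basis.U, y)
        n = len(y)
        sst = float(((y - y.mean()) ** 2).sum())
        r2s, crits = [], []
        for size in range(len(selected) + 1):
            design = np.column_stack([np.ones(n), basis.U[:, selected[:size]]])
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            sse = float((y - design @ coef) @ (y - design @ coef))
            r2s.append(1 - sse / sst)
            crits.append(aicc(sse, n, design.shape[1]))
        assert (np.diff(r2s) >= -1e-12).all()
        assert (np.diff(crits) < 0).all()

    def test_r2_criterion_fills_budget(self, dataset):
        table, basis = dataset
        y = np.log(
            table.set_index("taxon").loc[basis.tip_labels, "RBC_area"].to_numpy()
        )
        selected = forward_select_eigenvectors(basis.U, y, max_k=4, criterion="r2")
        assert len(selected) == 4

    def test_unknown_criterion(self, dataset):
        _, basis = dataset
        with pytest.raises(ValueError, match="criterion"):
            forward_select_eigenvectors(basis.U, basis.U[:, 0], criterion="bic")


class TestFitCandidateModel:
    def test_saturated_signal(self, dataset):
        table, basis = dataset
        table = table.copy()
        # make the response an exact function of the co-predictor
        table["RBC_area"] = np.exp(table["lnCan_min"])
        spec = CandidateModel("RBC_area", ("lnCan_min",), use_phylogeny=False)
        fitted = fit_candidate_model(table, basis, spec)
        assert fitted.r2 == pytest.approx(1.0, abs=1e-12)
        assert fitted.p_value < 1e-30

    def test_ols_closed_form_without_phylogeny(self, dataset):
        table, basis = dataset
        spec = CandidateModel("RBC_area", ("lnCan_min",), use_phylogeny=False)
        fitted = fit_candidate_model(table, basis, spec)
        rows = table.set_index("taxon").loc[basis.tip_labels]
        x = rows["lnCan_min"].to_numpy()
        y = np.log(rows["RBC_area"].to_numpy())
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fitted.coef["lnCan_min"] == pytest.approx(slope, rel=1e-10)
        assert fitted.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_too_few_taxa(self):
        config = SimulationConfig(seed=5, n_tips=6, fossil_fraction=0.0)
        tree, table, _ = simulate_dataset(config)
        training = table["taxon"].head(4).tolist()
        basis = build_pem(influence_matrix(tree, training))
        with pytest.raises(FitError, match=">=5"):
            fit_candidate_model(table, basis, CandidateModel("RBC_area", ("lnCan_min",)))

    def test_missing_training_response(self, dataset):
        table, basis = dataset
        broken = table.copy()
        broken.loc[broken["taxon"] == basis.tip_labels[0], "RBC_area"] = np.nan
        with pytest.raises(FitError, match="missing response"):
            fit_candidate_model(broken, basis, CandidateModel("RBC_area", ("lnCan_min",)))

    def test_collinear_design_names_columns(self, dataset):
        table, basis = dataset
        clone = table.copy()
        clone["lnCan_harmean"] = clone["lnCan_min"]  # exact duplicate column
        spec = CandidateModel(
            "RBC_area", ("lnCan_min", "lnCan_harmean"), use_phylogeny=False
        )
        with pytest.raises(FitError, match="lnCan_harmean"):
            fit_candidate_model(clone, basis, spec)

    def test_log_response_off(self, dataset):
        table, basis = dataset
        spec = CandidateModel("RBC_area", ("lnCan_min",), use_phylogeny=False,
                              log_response=False)
        fitted = fit_candidate_model(table, basis, spec)
        assert np.isfinite(fitted.r2)


class TestModelComparison:
    def test_four_rows_matching_grid(self, dataset):
        table, basis = dataset
        out, fits = model_comparison_table(table, basis, "RBC_area")
        assert len(out) == 4
        expected = {m.model_id for m in candidate_model_grid("RBC_area")}
        assert set(out["model"]) == expected
        assert set(fits) <= expected

    def test_best_flag_is_max_r2(self, dataset):
        table, basis = dataset
        out, _ = model_comparison_table(table, basis, "RBC_area")
        assert out.loc[out["best"], "r2"].iloc[0] == out["r2"].max()
        assert out["best"].sum() == 1

    def test_adjusted_at_least_raw(self, dataset):
        table, basis = dataset
        out, _ = model_comparison_table(table, basis, "RBC_area")
        assert (out["p_holm_sidak"] >= out["p_value"] - 1e-15).all()

    def test_deterministic(self, dataset):
        table, basis = dataset
        out1, fits1 = model_comparison_table(table, basis, "RBC_area")
        out2, fits2 = model_comparison_table(table, basis, "RBC_area")
        pd.testing.assert_frame_equal(out1, out2)
        for key in fits1:
            assert fits1[key].selected == fits2[key].selected
            assert fits1[key].coef == fits2[key].coef

    def test_phylogeny_only_not_better_than_augmented(self):
        # with independent co-predictor signal, adding it cannot hurt
        wins = 0
        for seed in range(5):
            config = SimulationConfig(seed=seed + 100, n_tips=20, fossil_fraction=0.2)
            tree, table, _ = simulate_dataset(config)
            training = table.loc[table["status"] == "extant", "taxon"].tolist()
            basis = build_pem(influence_matrix(tree, training))
            out, _ = model_comparison_table(table, basis, "RBC_area")
            r2 = out.set_index("model")["r2"]
            if (r2.drop("phylogeny") >= r2["phylogeny"] - 1e-9).all():
                wins += 1
        assert wins >= 4
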