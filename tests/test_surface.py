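import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import random_design
from nlcopt.doe import DesignMatrix, DesignSpec, Factor, build_ccd
from nlcopt.surface import (MODEL_CLASSES, ResponseSet, SingularDesignError,
                            SurfaceModel, expand_terms, fit_surface,
                            load_models, model_terms, save_models,
                            select_model, sequential_term_ss)
from nlcopt.synthetic import SurfaceTruth, gen_ccd_responses

# coefficients of the published models (actual units), 3-4 significant figures
PUBLISHED_Y1_PQ = (798.9, -1.135, -2.027, 0.00298, 0.001862)
PUBLISHED_Y2_SO = (0.9387, -0.00318, -0.00078, -3.40e-6, 8.14e-6, 1.62e-6)
PUBLISHED_Y3_LIN = (-17.87, 0.01467)


def _response_set(design, values, response="y", sd=0.0, n=1):
    rows = [(rid, response, float(v), sd, n)
            for rid, v in zip(design.runs["run_id"], values)]
    return ResponseSet(pd.DataFrame(rows, columns=list(ResponseSet.REQUIRED)))


class TestExpandTerms:
    @pytest.mark.parametrize("model_class,ncols", [("FO", 3), ("TWI", 4),
                                                   ("PQ", 5), ("SO", 6)])
    def test_term_counts_k2(self, k2_design, model_class, ncols):
        assert expand_terms(k2_design, model_class).shape[1] == ncols

    def test_canonical_column_order(self, k2_design):
        cols = list(expand_terms(k2_design, "SO").columns)
        assert cols == ["intercept", "lipid", "surfactant",
                        "lipid:surfactant", "lipid^2", "surfactant^2"]

    def test_pq_has_no_interaction(self, k2_design):
        assert "lipid:surfactant" not in expand_terms(k2_design, "PQ").columns

    def test_unknown_class_rejected(self, k2_design):
        with pytest.raises(ValueError, match="model class"):
            expand_terms(k2_design, "CUBIC")


class TestPublishedFits:
    def test_particle_size_pure_quadratic_coefficients(self, paper_models):
        """Refitting the pure-quadratic particle-size model on the run means
        recovers the published coefficients within 1% each."""
        got = paper_models["particle_size"].coef_actual
        assert np.allclose(got, PUBLISHED_Y1_PQ, rtol=0.01)

    def test_pdi_second_order_coefficients(self, paper_models):
        got = paper_models["pdi"].coef_actual
        assert np.allclose(got, PUBLISHED_Y2_SO, rtol=0.01)

    def test_zeta_linear_in_surfactant(self, paper_models):
        got = paper_models["zeta_potential"].coef_actual
        assert got == pytest.approx(PUBLISHED_Y3_LIN, rel=0.01)

    def test_predictions_at_reported_optimum(self, paper_models):
        """The refit models evaluated at (268.4, 553.4) mg reproduce the
        reported predicted responses."""
        opt = [268.4, 553.4]
        assert paper_models["particle_size"].predict(opt) == pytest.approx(157.5, rel=0.005)
        assert paper_models["pdi"].predict(opt) == pytest.approx(0.231, rel=0.005)
        assert paper_models["zeta_potential"].predict(opt) == pytest.approx(-9.75, rel=0.005)

    def test_residuals_orthogonal_to_model_columns(self, study, paper_models):
        design, responses = study
        for resp, model in paper_models.items():
            X = np.column_stack([
                np.prod(design.actual()[:, list(t)], axis=1) if t
                else np.ones(design.n_runs) for t in model.terms])
            y = responses.means(resp, design.runs["run_id"])
            r = y - X @ model.coef_actual
            # scale-invariant orthogonality check per column
            assert np.max(np.abs(X.T @ r) / np.linalg.norm(X, axis=0)) < 1e-6


class TestOLSExactness:
    def test_noise_free_so_truth_recovered_exactly(self, k2_design):
        truth = SurfaceTruth(
            "SO", {"y": [50.0, -0.2, 0.1, 1e-3, 4e-4, -2e-4]}, {"y": 0.0})
        rs = gen_ccd_responses(k2_design, truth, seed=0)
        m = fit_surface(k2_design, rs, "y", "SO")
        assert np.allclose(m.coef_actual, truth.coefficients["y"],
                           rtol=1e-9, atol=1e-12)

    def test_normal_equations_oracle_three_terms(self):
        """Independent normal-equations solve matches the factorization path."""
        rng = np.random.default_rng(11)
        dm = random_design(rng)
        y = rng.normal(size=dm.n_runs)
        m = fit_surface(dm, _response_set(dm, y), "y", "FO")
        X = np.column_stack([np.ones(dm.n_runs), dm.coded()])
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(m.coef_coded, beta_ne, atol=1e-10)

    def test_statsmodels_cross_check(self, study):
        """Coefficients and R^2 agree with an independent OLS implementation."""
        import statsmodels.api as sm

        design, responses = study
        m = fit_surface(design, responses, "particle_size", "PQ")
        X = np.column_stack([design.actual(), design.actual() ** 2])
        res = sm.OLS(responses.means("particle_size", design.runs["run_id"]),
                     sm.add_constant(X)).fit()
        assert np.allclose(m.coef_actual, res.params, rtol=1e-8)
        assert m.r_squared == pytest.approx(res.rsquared, abs=1e-10)
        assert m.anova.p_model == pytest.approx(res.f_pvalue, abs=1e-10)

    def test_coded_and_actual_fits_agree_on_random_designs(self):
        """Predictions from the coded-unit and actual-unit parameterizations
        coincide over 100 random designs."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            dm = random_design(rng)
            y = rng.normal(size=dm.n_runs)
            m = fit_surface(dm, _response_set(dm, y), "y", "SO")
            Xa = np.column_stack([
                np.prod(dm.actual()[:, list(t)], axis=1) if t
                else np.ones(dm.n_runs) for t in m.terms])
            Xc = np.column_stack([
                np.prod(dm.coded()[:, list(t)], axis=1) if t
                else np.ones(dm.n_runs) for t in m.terms])
            diff = np.max(np.abs(Xa @ m.coef_actual - Xc @ m.coef_coded))
            assert diff < 1e-8 * max(1.0, np.max(np.abs(y)))


class TestAnova:
    @pytest.mark.parametrize("model_class", MODEL_CLASSES)
    @pytest.mark.parametrize("response", ["particle_size", "pdi", "zeta_potential"])
    def test_partition_identity(self, study, response, model_class):
        """SS(residual) = SS(lack of fit) + SS(pure error), dfs consistent."""
        design, responses = study
        a = fit_surface(design, responses, response, model_class).anova
        assert a.ss("residual") == pytest.approx(
            a.ss("lack_of_fit") + a.ss("pure_error"), rel=1e-8)
        assert a.df("residual") == a.df("lack_of_fit") + a.df("pure_error")
        assert a.df("model") + a.df("residual") == a.df("total")
        assert a.ss("model") + a.ss("residual") == pytest.approx(a.ss("total"), rel=1e-8)

    def test_pure_error_from_center_replicates(self, study):
        design, responses = study
        a = fit_surface(design, responses, "particle_size", "PQ").anova
        y = responses.means("particle_size", design.runs["run_id"])
        centers = y[(design.runs["point_type"] == "center").to_numpy()]
        assert a.df("pure_error") == len(centers) - 1
        assert a.ss("pure_error") == pytest.approx(
            np.sum((centers - centers.mean()) ** 2), rel=1e-12)

    def test_sequential_ss_sums_to_model_ss(self, study):
        design, responses = study
        seq = sequential_term_ss(design, responses, "particle_size", "SO")
        a = fit_surface(design, responses, "particle_size", "SO").anova
        assert seq["seq_ss"].iloc[1:].sum() == pytest.approx(a.ss("model"), rel=1e-8)


class TestSelection:
    def test_single_candidate_returned(self, study):
        design, responses = study
        sel = select_model(design, responses, "particle_size", candidates=["TWI"])
        assert sel.model_class == "TWI"

    def test_study_selection_matches_published_classes(self, study):
        """On the packaged study the rule lands on the published classes for
        particle size (PQ) and PdI (SO); the center-point pure error is small
        enough that lack of fit rejects every candidate, so both carry the
        no-significant-model flag."""
        design, responses = study
        s1 = select_model(design, responses, "particle_size")
        assert s1.model_class == "PQ"
        assert s1.flag == "no significant model"
        s2 = select_model(design, responses, "pdi")
        assert s2.model_class == "SO"

    def test_override_reproduces_published_zeta_model(self, study):
        design, responses = study
        sel = select_model(design, responses, "zeta_potential",
                           override="FO", factor_idx=[1])
        assert sel.flag == "override"
        assert sel.model.coef_actual == pytest.approx(PUBLISHED_Y3_LIN, rel=0.01)

    def test_fo_truth_prefers_fo_over_so(self, k2_design):
        """With first-order truth and tiny noise, the fits tie in adjusted
        R^2 and parsimony tie-breaking picks the true first-order class in
        at least 95% of 200 seeded replicates."""
        truth = SurfaceTruth("FO", {"y": [100.0, 5.0, -3.0]}, {"y": 1e-6})
        wins = 0
        for seed in range(200):
            rs = gen_ccd_responses(k2_design, truth, seed=seed)
            if select_model(k2_design, rs, "y", candidates=["FO", "SO"]).model_class == "FO":
                wins += 1
        assert wins >= 190

    def test_empty_candidates_rejected(self, study):
        design, responses = study
        with pytest.raises(ValueError):
            select_model(design, responses, "pdi", candidates=[])


class TestErrors:
    def test_singular_design_names_collinear_terms(self, factors):
        spec = DesignSpec(factors, n_center=3)
        dm = build_ccd(spec)
        runs = dm.runs.copy()
        runs["surfactant_coded"] = runs["lipid_coded"]
        runs["surfactant_actual"] = 400.0 + 200.0 * runs["surfactant_coded"]
        collinear = DesignMatrix(factors=factors, runs=runs, alpha=dm.alpha)
        y = np.arange(collinear.n_runs, dtype=float)
        with pytest.raises(SingularDesignError, match="surfactant"):
            fit_surface(collinear, _response_set(collinear, y), "y", "SO")

    def test_too_few_runs_rejected(self, factors):
        dm = build_ccd(DesignSpec(factors, n_center=1))
        small = DesignMatrix(factors=factors, runs=dm.runs.iloc[:4].copy(),
                             alpha=dm.alpha)
        with pytest.raises(ValueError, match="runs"):
            fit_surface(small, _response_set(small, np.ones(4)), "y", "SO")

    def test_extrapolation_warns(self, paper_models):
        m = paper_models["particle_size"]
        with pytest.warns(UserWarning, match="extrapolates"):
            m.predict([600.0, 400.0])
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            m.predict([300.0, 400.0])  # inside the region: no warning


def test_model_json_round_trip(tmp_path, paper_models):
    path = tmp_path / "models.json"
    models = list(paper_models.values())
    save_models(models, path)
    back = load_models(path)
    for orig, re in zip(models, back):
        assert re.response == orig.response
        assert re.terms == orig.terms
        assert np.allclose(re.coef_actual, orig.coef_actual, rtol=1e-15)
        assert re.anova.p_model == pytest.approx(orig.anova.p_model, abs=1e-15)
        assert re.predict([268.4, 553.4]) == pytest.approx(
            orig.predict([268.4, 553.4]), rel=1e-15)


def test_intercept_only_prediction_is_intercept(k2_design):
    y = np.full(k2_design.n_runs, 7.5)
    m = fit_surface(k2_design, _response_set(k2_design, y), "y", "FO")
    assert m.predict([300.0, 400.0]) == pytest.approx(7.5, abs=1e-9)
    assert m.coef_actual[1:] == pytest.approx([0.0, 0.0], abs=1e-12)
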