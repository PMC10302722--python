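"""Quadratic response surfaces: terms, fit, Q2, refinement, prediction."""

import numpy as np
import pytest

from aqbd import datasets
from aqbd.design import DesignMatrix, Factor, ccd
from aqbd.rsm import (
    ExtrapolationWarning,
    QuadraticSurface,
    build_columns,
    make_panels,
    quadratic_terms,
    sweet_spot,
    term_definitions,
)


class TestTermConstruction:
    def test_five_factor_inventory(self, table3):
        design, _ = table3
        X, names = quadratic_terms(design)
        assert X.shape == (29, 21)
        assert names[0] == "intercept"
        assert sum("^2" in n for n in names) == 5
        assert sum("*" in n for n in names) == 10

    def test_single_factor(self):
        dm = DesignMatrix(np.array([[-1.0], [0.0], [1.0]]),
                          [Factor("x", 0, 1)])
        X, names = quadratic_terms(dm)
        assert names == ["intercept", "x", "x^2"]

    def test_center_run_row(self, table3):
        design, _ = table3
        X, _ = quadratic_terms(design)
        center = X[28]  # a pure center point
        assert center[0] == 1.0
        assert np.allclose(center[1:], 0.0)


class TestFit:
    def test_missing_runs_excluded_for_log_efficiency(self, table3):
        design, responses = table3
        res = QuadraticSurface(responses["N_I2"].to_numpy(), design,
                               transform="log10").fit()
        assert res.n_used == 26

    def test_log_transform_requires_positive(self, table3):
        design, _ = table3
        y = np.ones(29)
        y[5] = -2.0
        with pytest.raises(ValueError, match="positive"):
            QuadraticSurface(y, design, transform="log10")

    def test_noise_free_coefficients_recovered(self, table3):
        design, _ = table3
        rng = np.random.default_rng(11)
        beta = rng.normal(0, 1, 21)
        X, _ = quadratic_terms(design)
        res = QuadraticSurface(X @ beta, design).fit()
        assert np.allclose(res.params, beta, atol=1e-8)

    def test_rsquared_matches_statsmodels(self, table3):
        import statsmodels.api as sm

        design, responses = table3
        y = responses["t"].to_numpy()
        X, _ = quadratic_terms(design)
        res = QuadraticSurface(y, design).fit()
        ols = sm.OLS(y, X).fit()
        assert res.rsquared == pytest.approx(ols.rsquared, abs=1e-10)
        assert np.allclose(res.params, ols.params, atol=1e-8)

    def test_too_few_runs_raises(self):
        fs = [Factor(f"x{i}", 0, 1) for i in range(5)]
        dm = ccd(fs, fraction="half", n_center=3)
        y = np.full(29, np.nan)
        y[:10] = 1.0
        with pytest.raises(ValueError, match="usable runs"):
            QuadraticSurface(y, dm).fit()


class TestQ2:
    def test_loo_identity_matches_explicit_refits(self, table3):
        """PRESS via e_i/(1-h_ii) equals 29 explicit leave-one-out refits."""
        design, responses = table3
        y = responses["t"].to_numpy()
        X, _ = quadratic_terms(design)
        res = QuadraticSurface(y, design).fit()
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            press += (y[i] - X[i] @ beta) ** 2
        q2_oracle = 1 - press / np.sum((y - y.mean()) ** 2)
        assert res.q2 == pytest.approx(q2_oracle, abs=1e-10)

    def test_q2_never_exceeds_r2(self, table3, refined_models):
        design, responses = table3
        for name in datasets.RESPONSES:
            tr = "log10" if name == "N_I2" else None
            full = QuadraticSurface(responses[name].to_numpy(), design,
                                    transform=tr).fit()
            assert full.q2 <= full.rsquared + 1e-12
            assert refined_models[name].q2 <= refined_models[name].rsquared

    def test_noise_free_fit_gives_q2_of_one(self, table3):
        design, _ = table3
        X, _ = quadratic_terms(design)
        beta = np.zeros(21)
        beta[[0, 1, 7]] = [2.0, 0.5, -0.3]
        res = QuadraticSurface(X @ beta, design).fit(
            terms=[0, 1, 7]
        )
        assert res.q2 == pytest.approx(1.0, abs=1e-9)

    def test_self_predicting_run_raises(self):
        # saturated fit: every h_ii = 1, leave-one-out is undefined
        dm = DesignMatrix(np.array([[-1.0], [0.0], [1.0]]),
                          [Factor("x", 0, 1)])
        res = QuadraticSurface(np.array([1.0, 2.0, 1.5]), dm).fit()
        with pytest.raises(ValueError, match="self-predicting"):
            res.press


class TestRefinement:
    def test_refined_quality_on_study_data(self, refined_models, table3):
        design, responses = table3
        for name, res in refined_models.items():
            tr = "log10" if name == "N_I2" else None
            full = QuadraticSurface(responses[name].to_numpy(), design,
                                    transform=tr).fit()
            # the stopping rule guarantees monotone Q2 improvement
            assert res.q2 >= full.q2
            # dropping terms can only lower R2
            assert res.rsquared <= full.rsquared + 1e-12

    def test_all_significant_model_unchanged(self, table3):
        design, _ = table3
        X, _ = quadratic_terms(design)
        rng = np.random.default_rng(5)
        beta = np.zeros(21)
        beta[:6] = [3, 2, -2, 1.5, 1, -1]  # strong linear truth
        y = X @ beta + rng.normal(0, 0.01, 29)
        res = QuadraticSurface(y, design).fit(terms=list(range(6)))
        refined = res.refine()
        assert refined.term_idx == res.term_idx

    def test_refinement_invariant_to_run_order(self, table3):
        design, responses = table3
        y = responses["R2"].to_numpy()
        rng = np.random.default_rng(1)
        perm = rng.permutation(29)
        shuffled = DesignMatrix(design.coded[perm], design.factors,
                                design_kind="ccd")
        a = QuadraticSurface(y, design).fit().refine()
        b = QuadraticSurface(y[perm], shuffled).fit().refine()
        assert a.term_names == b.term_names
        assert np.allclose(a.params, b.params, atol=1e-9)


class TestPredict:
    def test_center_prediction_matches_center_runs(self, table3):
        design, responses = table3
        y = responses["t"].to_numpy()
        res = QuadraticSurface(y, design).fit()
        pred = res.predict(np.zeros((1, 5)))[0]
        # the three replicated center runs share one fitted value: beta_0
        fitted = res._fit.fitted
        assert fitted[26] == pytest.approx(fitted[27], abs=1e-10)
        assert fitted[27] == pytest.approx(fitted[28], abs=1e-10)
        assert pred == pytest.approx(res.params[0], abs=1e-10)
        # and it tracks the center-run mean closely on the study data
        assert pred == pytest.approx(y[26:29].mean(), rel=0.01)

    def test_log_back_transform(self, table3):
        design, responses = table3
        res = QuadraticSurface(responses["N_I2"].to_numpy(), design,
                               transform="log10").fit()
        x = np.zeros((1, 5))
        mean = res.predict(x)[0]
        X = build_columns(x, res.terms)
        assert mean == pytest.approx(10.0 ** float((X @ res.params)[0]))

    def test_prediction_variance_oracle(self, table3):
        design, responses = table3
        y = responses["R5"].to_numpy()
        res = QuadraticSurface(y, design).fit()
        pt = design.coded[[3]]
        _, sd = res.predict(pt, with_sd=True)
        X, _ = quadratic_terms(design)
        s2 = res.residual_sd**2
        x = X[3]
        var_oracle = x @ np.linalg.inv(X.T @ X) @ x * s2 + s2
        assert sd[0] ** 2 == pytest.approx(var_oracle, rel=1e-8)

    def test_extrapolation_warns(self, table3):
        design, responses = table3
        res = QuadraticSurface(responses["t"].to_numpy(), design).fit()
        with pytest.warns(ExtrapolationWarning):
            res.predict(np.full((1, 5), 2.5))


class TestSweetSpot:
    def test_counts_match_brute_force(self, refined_models, study_config):
        grid = make_panels(study_config.factors, "pH", "CyD conc",
                           ("V", [0.0]), ("Buffer conc", [0.0]),
                           fixed={"BuOH conc": 0.0}, n=11)
        sw = sweet_spot(refined_models, study_config.specs, grid)
        pts = grid.panels[(0.0, 0.0)]
        counts = np.zeros(len(pts), dtype=int)
        for spec in study_config.specs:
            mean = refined_models[spec.response].predict(pts)
            ok = (mean >= spec.threshold if spec.direction == "ge"
                  else mean <= spec.threshold)
            counts += ok.astype(int)
        assert np.array_equal(sw.counts[(0.0, 0.0)].ravel(), counts)

    def test_full_pass_nodes_meet_every_spec(self, refined_models,
                                             study_config):
        grid = make_panels(study_config.factors, "pH", "CyD conc",
                           ("V", [0.0]), ("Buffer conc", [0.0]),
                           fixed={"BuOH conc": 0.0}, n=11)
        sw = sweet_spot(refined_models, study_config.specs, grid)
        key = (0.0, 0.0)
        full = sw.counts[key] == len(study_config.specs)
        pts = grid.panels[key]
        for spec in study_config.specs:
            mean = refined_models[spec.response].predict(pts).reshape(
                grid.shape
            )
            ok = (mean >= spec.threshold if spec.direction == "ge"
                  else mean <= spec.threshold)
            assert np.all(ok[full])
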