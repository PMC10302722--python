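"""Monte Carlo design-space mapping: probabilities, maps, box extraction."""

import numpy as np
import pytest

from aqbd.modr import (
    CMASpec,
    MODRConfig,
    extract_modr_box,
    joint_pass_probability,
    node_seed,
    probability_map,
    verify_edges,
)
from aqbd.rsm import QuadraticSurface, make_panels, quadratic_terms


@pytest.fixture(scope="module")
def degenerate_models(table3):
    """Noise-free fits: zero residual sd and zero covariance, means known."""
    design, _ = table3
    X, _ = quadratic_terms(design)
    out = {}
    for name, const in (("A", 5.0), ("B", 2.0)):
        beta = np.zeros(21)
        beta[0] = const
        beta[1] = 0.1
        out[name] = QuadraticSurface(X @ beta, design).fit(
            terms=list(range(6))
        )
    return out


@pytest.fixture(scope="module")
def noisy_model(table3):
    design, responses = table3
    return QuadraticSurface(responses["R5"].to_numpy(), design).fit().refine()


class TestJointPassProbability:
    def test_degenerate_passing_models_give_certainty(self, degenerate_models):
        specs = [CMASpec("A", "ge", 1.0), CMASpec("B", "le", 10.0)]
        p = joint_pass_probability(degenerate_models, specs,
                                   np.zeros(5), n_sims=2000, seed=1)
        assert p == 100.0

    def test_mean_at_threshold_is_a_coin_flip(self, noisy_model):
        point = np.zeros(5)
        mean = float(noisy_model.predict(point[None, :])[0])
        specs = [CMASpec("R5", "ge", mean)]
        p = joint_pass_probability({"R5": noisy_model}, specs, point,
                                   n_sims=20_000, seed=4)
        assert p == pytest.approx(50.0, abs=1.5)

    def test_seed_reproducibility(self, refined_models, study_config):
        wp = study_config.working_point_coded()
        a = joint_pass_probability(refined_models, study_config.specs, wp,
                                   n_sims=3000, seed=99)
        b = joint_pass_probability(refined_models, study_config.specs, wp,
                                   n_sims=3000, seed=99)
        assert a == b

    def test_binomial_scatter_across_seeds(self, refined_models,
                                           study_config):
        wp = study_config.working_point_coded()
        n_sims = 2000
        reps = np.array([
            joint_pass_probability(refined_models, study_config.specs, wp,
                                   n_sims=n_sims, seed=s)
            for s in range(20)
        ])
        p = reps.mean() / 100.0
        se = 100.0 * np.sqrt(p * (1 - p) / n_sims)
        assert reps.std(ddof=1) < 3 * se

    def test_inflating_residual_noise_cannot_help(self, table3):
        """Doubling residual scatter (same coefficients) never raises the
        joint pass probability."""
        design, responses = table3
        y = responses["R5"].to_numpy()
        base = QuadraticSurface(y, design).fit()
        fitted = base._fit.fitted
        inflated = QuadraticSurface(
            fitted + 2 * (y - fitted), design
        ).fit()
        assert np.allclose(inflated.params, base.params, atol=1e-8)
        assert inflated.residual_sd == pytest.approx(2 * base.residual_sd)
        spec = [CMASpec("R5", "ge", 1.5)]
        rng = np.random.default_rng(12)
        pts = rng.uniform(-1, 1, size=(20, 5))
        for i, pt in enumerate(pts):
            pa = joint_pass_probability({"R5": base}, spec, pt,
                                        n_sims=4000, seed=100 + i)
            pb = joint_pass_probability({"R5": inflated}, spec, pt,
                                        n_sims=4000, seed=100 + i)
            assert pb <= pa + 2.5  # MC slack at 4000 draws

    def test_relaxing_threshold_monotone_under_shared_seed(self, noisy_model):
        """With identical draws, loosening a spec can only add passes."""
        point = np.zeros(5)
        mean = float(noisy_model.predict(point[None, :])[0])
        probs = [
            joint_pass_probability(
                {"R5": noisy_model}, [CMASpec("R5", "ge", thr)], point,
                n_sims=4000, seed=7,
            )
            for thr in np.linspace(mean + 1.0, mean - 1.0, 9)
        ]
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_missing_model_raises(self, noisy_model):
        with pytest.raises(KeyError):
            joint_pass_probability({"R5": noisy_model},
                                   [CMASpec("R2", "ge", 1.5)],
                                   np.zeros(5), n_sims=1000, seed=0)


class TestProbabilityMap:
    def test_degenerate_models_give_zero_risk(self, degenerate_models,
                                              study_config):
        specs = [CMASpec("A", "ge", 1.0), CMASpec("B", "le", 10.0)]
        grid = make_panels(study_config.factors, "pH", "CyD conc",
                           ("V", [0.0]), ("Buffer conc", [0.0]),
                           fixed={"BuOH conc": 0.0}, n=5)
        pm = probability_map(degenerate_models, specs, grid,
                             MODRConfig(n_sims=1000, seed=3))
        risk = pm.risk[(0.0, 0.0)]
        assert np.all(risk == 0.0)
        assert np.all(pm.in_modr[(0.0, 0.0)])

    def test_node_risk_reproducible_via_node_seed(self, refined_models,
                                                  study_config):
        grid = make_panels(study_config.factors, "pH", "CyD conc",
                           ("V", [0.0]), ("Buffer conc", [0.0]),
                           fixed={"BuOH conc": 0.0}, n=4)
        cfg = MODRConfig(n_sims=1500, seed=21)
        pm = probability_map(refined_models, study_config.specs, grid, cfg)
        key = (0.0, 0.0)
        for idx in (0, 7, 15):
            pt = grid.panels[key][idx]
            jp = joint_pass_probability(
                refined_models, study_config.specs, pt,
                n_sims=1500, seed=node_seed(21, idx),
            )
            assert pm.risk[key].ravel()[idx] == pytest.approx(100.0 - jp,
                                                              abs=1e-9)

    def test_dpmo_risk_equivalence(self, refined_models, study_config):
        grid = make_panels(study_config.factors, "pH", "CyD conc",
                           ("V", [0.0]), ("Buffer conc", [0.0]),
                           fixed={"BuOH conc": 0.0}, n=4)
        pm = probability_map(refined_models, study_config.specs, grid,
                             MODRConfig(n_sims=1500, seed=5))
        key = (0.0, 0.0)
        assert np.allclose(pm.dpmo[key], pm.risk[key] * 1e4)
        assert np.array_equal(pm.in_modr[key], pm.dpmo[key] <= 1e5)


class TestBoxExtraction:
    def test_degenerate_models_fill_the_domain(self, degenerate_models,
                                               study_config):
        specs = [CMASpec("A", "ge", 1.0), CMASpec("B", "le", 10.0)]
        cfg = MODRConfig(n_sims=1000, seed=9)
        box = extract_modr_box(degenerate_models, specs,
                               np.zeros(5), cfg)
        # always-passing models: box = the coded factor domain
        for j, f in enumerate(degenerate_models["A"].model.design.factors):
            lo, hi = f.coded_domain(default=1.664)
            assert box.lo[j] == pytest.approx(lo, abs=1e-9)
            assert box.hi[j] == pytest.approx(hi, abs=1e-9)

    def test_noncompliant_working_point_rejected(self, refined_models,
                                                 study_config):
        bad = np.array([1.6, 1.6, -1.6, -1.6, 1.6])
        with pytest.raises(ValueError, match="outside MODR"):
            extract_modr_box(refined_models, study_config.specs, bad,
                             MODRConfig(n_sims=1000, seed=2))

    def test_box_vertices_pass_with_independent_seed(self, refined_models,
                                                     study_config):
        """Dense-MC vertex oracle: every vertex of the returned box stays
        compliant when re-checked with fresh draws (binomial margin)."""
        cfg = MODRConfig(n_sims=4000, seed=17)
        wp = study_config.working_point_coded()
        box = extract_modr_box(refined_models, study_config.specs, wp, cfg)
        target = cfg.target_pass_percent
        assert box.min_vertex_pass >= target
        for vtx in box.vertices():
            p = joint_pass_probability(refined_models, study_config.specs,
                                       vtx, n_sims=10_000, seed=4242)
            # extraction stops exactly at the target, so an independent
            # re-check fluctuates around it by the combined binomial error
            assert p >= target - 1.5

    def test_working_point_inside_box_inside_domain(self, refined_models,
                                                    study_config):
        cfg = MODRConfig(n_sims=2000, seed=31)
        wp = study_config.working_point_coded()
        box = extract_modr_box(refined_models, study_config.specs, wp, cfg)
        assert np.all(box.lo <= wp) and np.all(wp <= box.hi)
        for j, f in enumerate(study_config.factors):
            lo, hi = f.coded_domain()
            assert lo - 1e-9 <= box.lo[j] and box.hi[j] <= hi + 1e-9


class TestVerifyEdges:
    def test_vertex_means_match_predict(self, refined_models, study_config):
        cfg = MODRConfig(n_sims=2000, seed=31)
        wp = study_config.working_point_coded()
        box = extract_modr_box(refined_models, study_config.specs, wp, cfg)
        tab = verify_edges(refined_models, study_config.specs, box)
        assert len(tab) == len(box.vertices())
        for i, vtx in enumerate(box.vertices()):
            for spec in study_config.specs:
                mean = float(
                    refined_models[spec.response].predict(vtx[None, :])[0]
                )
                assert tab.iloc[i][f"pred_{spec.response}"] == pytest.approx(
                    mean
                )
        assert tab["all_pass"].all()

    def test_collapsed_box_reduces_to_working_point(self, refined_models,
                                                    study_config):
        from aqbd.modr import MODRBox

        wp = study_config.working_point_coded()
        box = MODRBox(study_config.factors, wp, wp.copy(), wp.copy(), 100.0)
        tab = verify_edges(refined_models, study_config.specs, box)
        assert len(tab) == 1
        mean = float(refined_models["t"].predict(wp[None, :])[0])
        assert tab.iloc[0]["pred_t"] == pytest.approx(mean)


class TestSpecAndConfigValidation:
    def test_bad_direction(self):
        with pytest.raises(ValueError):
            CMASpec("R2", "gt", 1.5)

    def test_config_bounds(self):
        with pytest.raises(ValueError):
            MODRConfig(n_sims=10)
        with pytest.raises(ValueError):
            MODRConfig(dpmo_target=2e6)

    def test_target_pass_percent(self):
        assert MODRConfig().target_pass_percent == pytest.approx(90.0)
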