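"""Mediational g-formula: component fits, decompositions, oracle, bootstrap."""

import numpy as np
import pytest

import longmed as lm
from longmed.gformula import (
    AnalysisError,
    ExposureContrast,
    GFormulaSpec,
    MediationDecomposition,
    bootstrap_decomposition,
    decompose_cpts,
    decompose_pathspecific,
    decompose_twoway,
    enumerate_oracle,
    fit_component_models,
)
from longmed.synthetic_cohort import (
    ToyCPTs,
    random_toy_cpts,
    simulate_linear_toy,
    simulate_toy_discrete,
)
from tests.conftest import BASE_SEED


def _const(v):
    return lambda t: v + 0.0 * np.asarray(t, dtype=float)


ON, OFF = np.array([0.0, 1.0]), np.array([1.0, 0.0])


class TestFitComponentModels:
    def test_deterministic(self, small_panel):
        spec = GFormulaSpec(seed=BASE_SEED)
        m1 = fit_component_models(small_panel, spec)
        m2 = fit_component_models(small_panel, spec)
        for key in m1.models:
            assert np.array_equal(m1.models[key].coef, m2.models[key].coef)

    def test_saturated_cell_means_match_cpts(self):
        cpts = random_toy_cpts(seed=21, n_visits=2)
        panel, _ = simulate_toy_discrete(40_000, cpts, seed=7)
        spec = GFormulaSpec(model_form="saturated", contrast=ExposureContrast(1, 0))
        models = fit_component_models(panel, spec)
        m = models.models[("gds15", 0)]  # M1_0 | X_0
        for x in (0, 1):
            p_true = cpts.pm1[0][x, 1]
            p_hat = m.table[(x,)]
            n_cell = 40_000 * cpts.px[0][x]
            assert abs(p_hat - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n_cell)

    def test_constant_mediator_flagged_degenerate(self, small_panel):
        df = small_panel.df.copy()
        df["moca"] = 25
        models = fit_component_models(
            lm.CohortPanel(df), GFormulaSpec(seed=BASE_SEED)
        )
        assert any(var == "moca" for var, _ in models.degenerate_models)

    def test_identical_regimes_rejected(self):
        with pytest.raises(ValueError):
            ExposureContrast(3.0, 3.0).resolve(9)


class TestLinearGaussianClosedForm:
    def test_single_visit_paths_recovered(self):
        # a=0.5, b=0.4, c=0.3, unit contrast: TE=0.50, DE=0.30, IE=0.20
        panel = simulate_linear_toy(20_000, a=0.5, b=0.4, c=0.3,
                                    noise_sd=0.1, seed=BASE_SEED)
        spec = GFormulaSpec(
            mediators=("gds15",), contrast=ExposureContrast(7.0, 6.0),
            n_mc=40_000, seed=BASE_SEED,
        )
        models = fit_component_models(panel, spec)
        tw = decompose_twoway(models)
        ps = decompose_pathspecific(models)
        assert tw.te == pytest.approx(0.50, abs=0.02)
        assert tw.de == pytest.approx(0.30, abs=0.02)
        assert tw.ie_joint == pytest.approx(0.20, abs=0.02)
        assert ps.per_mediator["gds15"] == pytest.approx(0.20, abs=0.02)
        assert abs(ps.interaction_remainder) < 0.01

    def test_two_independent_mediators_partition_and_order_invariance(self):
        # conditionally independent mediators: contributions are the path
        # products and do not depend on the declared order
        cfg = lm.DGPConfig(
            n_subjects=3000, n_visits=2, seed=BASE_SEED,
            alpha_fns={"gds15": _const(0.5), "moca": _const(0.25)},
            beta_fns={"gds15": _const(0.4), "moca": _const(0.4)},
            tau_fn=_const(0.3),
            noise_sd={"gds15": 0.5, "moca": 0.5, "updrs2": 0.5},
            random_effect_sd={"gds15": 0.2, "moca": 0.2, "updrs2": 0.2},
            clipping=False,
        )
        panel = lm.simulate_cohort(cfg)
        contrast = ExposureContrast(6.0, 5.0)  # unit sustained contrast
        spec = GFormulaSpec(contrast=contrast, n_mc=40_000, seed=BASE_SEED)
        ps = decompose_pathspecific(fit_component_models(panel, spec))
        # per-visit structure: unit X shift moves final M1 by 0.5 -> Y by .2
        assert ps.per_mediator["gds15"] == pytest.approx(0.20, abs=0.03)
        assert ps.per_mediator["moca"] == pytest.approx(0.10, abs=0.03)
        rev = spec.with_(mediators=("moca", "gds15"))
        ps_rev = decompose_pathspecific(fit_component_models(panel, rev))
        for m in ("gds15", "moca"):
            assert ps_rev.per_mediator[m] == pytest.approx(
                ps.per_mediator[m], abs=0.03
            )

    def test_zero_path_mediator_contributes_nothing(self):
        cfg = lm.DGPConfig(
            n_subjects=2000, n_visits=2, seed=BASE_SEED + 1,
            alpha_fns={"gds15": _const(0.5), "moca": _const(0.0)},
            beta_fns={"gds15": _const(0.4), "moca": _const(0.0)},
            tau_fn=_const(0.3),
            noise_sd={"gds15": 0.5, "moca": 0.5, "updrs2": 0.5},
            random_effect_sd={"gds15": 0.2, "moca": 0.2, "updrs2": 0.2},
            clipping=False,
        )
        panel = lm.simulate_cohort(cfg)
        spec = GFormulaSpec(contrast=ExposureContrast(6.0, 5.0),
                            n_mc=40_000, seed=BASE_SEED)
        ps = decompose_pathspecific(fit_component_models(panel, spec))
        assert abs(ps.per_mediator["moca"]) < 0.02


class TestAdditivity:
    def test_exact_closure_on_synthetic_cohort(self, default_panel):
        spec = GFormulaSpec(n_mc=4000, seed=BASE_SEED)
        models = fit_component_models(default_panel, spec)
        tw = decompose_twoway(models)
        ps = decompose_pathspecific(models)
        assert tw.te == tw.de + tw.ie_joint + tw.xi  # exact by construction
        assert ps.ie_joint == pytest.approx(
            sum(ps.per_mediator.values()) + ps.interaction_remainder, abs=1e-14
        )

    def test_zero_total_effect_shares_undefined(self):
        d = MediationDecomposition(te=0.0, de=0.0, ie_joint=0.0, xi=0.0, mc_se={})
        shares = d.shares()
        assert np.isnan(shares["de"]) and np.isnan(shares["ie_joint"])


class TestEnumerateOracle:
    def test_deterministic_chain_fully_mediated(self):
        # X flips M1, M1 flips Y, M2 inert: TE = IE via M1 = 1, DE = 0
        cpts = ToyCPTs(
            px=(np.array([0.5, 0.5]),),
            pm1=(np.stack([OFF, ON]),),
            pm2=(np.stack([[OFF, OFF], [OFF, OFF]]),),
            py=np.stack([[[OFF, OFF], [ON, ON]], [[OFF, OFF], [ON, ON]]]),
        )
        tw, ps = enumerate_oracle(cpts, GFormulaSpec())
        assert tw.te == pytest.approx(1.0)
        assert tw.de == pytest.approx(0.0)
        assert tw.ie_joint == pytest.approx(1.0)
        assert tw.xi == 0.0
        assert ps.per_mediator["gds15"] == pytest.approx(1.0)
        assert ps.per_mediator["moca"] == pytest.approx(0.0)

    def test_exposure_independent_system_has_no_effects(self):
        half = np.array([0.5, 0.5])
        cpts = ToyCPTs(
            px=(half,),
            pm1=(np.stack([half, half]),),
            pm2=(np.full((2, 2, 2), 0.5),),
            py=np.full((2, 2, 2, 2), 0.5),
        )
        tw, ps = enumerate_oracle(cpts, GFormulaSpec())
        for v in (tw.te, tw.de, tw.ie_joint, *ps.per_mediator.values()):
            assert v == pytest.approx(0.0)

    @pytest.mark.parametrize("n_mc", [1_000, 10_000, 100_000])
    def test_monte_carlo_converges_to_enumeration(self, n_mc):
        cpts = random_toy_cpts(seed=13, n_visits=2)
        spec = GFormulaSpec(seed=BASE_SEED)
        otw, ops = enumerate_oracle(cpts, spec)
        mtw, mps = decompose_cpts(cpts, spec, n_mc=n_mc)
        for key in ("te", "de", "ie_joint"):
            err = abs(getattr(otw, key) - getattr(mtw, key))
            assert err < max(4 * mtw.mc_se[key], 4 / np.sqrt(n_mc))
        for m in ("gds15", "moca"):
            err = abs(ops.per_mediator[m] - mps.per_mediator[m])
            assert err < max(4 * mps.mc_se[m], 4 / np.sqrt(n_mc))

    def test_fitted_saturated_models_agree_with_oracle(self):
        cpts = random_toy_cpts(seed=17, n_visits=2)
        panel, _ = simulate_toy_discrete(40_000, cpts, seed=3)
        spec = GFormulaSpec(model_form="saturated",
                            contrast=ExposureContrast(1, 0),
                            n_mc=100_000, seed=BASE_SEED)
        tw = decompose_twoway(fit_component_models(panel, spec))
        otw, _ = enumerate_oracle(cpts, spec)
        # tolerance covers cell-mean sampling error at n=40k plus MC error
        for key in ("te", "de", "ie_joint"):
            assert getattr(tw, key) == pytest.approx(getattr(otw, key), abs=0.02)


class TestBootstrap:
    def test_smoke_run_yields_ordered_intervals(self, small_panel):
        spec = GFormulaSpec(n_mc=2000, n_boot=2, seed=BASE_SEED)
        res = bootstrap_decomposition(small_panel, spec)
        for lo, hi in {**res.twoway.ci, **res.pathspecific.ci}.values():
            assert lo <= hi
        assert res.n_boot_done == 2

    def test_same_seed_identical_intervals(self, small_panel):
        spec = GFormulaSpec(n_mc=2000, n_boot=3, seed=BASE_SEED)
        r1 = bootstrap_decomposition(small_panel, spec)
        r2 = bootstrap_decomposition(small_panel, spec)
        assert r1.twoway.ci == r2.twoway.ci
        assert r1.pathspecific.ci == r2.pathspecific.ci

    def test_null_mediation_interval_contains_zero(self):
        cfg = lm.DGPConfig(
            n_subjects=150, seed=BASE_SEED + 5,
            alpha_fns={"gds15": _const(0.0), "moca": _const(0.0)},
        )
        panel = lm.simulate_cohort(cfg)
        spec = GFormulaSpec(n_mc=3000, n_boot=30, seed=BASE_SEED)
        res = bootstrap_decomposition(panel, spec)
        lo, hi = res.twoway.ci["ie_joint"]
        assert lo <= 0 <= hi

    def test_decomposition_frame_layout(self, small_panel):
        spec = GFormulaSpec(n_mc=2000, n_boot=2, seed=BASE_SEED)
        frame = bootstrap_decomposition(small_panel, spec).to_frame()
        assert list(frame["component"][:4]) == [
            "total_effect", "direct_effect", "indirect_effect_joint", "xi_residual",
        ]
        assert {"indirect_via_gds15", "indirect_via_moca"} <= set(frame["component"])


class TestSpecValidation:
    def test_no_mediators_rejected(self):
        with pytest.raises(ValueError):
            GFormulaSpec(mediators=()).validate()

    def test_unknown_model_form_rejected(self):
        with pytest.raises(ValueError):
            GFormulaSpec(model_form="quadratic").validate()
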