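"""Single-mediator Bayesian dynamic mediation: sampler, IE curve, diagnostics."""

import warnings

import numpy as np
import pytest

import longmed as lm
from longmed.dynamic_mediation import (
    BasisSpec,
    DynMedSpec,
    FitError,
    PosteriorDraws,
    curve_frame,
    diagnose,
    fit_dynamic_mediation,
    indirect_effect_curve,
)
from tests.conftest import BASE_SEED


def _const(v):
    return lambda t: v + 0.0 * np.asarray(t, dtype=float)


QUICK = dict(n_iter=800, n_warmup=300, n_chains=2)


def _fit(panel, **kw):
    spec = DynMedSpec(**{**QUICK, "seed": BASE_SEED, **kw})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_dynamic_mediation(panel, spec)


class TestBasis:
    def test_bspline_partition_of_unity(self):
        t = np.linspace(0, 1, 33)
        B = BasisSpec("bspline", 5).matrix(t)
        assert B.shape == (33, 5)
        assert np.allclose(B.sum(axis=1), 1.0)
        assert np.all(B >= 0)

    def test_linear_basis(self):
        B = BasisSpec("linear").matrix(np.array([0.0, 0.5, 1.0]))
        assert np.allclose(B, [[1, 0], [1, 0.5], [1, 1]])

    def test_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            BasisSpec().matrix(np.array([-0.1]))


class TestFit:
    def test_same_seed_identical_draws(self, small_panel):
        d1 = _fit(small_panel, n_iter=200, n_warmup=50)
        d2 = _fit(small_panel, n_iter=200, n_warmup=50)
        for k in d1.params:
            assert np.array_equal(d1.params[k], d2.params[k])

    def test_retained_draw_count(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        assert d.params["sigma_m"].shape == (2, 150)
        assert d.n_draws == 300

    def test_row_order_invariance(self, small_panel):
        shuffled = lm.CohortPanel(
            small_panel.df.sample(frac=1.0, random_state=0).reset_index(drop=True),
            n_visits=small_panel.n_visits,
        )
        s1 = indirect_effect_curve(_fit(small_panel, n_iter=200, n_warmup=50), [0.5])
        s2 = indirect_effect_curve(_fit(shuffled, n_iter=200, n_warmup=50), [0.5])
        assert s1[0].ie_mean == pytest.approx(s2[0].ie_mean, rel=1e-12)

    def test_constant_exposure_rejected(self, small_panel):
        df = small_panel.df.copy()
        df["rbdsq"] = 5
        with pytest.raises(FitError, match="exposure"):
            _fit(lm.CohortPanel(df))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DynMedSpec(n_iter=100, n_warmup=100).validate()
        with pytest.raises(ValueError):
            DynMedSpec(n_chains=1).validate()

    def test_null_path_posterior_covers_zero(self):
        cfg = lm.DGPConfig(
            n_subjects=150, seed=BASE_SEED,
            alpha_fns={"gds15": _const(0.0),
                       "moca": lm.DGPConfig().alpha_fns["moca"]},
        )
        draws = _fit(lm.simulate_cohort(cfg), mediator="gds15")
        for s in indirect_effect_curve(draws, [0.25, 0.5, 0.75]):
            assert s.ci_low <= 0 <= s.ci_high

    def test_constant_paths_recovered_and_match_per_visit_ols(self):
        # truth IE = 0.5 * 0.4 = 0.20 at every t; cross-checked against the
        # independent per-visit product-of-coefficients estimate
        cfg = lm.DGPConfig(
            n_subjects=500, seed=BASE_SEED + 3,
            alpha_fns={"gds15": _const(0.5), "moca": _const(0.0)},
            beta_fns={"gds15": _const(0.4), "moca": _const(0.0)},
            tau_fn=_const(0.0),
            covariate_effects={},  # keeps the simple OLS oracle unconfounded
            noise_sd={"gds15": 0.5, "moca": 0.5, "updrs2": 0.5},
            random_effect_sd={"gds15": 0.3, "moca": 0.3, "updrs2": 0.3},
            clipping=False,
        )
        panel = lm.simulate_cohort(cfg)
        draws = _fit(panel, mediator="gds15")
        summaries = indirect_effect_curve(draws, [0.25, 0.5, 0.75], scale="raw")
        for s in summaries:
            assert s.ci_low <= 0.20 <= s.ci_high
        df = panel.df[panel.df["visit"] == 4]
        a = np.polyfit(df["rbdsq"], df["gds15"], 1)[0]
        X = np.column_stack([np.ones(len(df)), df["rbdsq"], df["gds15"]])
        b = np.linalg.lstsq(X, df["updrs2"], rcond=None)[0][2]
        mid = summaries[1]
        assert mid.ie_mean == pytest.approx(a * b, abs=3 * mid.ie_sd)


class TestIndirectEffectCurve:
    def test_grid_order_preserved(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        out = indirect_effect_curve(d, [0.25, 0.5, 0.75])
        assert [s.t for s in out] == [0.25, 0.5, 0.75]
        assert all(s.ci_low <= s.ci_high for s in out)

    def test_degenerate_draws_collapse_interval(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        for k in ("alpha_w", "beta_w"):
            d.params[k] = np.ones_like(d.params[k]) * 0.3
        (s,) = indirect_effect_curve(d, [0.5])
        assert s.ie_sd == pytest.approx(0.0, abs=1e-12)
        assert s.ci_low == s.ci_high == pytest.approx(s.ie_mean)

    def test_empty_grid_rejected(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        with pytest.raises(ValueError):
            indirect_effect_curve(d, [])

    def test_raw_scale_is_exact_rescaling(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        std = curve_frame(d, [0.25, 0.75])
        raw = curve_frame(d, [0.25, 0.75], scale="raw")
        factor = d.scale["y"] / d.scale["x"]
        assert np.allclose(raw["ie_mean"], std["ie_mean"] * factor)
        assert np.allclose(raw["ci_low"], std["ci_low"] * factor)

    def test_standardized_and_raw_fits_agree_after_rescaling(self, small_panel):
        d_std = _fit(small_panel)
        d_raw = _fit(small_panel, standardize=False)
        s_std = indirect_effect_curve(d_std, [0.5], scale="raw")[0]
        s_raw = indirect_effect_curve(d_raw, [0.5])[0]
        tol = 3 * np.sqrt(s_std.ie_sd**2 + s_raw.ie_sd**2)
        assert s_std.ie_mean == pytest.approx(s_raw.ie_mean, abs=tol)


class TestDiagnose:
    def test_clean_fit_passes_rhat(self, small_panel):
        report = diagnose(_fit(small_panel))
        finite = report.table["rhat"].dropna()
        assert (finite <= 1.05).all()

    def test_constant_chains_flagged_not_crash(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        d.params["sigma_m"] = np.ones_like(d.params["sigma_m"])
        report = diagnose(d)
        assert "sigma_m" in report.flagged

    def test_truncated_draws_raise_ess_flags(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        short = PosteriorDraws(
            spec=d.spec,
            params={k: v[:, :10] for k, v in d.params.items()},
            param_labels=d.param_labels,
            scale=d.scale,
            data_hash=d.data_hash,
        )
        assert not diagnose(short).ok

    def test_single_chain_rejected(self, small_panel):
        d = _fit(small_panel, n_iter=200, n_warmup=50)
        single = PosteriorDraws(
            spec=d.spec,
            params={k: v[:1] for k, v in d.params.items()},
            param_labels=d.param_labels,
            scale=d.scale,
            data_hash=d.data_hash,
        )
        with pytest.raises(ValueError, match="chains"):
            diagnose(single)
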