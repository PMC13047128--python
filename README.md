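# longmed — longitudinal causal mediation for bounded rating-scale panels

`longmed` implements a complete longitudinal causal mediation pipeline for
repeated-measures cohorts of the kind collected in Parkinson's disease
research: an exposure scale (RBDSQ, REM-sleep behavior disorder severity,
0–13), two candidate mediators (GDS-15 depression, 0–15; MoCA cognition,
0–30) and an outcome scale (MDS-UPDRS Part II, limitation in activities of
daily living, 0–52), measured at a baseline visit and eight annual
follow-ups. Study time is min–max normalized, visit *k* ↦ *t* = *k*/8 ∈ [0, 1].

It is a library first (importable API plus `examples/`), with a thin
`longmed` command-line wrapper for the common pipeline stages. Real
PPMI-style cohort data are access-controlled, so the package ships a
first-class synthetic cohort generator with known time-varying mediation
structure; every method is validated against analytic truths, closed forms
and exact enumeration oracles on that generator.

## The models

**Bayesian dynamic (time-varying-coefficient) mediation, one mediator.**
For subject *i* at normalized time *t*, with exposure *X*, mediator *M*,
outcome *Y* and baseline covariates *C<sub>i</sub>* (sex, age band,
education band, race, family history, disease-duration band):

    M_it = a0(t) + α(t) X_it + γ_M' C_i + u_i^M + ε_it^M
    Y_it = b0(t) + β(t) M_it + τ(t) X_it + γ_Y' C_i + u_i^Y + ε_it^Y

α(t) is the time-varying exposure→mediator path, β(t) the mediator→outcome
path adjusted for exposure, τ(t) the direct path; all are cubic B-spline
expansions of *t*. Subject random intercepts *u<sub>i</sub>* handle repeated
measures. The time-*t* indirect effect is the product of paths,
**IE(t) = α(t)·β(t)**, summarized by its posterior mean, SD and equal-tailed
95% credible interval. The model is linear-Gaussian and fully conjugate, so
it is sampled by a collapsed block Gibbs sampler (no external MCMC engine),
with split-R̂/ESS diagnostics via `arviz`.

**Mediational g-formula, two time-varying mediators jointly.** Per-visit
parametric models for each mediator (in a declared causal order: depression
before cognition) and for the end-of-follow-up outcome are fitted given
current exposure, same-visit earlier mediators, the previous visit's
exposure/mediators and baseline covariates. Monte Carlo pseudo-subjects are
pushed through the fitted system under a sustained exposure contrast
(default: the panel's 90th vs 10th percentile RBDSQ trajectory), giving

* the **two-way decomposition** TE = DE + IE<sub>joint</sub> + ξ, where ξ is
  the reported residual between the simulated total effect and the sum of
  separately estimated components (exactly zero under exhaustive
  enumeration), and
* the **path-specific decomposition**, which switches each mediator from its
  low- to its high-exposure counterfactual distribution in causal order and
  partitions IE<sub>joint</sub> into per-mediator contributions plus an
  interaction remainder — exactly, by construction.

Uncertainty comes from a subject-level bootstrap (percentile 95% intervals).

**Monte Carlo post-hoc power.** Cohorts are simulated with true indirect
effects calibrated to target values (defaults: the published time-averaged
indirect effects 0.068 and 0.095 at N = 337) and each replicate tests
whether a 95% interval for the product of paths excludes zero.

## Worked example

```python
import longmed as lm
from longmed.dynamic_mediation import DynMedSpec, curve_frame, fit_dynamic_mediation

panel = lm.simulate_cohort(lm.DGPConfig(seed=42))       # 337 subjects, 9 visits
spec = DynMedSpec(mediator="gds15", n_iter=3000, n_warmup=1000, n_chains=2, seed=0)
draws = fit_dynamic_mediation(panel, spec)
print(curve_frame(draws, [0.25, 0.5, 0.75]).round(4))
```

prints (standardized scale):

```
   t  ie_mean  ie_sd  ci_low  ci_high
0.25   0.0422 0.0090  0.0255   0.0608
0.50   0.0529 0.0100  0.0345   0.0736
0.75   0.0892 0.0128  0.0649   0.1156
```

i.e. the mediated RBD→depression→ADL effect roughly doubles between the
second and sixth annual follow-up, and its 95% credible interval excludes
zero throughout — the generator's true indirect path is indeed positive and
increasing. The same cohort through the g-formula
(`examples/03_gformula_decomposition.py`) gives a decomposition table in ADL
points:

```
            component  estimate  percent_share  ci_low  ci_high
         total_effect     5.568            NaN   4.725    7.198
        direct_effect     3.805          68.34   2.694    5.365
indirect_effect_joint     1.785          32.06   1.191    2.771
          xi_residual    -0.022            NaN  -0.064    0.053
   indirect_via_gds15     0.746          13.39   0.306    1.356
    indirect_via_moca     1.018          18.29   0.467    1.568
interaction_remainder     0.021            NaN  -0.055    0.080
```

so worsening RBD raises final ADL scores by ≈5.6 points, about a third of
which flows through the two mediators. The `examples/` scripts cover each
capability one at a time; `longmed --help` lists the CLI equivalents
(`simulate`, `validate`, `describe`, `dynmed`, `gmed`, `power`).

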