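# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `longmed`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

Panels are long format, one row per subject-visit, with integer scale
scores validated against their published ranges (RBDSQ 0–13, GDS-15 0–15,
MoCA 0–30, UPDRS-II 0–52) and baseline covariates stored as categorical
band labels (sex; age <56/56–65/>65; education <13/13–23/>23 years; race;
family history first-degree/non-first-degree/none; disease duration
<5/5–10/>10 years). Downstream models treat scores as continuous. Visit
indices are 0-based with baseline = 0; normalized study time is
*t* = visit/(n_visits − 1), so follow-ups 2, 4 and 6 of the 9-visit design
sit at 0.25, 0.50 and 0.75. Clinical cut-offs are exposed as pure
functions: GDS-15 < 5 none, 5–9 mild, ≥10 moderate-to-severe depression;
MoCA ≥ 26 normal cognition.

Missing data are handled by an explicit complete-case filter with a
per-variable removal report. Nothing downstream imputes; a different
strategy can be slotted in ahead of the modeling stages.

## Synthetic cohort generator

The generator is the simplest process consistent with a linear
time-varying-coefficient mediation structure, and it defines the study
conditions under which the pipeline is tested:

* exposure: latent AR(1) Gaussian per subject (ρ = 0.7, marginal mean 5.0,
  SD 2.5), rounded and truncated to the RBDSQ range — a stable trait
  measured repeatedly;
* mediators and outcome: linear in exposure/mediators with affine
  increasing paths, Gaussian subject random intercepts (SD 1.0 for the
  mediators, 2.0 for the outcome) and Gaussian residuals (SD 1.8/2.0/3.0
  for GDS-15/MoCA/UPDRS-II), plus modest baseline-covariate shifts;
* default paths: α_gds(t) = 0.20 + 0.20 t, β_gds(t) = 0.30 + 0.30 t,
  α_moca(t) = −(0.15 + 0.25 t), β_moca(t) = −(0.25 + 0.35 t),
  τ(t) = 0.5 + 0.3 t. Each mediator's true indirect effect
  α(t)·β(t) is therefore small, positive and roughly doubles between
  t = 0.25 and t = 0.75 — the regime in which mediation strengthens with
  disease duration. Intercepts (2.5 / 26.5 / 13.6) put score means in
  realistic mid-scale territory so that rounding/truncation to the scale
  ranges is active but rarely binding;
* covariate marginals follow PPMI-like demographics (65.28% male, 74.78%
  over 65, 96.14% White, …);
* seeding: one master seed; per-subject streams are spawned
  deterministically, so growing `n_subjects` extends a cohort without
  reshuffling existing subjects.

What the generator does **not** emulate: item-level scale responses,
informative dropout (a simple per-visit MAR dropout hazard is available,
off by default), time-varying confounders, floor/ceiling pile-ups, and PD
progression biology. Passing tests on this generator demonstrate
correctness of the estimators under a linear-Gaussian world with bounded
integer observation; they do not certify behavior under real-data
pathologies such as strong ceiling effects or informative missingness.

Two toy families provide exact oracles: a binary two-mediator toy over one
or two visits sampled from explicit conditional probability tables (kept
alongside the panel so the g-formula can be enumerated exhaustively), and a
single-visit linear-Gaussian toy whose decomposition has the closed form
TE = c + a·b, DE = c, IE = a·b per unit of exposure.

## Descriptives

Baseline ADL comparisons use the classic equal-variance two-sample t-test
for two-level covariates and one-way ANOVA otherwise; empty levels are
dropped and the test follows the number of nonempty levels. Correlations
are pairwise Pearson with two-sided p-values on complete pairs, pooled
across visits by default (`scope="baseline"` restricts to visit 0). No
multiple-testing correction is applied; zero-variance variables yield
flagged undefined entries rather than silent NaNs.

## Dynamic Bayesian mediation

Model as in the README. Choices that were genuinely open:

* **Basis.** Cubic B-spline with 5 degrees of freedom on [0, 1] (one
  interior knot at 0.5) for every time-varying coefficient — smooth curves
  without overfitting nine time points. A linear-in-t basis is available
  for small samples.
* **Priors.** On z-scored data: Normal(0, 1) on all basis weights and
  covariate coefficients; InverseGamma(2, 1) on residual variances;
  InverseGamma(2, 0.5) on random-intercept variances. Inverse-gamma (rather
  than half-normal) variance priors keep every full conditional conjugate,
  which is what makes the dedicated Gibbs sampler possible; at these data
  sizes the likelihood dominates either choice.
* **Sampler.** Block Gibbs with a *collapsed* coefficient update: the
  coefficient vector is drawn with the subject random intercepts
  marginalized out of its conditional (their covariance contribution is a
  rank-one term per subject), which removes the strong posterior
  correlation between between-subject covariate effects and the
  intercepts. Without the collapse, covariate coefficients mix an order of
  magnitude more slowly. Chains start from prior draws (overdispersed);
  defaults are 10,000 iterations, 5,000 warmup, 4 chains, all configurable;
  the test suite and acceptance script use shorter, verified-converged runs
  (≈1,000–3,000 iterations, 2 chains) to keep wall-clock time modest.
* **Standardization.** X, M, Y are z-scored by default; IE(t) on the
  standardized scale has magnitudes of order 0.05–0.15 on the default
  cohort. The raw-score scale is the exact rescaling IE_raw = IE_std ·
  sd(Y)/sd(X) (tested numerically against a raw-scale fit).
* **Reporting.** IE(t) per draw is the product of the basis expansions;
  summaries are the posterior mean, posterior SD and equal-tailed 95%
  credible interval from draw quantiles. The reported SD is the posterior
  SD of IE(t), not a Monte Carlo standard error.
* **Random effects.** Independent subject intercepts in both equations;
  random slopes are out of scope. Covariates are dummy-coded with the
  largest category as reference; covariates constant in a panel contribute
  no columns.
* **Diagnostics.** Split-R̂ and bulk ESS per scalar parameter via arviz;
  parameters with R̂ > 1.05 or ESS < 400 are flagged, and a non-converged
  fit attaches a warning to the returned draws rather than failing.
  Degenerate (constant) chains are flagged, not fatal.

## Mediational g-formula

* **Component models.** Per visit *k* (including baseline, so mediators can
  respond to the exposure regime from the first visit) and per variable in
  the declared causal order: linear-Gaussian regression on current
  exposure, same-visit earlier mediators, the previous visit's exposure and
  mediators, and baseline covariates. The outcome is modeled at the final
  visit only, on current and one-visit-lagged exposure/mediators plus
  covariates. A "saturated" form (conditional cell means, equivalent to the
  saturated MLE) serves the binary toys, avoiding logistic separation on
  deterministic tables. Constant targets are flagged degenerate;
  zero-variance columns are pruned before fitting and any remaining rank
  deficiency is an error naming the model.
* **Estimands.** With regimes x_high/x_low (default: per-visit 90th vs 10th
  percentile RBDSQ trajectory — a concrete, data-adaptive "worsening RBD"
  contrast, fully configurable): TE contrasts joint simulation under the
  two regimes; DE holds the joint mediator distribution at x_low; IE_joint
  switches it; each is estimated from its own Monte Carlo stream, and
  ξ = TE − DE − IE_joint is reported as the decomposition's closure
  discrepancy (identically zero under enumeration). Path-specific
  contributions switch mediators one at a time in causal order, each drawn
  independently from its *marginal* counterfactual trajectory law
  (interventional-effect style); their sum plus the interaction remainder
  equals IE_joint exactly by construction. With mediators conditionally
  dependent, contributions are order-sensitive and the remainder absorbs
  the joint-vs-product-of-marginals discrepancy; with conditionally
  independent mediators the contributions are order-invariant (tested).
* **Monte Carlo.** Pseudo-subjects resample baseline covariate rows from
  the panel; mediator trajectories are simulated with Gaussian residual
  draws; outcome expectations use the fitted mean (no outcome noise), which
  strictly reduces variance. Default n_mc = 10,000; the enumeration
  agreement check runs at 10^6.
* **Uncertainty.** Subject-level nonparametric bootstrap (default 500
  replicates), percentile 95% intervals; replicate failures are counted and
  more than 10% failing is an error.

## Power analysis

The published power figures came from a structural-equation machinery whose
simulation configuration is not recoverable, so the module exposes a fully
specified procedure instead: standardized cohorts (AR(1) exposure, linear
mediator/outcome equations, subject random intercepts of SD 0.3) calibrated
so each mediator's true indirect effect equals its target; per replicate,
pooled OLS per equation with cluster-robust (subject) standard errors and a
Monte-Carlo normal-draw percentile interval for each product of paths and
for their sum. Calibration anchors the mediator→outcome path at ≥0.3 and
puts the target into the exposure→mediator path, so a zero target yields a
product test with asymptotically nominal size (both-paths-zero nulls make
the product non-normal). Targets whose implied path leaves no residual
variance are rejected as non-calibratable. Power is the rejection
proportion with binomial Monte Carlo standard errors; it is nondecreasing
in sample size and effect magnitude (tested with Monte Carlo slack).

## Numerical conventions

* Equal-tailed 95% intervals from empirical quantiles throughout.
* Percentage shares are component/TE × 100, reported to 2 decimals and
  undefined (NaN) when TE = 0.
* All randomness flows from user-supplied integer seeds through
  `numpy.random.SeedSequence` spawning; same seed ⇒ bit-identical output.
* Problem sizes in the test suite (20 replicate cohorts for coverage
  checks, 500 power replicates, 10^5–10^6 Monte Carlo draws for oracle
  agreement) are the package's chosen desk-scale defaults for routine
  verification; the library defaults (10,000 MCMC iterations, 2,000 power
  replicates, 500 bootstrap replicates) match the scale of the original
  analysis.

## Limitations

* Published cohort-specific estimates cannot be reproduced without access
  to the underlying PPMI data; the package verifies their internal
  arithmetic and reproduces their qualitative structure on synthetic data.
* The g-formula supports baseline covariates plus lagged analysis variables
  as the confounding set; general time-varying confounders, censoring and
  survival outcomes are out of scope.
* Outcomes and mediators are modeled as Gaussian; bounded-scale floor and
  ceiling effects are handled only through truncation in the generator, not
  in the likelihood.
* Path-specific effects require the declared causal ordering of mediators
  and stronger identification assumptions than the joint indirect effect;
  the ordering (depression before cognition) is a substantive choice, and
  its order-sensitivity is documented and tested rather than removed.
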