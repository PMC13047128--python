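"""Bayesian dynamic mediation: the indirect-effect curve of one mediator.

Fits the two-equation time-varying-coefficient model with depression
(GDS-15) mediating the RBD -> ADL relationship, on a synthetic cohort whose
true indirect effect alpha(t) * beta(t) rises over the study.  Prints the
posterior summary of IE(t) at the three reference time points and the
convergence diagnostics.
"""

import warnings

import longmed as lm
from longmed.dynamic_mediation import (
    DynMedSpec, curve_frame, diagnose, fit_dynamic_mediation,
)

config = lm.DGPConfig(seed=42)
panel = lm.simulate_cohort(config)

spec = DynMedSpec(mediator="gds15", n_iter=3000, n_warmup=1000, n_chains=2, seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    draws = fit_dynamic_mediation(panel, spec)

print("Indirect effect IE(t) = alpha(t)*beta(t), standardized scale:")
print(curve_frame(draws, [0.25, 0.5, 0.75]).round(4).to_string(index=False))
print("Raw ADL-points-per-RBDSQ-point scale:")
print(curve_frame(draws, [0.25, 0.5, 0.75], scale="raw").round(4).to_string(index=False))
truth = lm.true_effects(config, [0.25, 0.5, 0.75]).ie_true["gds15"]
print("True raw-scale IE at these times:", truth.round(4))
print("The posterior mean should track the truth and the credible interval")
print("should widen late in follow-up where fewer subjects contribute spread.")

report = diagnose(draws)
print(f"\nConvergence: {len(report.flagged)} flagged parameters "
      f"(split-R-hat > {report.rhat_threshold} or ESS < {report.ess_threshold:g}); "
      f"max R-hat = {report.table['rhat'].max():.4f}")
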