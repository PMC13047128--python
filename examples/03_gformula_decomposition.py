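"""Mediational g-formula: two-way and path-specific decompositions.

Decomposes the effect of a sustained "worsening RBD" exposure contrast
(90th vs 10th percentile RBDSQ trajectory) on end-of-follow-up ADL into a
direct effect and indirect effects through depression and cognition, with
subject-level bootstrap 95% intervals.
"""

import longmed as lm
from longmed.gformula import GFormulaSpec, bootstrap_decomposition

panel = lm.simulate_cohort(lm.DGPConfig(seed=42))
spec = GFormulaSpec(n_mc=10_000, n_boot=100, seed=0)
result = bootstrap_decomposition(panel, spec)

print(result.to_frame().round(3).to_string(index=False))
print()
print("Reading the table: the exposure contrast raises final ADL by the")
print("total_effect (in UPDRS-II points); percent_share allocates it to the")
print("direct path and to each mediator.  xi_residual is the Monte Carlo")
print("closure discrepancy of the decomposition and should be near zero;")
print("TE = DE + IE_joint + xi holds exactly by construction.")
tw = result.twoway
assert tw.te == tw.de + tw.ie_joint + tw.xi
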