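"""Exact enumeration oracle vs the Monte Carlo g-formula engine.

On a binary two-visit toy with known conditional probability tables, every
counterfactual expectation can be summed exhaustively.  The Monte Carlo
engine run on the same tables must agree up to sampling error — the central
correctness check for the g-computation machinery.
"""

from longmed.gformula import GFormulaSpec, decompose_cpts, enumerate_oracle
from longmed.synthetic_cohort import random_toy_cpts

cpts = random_toy_cpts(seed=11, n_visits=2)
spec = GFormulaSpec(seed=0)

oracle_tw, oracle_ps = enumerate_oracle(cpts, spec)
mc_tw, mc_ps = decompose_cpts(cpts, spec, n_mc=200_000)

print(f"{'component':<22}{'exact':>10}{'monte carlo':>14}{'abs err':>10}")
rows = [("total effect", oracle_tw.te, mc_tw.te),
        ("direct effect", oracle_tw.de, mc_tw.de),
        ("joint indirect", oracle_tw.ie_joint, mc_tw.ie_joint),
        ("via mediator 1", oracle_ps.per_mediator["gds15"],
         mc_ps.per_mediator["gds15"]),
        ("via mediator 2", oracle_ps.per_mediator["moca"],
         mc_ps.per_mediator["moca"])]
for name, exact, mc in rows:
    print(f"{name:<22}{exact:>10.5f}{mc:>14.5f}{abs(exact - mc):>10.5f}")
print("\nErrors shrink as 1/sqrt(n_mc); at n_mc = 200,000 they should sit")
print("well below 0.005.  The exact xi is identically zero:",
      oracle_tw.xi)
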