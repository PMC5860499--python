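"""Exact nonparametric identity on an enumerable toy law.

On a discrete two-period law (binary covariate, binary treatment) with the
fully saturated learner, IPTW, sequential-regression g-computation and TMLE
all reproduce the exhaustive g-computation sum evaluated on the empirical
distribution *exactly* — the three estimators are algebraic rearrangements
of the same nonparametric plug-in.
"""

import longtmle as lt

dgp = lt.discrete_toy_dgp(2)
panel = dgp.sample(2000, seed=100)
regime = lt.static_regime([1, 1], "always_treat")

oracle = lt.gformula_exhaustive(panel, regime, 2)
mech = lt.fit_treatment_mechanism(panel, regime, 2, library=["saturated"],
                                  markov_order="full")
iptw = lt.iptw_estimate(panel, regime, 2, mech)
gcomp, _ = lt.ice_gcomp_estimate(panel, regime, 2, library=["saturated"])
tmle, _ = lt.tmle_estimate(panel, regime, 2, mechanism=mech, library=["saturated"])

print(f"exhaustive g-formula on the empirical law : {oracle:.12f}")
print(f"IPTW   (saturated g)                      : {iptw.psi_hat:.12f}")
print(f"g-comp (saturated regressions)            : {gcomp.psi_hat:.12f}")
print(f"TMLE   (saturated everything)             : {tmle.psi_hat:.12f}")
print(f"exact counterfactual truth of the law     : {dgp.true_psi(regime, 2):.12f}")
print("\nThe first four agree to machine precision; the last differs only by"
      "\nthe n = 2000 sampling error of the empirical distribution.")
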