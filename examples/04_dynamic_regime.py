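"""Dynamic treatment rules and the positivity diagnostic.

Dynamic regimes assign treatment as a function of the evolving covariates,
so each child's required feeding sequence depends on their own extubation
path.  The two complementary rules below — "feed on ventilated days" versus
"feed on days off ventilation" — differ sharply in how well the
observational data support them: clinicians in this cohort rarely feed
extubated children, so the second rule is followed by almost nobody and its
minimum cumulative follow probability collapses far below the 0.05
truncation-policy threshold.  The diagnostic flags exactly this.
"""

import longtmle as lt

spec = lt.DGPSpec()
panel = lt.simulate_chip_like(spec, n=2000, seed=3)

for trigger, label in ((1, "feed_when_ventilated"), (0, "feed_off_vent")):
    dyn = lt.dynamic_rule_regime("vent", feed_when_value=trigger, label=label)
    truth = lt.true_psi_monte_carlo(spec, dyn, 4, n_mc=200_000, seed=5)
    mech = lt.fit_treatment_mechanism(panel, dyn, 4, library=["logit_main"],
                                      markov_order=2, seed=2)
    tmle, _ = lt.tmle_estimate(panel, dyn, 4, mechanism=mech,
                               library=["logit_main"], markov_order=2, seed=2)
    print(f"\nregime: {label} (treat iff ventilation == {trigger})")
    print(f"  followers through day 4 : {tmle.n_followers} / {panel.n}")
    print(f"  min cumulative g        : {tmle.min_cum_g:.4f}")
    print(f"  TMLE                    : {tmle.psi_hat:.3f} "
          f"(95% CI {tmle.ci_low:.3f}-{tmle.ci_high:.3f})")
    print(f"  Monte-Carlo truth       : {truth.true_psi:.3f} "
          f"(+/- {2 * truth.mc_se:.4f})")

print(
    "\nThe well-supported rule is estimated accurately.  For the poorly"
    "\nsupported rule the minimum cumulative g is orders of magnitude below"
    "\n0.05: the identifying positivity assumption is practically violated,"
    "\nand no estimator can be trusted there — the diagnostic, not the"
    "\npoint estimate, is the finding."
)
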