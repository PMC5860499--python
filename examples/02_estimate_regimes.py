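"""Counterfactual discharge curves under two contrasting feeding regimes.

Estimates the probability of live PICU discharge by the end of each day had
every child followed "never feed" versus "feed from day 3", using the naive
follower proportion and the three adjusted estimators (IPTW, sequential-
regression g-computation, longitudinal TMLE).  The generator's Monte-Carlo
truth shows how far the unadjusted curve is pulled up by time-dependent
confounding (children coming off ventilation are fed less AND discharged
sooner).
"""

import longtmle as lt

spec = lt.DGPSpec()
panel = lt.simulate_chip_like(spec, n=706, seed=1)
never = lt.static_regime([0] * 7, "never_feed")
fd3 = lt.static_regime([0, 0, 1, 1, 1, 1, 1], "feed_from_day_3")

table = lt.survival_curve(
    panel, [never, fd3],
    estimators=("naive", "iptw", "gcomp", "tmle"),
    t_range=[3, 5],
    library=["logit_main"], g_library=["logit_main"],
    markov_order="full", g_markov_order=2, folds=10, seed=7,
)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

for reg in (never, fd3):
    truth = lt.true_psi_monte_carlo(spec, reg, 5, n_mc=200_000, seed=11)
    print(f"\nMonte-Carlo truth psi({reg.label}, day 5) = {truth.true_psi:.3f}"
          f" (+/- {2 * truth.mc_se:.4f})")

print(
    "\nThe naive follower proportions overstate both truths; the adjusted"
    "\nestimators move toward the Monte-Carlo truth, and TMLE/IPTW attach"
    "\ninfluence-curve Wald intervals (g-computation reports none)."
)
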