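"""Cross-validated convex stacking of the candidate learner library.

Fits the default four-candidate library (intercept, main-terms logistic,
all-pairwise-interaction logistic, L1-penalized logistic) to a day-2 feeding
model and prints each candidate's 10-fold CV log-loss together with the
convex ensemble weights.  The stack's CV loss can never exceed the best
single candidate's — every vertex of the weight simplex is feasible.
"""

import longtmle as lt

panel = lt.simulate_chip_like(lt.DGPSpec(), n=1500, seed=4)
at_risk = lt.at_risk_mask(panel, 1) == 1
X = lt.history_matrix(panel, 1, markov_order=2).to_numpy()
y = panel.a(1)

fit = lt.cv_superlearner(
    ["intercept", "logit_main", "logit_interact", "logit_l1"],
    X[at_risk], y[at_risk], folds=10, seed=9,
)

names = ["intercept", "logit_main", "logit_interact", "logit_l1"]
print("candidate          CV log-loss   ensemble weight")
for name, loss, w in zip(names, fit.cv_losses, fit.weights):
    print(f"{name:<18} {loss:>11.4f}   {w:>15.3f}")
print(f"{'convex stack':<18} {fit.ensemble_cv_loss:>11.4f}")
print("\nWeights are nonnegative and sum to one; the stack's cross-validated"
      "\nloss is no worse than the best single candidate's.")
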