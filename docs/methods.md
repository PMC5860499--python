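# Methods

## Data structure and conventions

One subject's record is the ordered vector
`O = (Z0, A0, Y1, M1, Z1, A1, …, A_T, Y_{T+1})` with `T+1` daily periods
(default 7).  `Z0` holds the baseline covariates together with the first
measurement of the time-varying ones; `A_t ∈ {0,1}` is the treatment decided
during period `t`; `Y_t` and `M_t` indicate live discharge and death by the
end of period `t`.  Both events are absorbing and mutually exclusive; there
is no `M_{T+1}` node (the record ends with `Y_{T+1}`).  After a subject's
first event at period `e`, every later treatment and covariate cell is
deterministically the last observed value — `A_{e-1}` and `Z_{e-1}`, the
nodes that causally precede the event indicator.  `validate_panel` checks
monotonicity, mutual exclusivity, the carry-forward rule and completeness
(missing values are rejected, not imputed: the artifact targets complete
daily panels); `apply_absorbing_states` is the idempotent projection onto
that convention.

History design matrices contain the baseline block plus the `Z` and `A`
columns of the most recent `markov_order` periods ("full" keeps everything).
Outcome (`Y`/`M`) histories are omitted from designs because every
regression is fit in the at-risk set, where they are identically zero.

## Regimes

A regime pins down treatment only at *constrained* periods and only while
the subject is at risk:

* static: `A_t = a_t` for a fixed binary vector;
* delayed start `s`: unconstrained before `s`, `A_t = 1` from `s` on.  The
  unconstrained treatments remain random; the estimators condition on them
  (they join the adjustment history) and their treatment-mechanism factors
  are identically 1.  When no period before `t*` is constrained the
  estimand degenerates to the marginal mean of `Y_{t*}` and every estimator
  returns exactly that;
* dynamic: `d_t` is a deterministic function of a current binary covariate
  (e.g. feed iff off ventilation).  Richer rules can be passed as a
  callable on the current covariate map.

The follow indicator demands a match at every constrained period reached
while at risk; person-periods after discharge or death always count as
following, so events never leave the analysis — this is what makes
`psi(d, t*)` a *cumulative incidence* rather than a hazard-type contrast.
A consequence worth knowing: the naive follower proportion is biased even
when treatment is randomized every period (for `t* > 1`), because subjects
with early events need to match fewer periods; only the weighted or
g-computed estimators undo this length-of-stay selection.

## Nuisance estimation

Treatment mechanisms `g_t = Pr[A_t = d_t(V_t) | followed through t-1,
history]` are fit per period among at-risk followers (Markov order 2 by
default), predictions floored at 1e-4 as pure numerical protection —
distinct from user-requested truncation via `g_lower_bound`, which follows
the policy of truncating only when the minimum cumulative follow
probability drops below 0.05.  Unconstrained and post-event person-periods
contribute `g_t = 1`.

Sequential outcome regressions and treatment models share a learner
interface.  Fractional outcomes (the iterated regressions regress previous
*predictions*) are handled by the exact two-row Bernoulli expansion, whose
weighted binary log-likelihood equals the quasi-Bernoulli log-likelihood of
the fractional data, so any weighted binary classifier is a valid learner.
The default library is intercept-only, main-terms logistic, all-pairwise-
interaction logistic (tiny ridge for identifiability) and L1-penalized
logistic; a fully saturated cell-mean learner exists for discrete laws and
is what the exact oracle identities use.  Stacking weights minimize the
10-fold cross-validated negative Bernoulli log-likelihood over the simplex
(SLSQP; folds stratified on the binarized outcome, shared across learners;
if the optimizer fails to beat the best vertex, that vertex is used — the
guarantee `CV loss(stack) ≤ min CV loss(candidate)` is therefore
structural).  A single-candidate library short-circuits to weight 1 with no
CV pass; the large simulation studies use single-learner libraries, where
cross-validation would only add cost without changing the fit.

## Estimators

With `I_i(t)` the follow indicator through `t` and `g_{0:t} = Π_{s≤t} g_s`:

* **IPTW**: `psi = Σ w_i Y_i / Σ w_i`, `w_i = I_i(t*-1)/g_{0:t*-1,i}`;
  influence curve `IC_i = w_i (Y_i − psi) / mean(w)`, whose empirical mean
  is zero algebraically.  The estimated `g` is treated as fixed in the IC.
  This is deliberate and conservative: estimating `g` makes the weighted
  estimator *more* efficient than the known-`g` IC implies, so with several
  estimated factors and heavy weights the Wald intervals over-cover (we
  measure z-statistic standard deviations around 0.8–0.95 at `n = 2000` on
  the default synthetic law, i.e. coverage up to ~0.99 at horizons where the
  minimum cumulative g sits near 0.05).  TMLE's interval does not inherit
  this inflation when the sequential regressions are well specified, since
  its IC is the efficient one.
* **ICE g-computation**: innermost step regresses `Y_{t*}` on the history
  through `t*-1` among at-risk followers, predicts with constrained
  treatments set to the regime; outer steps repeat on the previous
  predictions with shorter histories; finally `psi = mean(Q_1)`.  Subjects
  already discharged (dead) at a step carry the deterministic value 1 (0),
  are excluded from fitting, and re-enter the averaging.  No interval is
  reported: without targeting there is no usable influence-function
  variance, and bootstrapping data-adaptive fits is both costly and
  unreliable, so it is deliberately not bundled.
* **TMLE**: after each regression the intercept fluctuation
  `logit(Q_t^1) = logit(Q_t) + ε_t` is fit with offset `logit(Q_t)` and
  weights `I(t-1)/g_{0:t-1}`, solving
  `Σ_i w_i (y_i − expit(logit(q_i)+ε)) = 0` by Brent bracketing plus Newton
  polish to |score| < 1e-10 (ε capped at ±18 with a warning when all
  weighted pseudo-outcomes sit on one boundary; ε = 0 when no weight is
  positive).  Predictions exactly 0 or 1 are deterministic nodes and are
  not moved by the submodel — this preserves the exact nonparametric
  identity under saturated fits.  The influence curve is
  `IC_i = Σ_{t=1}^{t*} [I_i(t-1)/g_{0:t-1,i}] (Q_{t+1,i}^1 − Q_{t,i}^1)
  + Q_{1,i}^1 − psi` with `Q_{t*+1}^1 := Y_{t*}`; each fluctuation zeroes
  the corresponding term, so `mean(IC) = 0` to solver tolerance on every
  run.  One scalar ε per step (no pooling across steps).

Wald intervals use ±1.96·sd(IC)/√n, truncated to [0,1]; no small-sample
correction.  `Q` predictions are clipped to [1e-4, 1−1e-4] before logits.
`survival_curve` evaluates any set of regimes over a day range, fitting
each regime's treatment mechanism once at the largest day and reusing it.

## Synthetic study law

`DGPSpec` encodes a 706-child-scale cardiac-surgery PICU cohort: age
(gamma, ≤36 months), sex, weight and height (age-linked), a 6-level
surgical risk category, a randomization arm, universal ventilation at
entry, rare renal replacement and infection, and a continuous inotrope
score with daily decay.  All hazards are logistic in the current state.
The confounding is structural: being ventilated raises the feeding
probability (+2.8 on the logit scale) and strongly lowers the discharge
hazard (−3.4); past feeding delays extubation (−0.4); younger and
higher-risk children are fed less and stay longer; the direct feeding
effect on discharge is modest (−0.3) and on death zero.  Magnitudes were
calibrated once so that the unadjusted "never feed" curve exceeds the
counterfactual truth by ≈0.1–0.2 on the probability scale at day 5 — the
qualitative signature the method exists to remove — with ~80% discharged
and ~1.5% dead by day 7.  Deaths are kept rare so the competing-risk code
paths are exercised without dominating.

What the generator does *not* emulate: continuous caloric intake and its
threshold dichotomization (treatment is generated directly as binary),
measurement error, missingness, irregular visit timing, re-intubation
(ventilation is absorbing-off within the window), and any correlation
structure beyond the listed hazards.  Passing tests therefore demonstrate
estimator correctness under a law with genuine time-dependent confounding
and competing risks — not fidelity to any particular clinical dataset.
One realistic feature to note: "feed from day 3"-type regimes and the
feed-off-ventilation dynamic rule are weakly supported under this law
(minimum cumulative g can fall well below 0.05), which is exactly the
situation the positivity diagnostic reports; the simulation studies
therefore use the well-supported "never feed" regime.

`true_psi_monte_carlo` replays the generator with constrained treatment
nodes forced to the regime (unconstrained ones stay observational),
giving truth to MC precision.  The discrete toy laws expose full
probability tables; their exact interventional means come from path
enumeration, and `gformula_exhaustive` also evaluates the g-computation
sum on a panel's *empirical* law (transition frequencies among observed
followers; unconstrained treatments join the history).  On such laws,
saturated IPTW, ICE g-computation and TMLE agree with the empirical
g-formula to machine precision whenever the draw leaves every follower
cell occupied — an empty cell is an empirical positivity hole where the
target itself is undefined, and is raised as an error rather than patched.

## Simulation study design

The packaged studies run at: double robustness — 200 panels of n = 4000,
horizon day 3, "never feed", truth from 10^6 forced draws; coverage and
interval width — 500 panels of n = 2000, both nuisances fit by main-terms
logistic.  "Correctly specified" means main-terms logistic on the
generating history: exact for the treatment hazard and the innermost
outcome step, approximate for the outer marginalized steps (marginalizing
a logistic hazard over transitions does not stay logit-linear; the
residual approximation error is well inside one Monte-Carlo SE here).
Misspecification arms use the intercept-only learner.  The measured
picture: TMLE is unbiased under either correct nuisance and its intervals
cover at ≈0.95–0.97; IPTW inherits the bias of a wrong treatment model,
and its deliberately conservative known-g intervals over-cover (≈0.99 at
the day-3 horizon); TMLE's intervals are systematically narrower than
IPTW's.

## Known limitations

* Inference treats nuisance estimates as fixed; no cross-fitting, so
  highly adaptive learners could invalidate the TMLE intervals in theory
  (the default library is low-complexity).
* No contrasts across regimes with joint inference — per-regime ICs are
  exposed so users can difference them.
* Discrete time only; no missing-data machinery; stochastic regimes and
  regime optimization are out of scope.
* The dynamic-rule surface covers rules on one current binary covariate
  (what the applied analyses need); the generic callable hook exists but
  richer rules are untested territory.
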