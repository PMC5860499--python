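"""Estimator correctness: hand examples, oracle identities, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import longtmle as lt
from longtmle.exceptions import EstimationError
from longtmle.treatment import TreatmentMechanism

from conftest import tiny_panel


def one_period_panel(A, Y, l0=None):
    A = np.asarray(A, dtype=float)[:, None]
    Y = np.asarray(Y, dtype=float)[:, None]
    l0 = np.zeros(len(A)) if l0 is None else np.asarray(l0, dtype=float)
    return lt.PanelData.from_arrays(pd.DataFrame({"l": l0}), A, Y)


class TestNaive:
    def test_proportion(self):
        p = one_period_panel(A=[1, 1, 1, 1], Y=[1, 1, 0, 1])
        res = lt.naive_estimate(p, lt.static_regime([1], "treat"), 1)
        assert res.psi_hat == pytest.approx(0.75)
        assert res.n_followers == 4

    def test_all_discharged_boundary(self):
        p = one_period_panel(A=[0, 0, 0], Y=[1, 1, 1])
        res = lt.naive_estimate(p, lt.static_regime([0], "never"), 1)
        assert res.psi_hat == 1.0 and res.se == 0.0
        assert res.ci_low == res.ci_high == 1.0

    def test_full_sample_reduction(self, chip_panel):
        # a regime every subject follows reproduces the marginal proportion
        reg = lt.delayed_start_regime(6, T_plus_1=7)
        res = lt.naive_estimate(chip_panel, reg, 5)
        assert res.psi_hat == pytest.approx(chip_panel.y(5).mean())
        assert res.n_followers == chip_panel.n

    def test_zero_followers(self):
        p = one_period_panel(A=[0, 0], Y=[1, 0])
        with pytest.raises(EstimationError):
            lt.naive_estimate(p, lt.static_regime([1], "treat"), 1)


def manual_mechanism(g_rows):
    g = np.asarray(g_rows, dtype=float)
    return TreatmentMechanism(g=g, t_star=g.shape[0], markov_order=2,
                              regime_label="manual", fits=[])


class TestIPTW:
    def test_four_subject_hand_example(self):
        # (A0, Y1, g0): (1,1,.5) (1,0,.25) (0,1,-) (1,1,.5)
        # numerator mean (2+0+0+2)/4 = 1, denominator mean (2+4+0+2)/4 = 2
        p = one_period_panel(A=[1, 1, 0, 1], Y=[1, 0, 1, 1])
        mech = manual_mechanism([[0.5, 0.25, 0.9, 0.5]])
        res = lt.iptw_estimate(p, lt.static_regime([1], "treat"), 1, mech)
        assert res.psi_hat == pytest.approx(0.5, abs=1e-12)
        assert res.n_followers == 3

    def test_unweighted_reduction_to_naive(self):
        p = one_period_panel(A=[1, 1, 1, 1], Y=[1, 0, 1, 1])
        mech = manual_mechanism([np.ones(4)])
        reg = lt.static_regime([1], "treat")
        assert lt.iptw_estimate(p, reg, 1, mech).psi_hat == pytest.approx(
            lt.naive_estimate(p, reg, 1).psi_hat
        )

    def test_scale_invariance(self):
        p = one_period_panel(A=[1, 1, 0, 1], Y=[1, 0, 1, 1])
        reg = lt.static_regime([1], "treat")
        a = lt.iptw_estimate(p, reg, 1, manual_mechanism([[0.5, 0.25, 0.9, 0.5]]))
        b = lt.iptw_estimate(p, reg, 1, manual_mechanism([[0.25, 0.125, 0.45, 0.25]]))
        assert a.psi_hat == pytest.approx(b.psi_hat, abs=1e-12)

    def test_ic_mean_zero(self, chip_panel, never_feed):
        mech = lt.fit_treatment_mechanism(chip_panel, never_feed, 4, library=["logit_main"])
        res = lt.iptw_estimate(chip_panel, never_feed, 4, mech)
        assert abs(res.ic.mean()) < 1e-10
        assert res.se == pytest.approx(res.ic.std(ddof=0) / np.sqrt(chip_panel.n))


class TestFluctuation:
    def test_closed_form_intercept_update(self):
        # offsets logit(0.5) = 0 -> eps = logit(weighted mean of pseudo-outcomes)
        q = np.full(4, 0.5)
        y = np.array([1.0, 1.0, 1.0, 0.0])
        eps, upd = lt.tmle_update_step(q, y, np.ones(4))
        assert eps == pytest.approx(logit(0.75), abs=1e-8)
        np.testing.assert_allclose(upd, 0.75, atol=1e-8)

    def test_score_already_solved(self):
        q = np.array([0.2, 0.8, 0.5])
        eps, upd = lt.tmle_update_step(q, q.copy(), np.ones(3))
        assert abs(eps) < 1e-8
        np.testing.assert_allclose(upd, q, atol=1e-8)

    def test_zero_weights_identity(self):
        q = np.array([0.3, 0.6])
        eps, upd = lt.tmle_update_step(q, np.array([1.0, 1.0]), np.zeros(2))
        assert eps == 0.0
        np.testing.assert_allclose(upd, q)

    def test_boundary_outcomes_cap_epsilon(self):
        q = np.full(3, 0.5)
        with pytest.warns(UserWarning, match="capped"):
            eps, upd = lt.tmle_update_step(q, np.ones(3), np.ones(3))
        assert eps == 18.0
        assert (upd > 0.999999).all()

    def test_deterministic_cells_untouched(self):
        q = np.array([0.0, 1.0, 0.5])
        eps, upd = lt.tmle_update_step(q, np.array([0.0, 1.0, 0.8]), np.ones(3))
        assert upd[0] == 0.0 and upd[1] == 1.0
        assert upd[2] == pytest.approx(0.8, abs=1e-8)


class TestOracleEquivalence:
    """Saturated fits reproduce the empirical g-formula exactly."""

    @pytest.mark.parametrize("regime_spec", [
        ("static", (1, 1)), ("static", (0, 1)), ("dynamic", None),
    ])
    def test_two_period(self, toy2_panel, regime_spec):
        kind, vec = regime_spec
        reg = (lt.static_regime(vec, f"s{vec}") if kind == "static"
               else lt.dynamic_rule_regime("l", 1, "dyn"))
        oracle = lt.gformula_exhaustive(toy2_panel, reg, 2)
        mech = lt.fit_treatment_mechanism(
            toy2_panel, reg, 2, library=["saturated"], markov_order="full")
        iptw = lt.iptw_estimate(toy2_panel, reg, 2, mech)
        gc, _ = lt.ice_gcomp_estimate(toy2_panel, reg, 2, library=["saturated"])
        tm, _ = lt.tmle_estimate(toy2_panel, reg, 2, mechanism=mech, library=["saturated"])
        for est in (iptw, gc, tm):
            assert est.psi_hat == pytest.approx(oracle, abs=1e-8)

    def test_one_period_matches_hand_value(self, toy1):
        # P(L0=1)=.5, P(Y1=1|A0=1,L0) = (.2,.6): psi = .5*.2 + .5*.6 = .4
        reg = lt.static_regime([1], "always")
        assert lt.gformula_exhaustive(toy1, reg, 1) == pytest.approx(0.4, abs=1e-12)
        panel = toy1.sample(4000, seed=5)
        gc, _ = lt.ice_gcomp_estimate(panel, reg, 1, library=["saturated"])
        assert gc.psi_hat == pytest.approx(
            lt.gformula_exhaustive(panel, reg, 1), abs=1e-10)
        assert gc.psi_hat == pytest.approx(0.4, abs=0.05)


class TestSequentialRecursion:
    def test_constant_outcome_gives_one(self):
        Y = np.zeros((30, 2))
        Y[:, 1] = 1.0  # everyone discharged by day 2
        rng = np.random.default_rng(0)
        A = rng.integers(0, 2, size=(30, 2)).astype(float)
        p = lt.apply_absorbing_states(lt.PanelData.from_arrays(
            pd.DataFrame({"l": rng.integers(0, 2, 30).astype(float)}),
            A, Y, np.zeros((30, 1)), {"l": rng.integers(0, 2, (30, 1)).astype(float)},
        ))
        reg = lt.static_regime([1, 1], "always")
        gc, _ = lt.ice_gcomp_estimate(p, reg, 2, library=["logit_main"])
        assert gc.psi_hat == pytest.approx(1.0, abs=1e-3)

    def test_delayed_start_before_start_is_marginal_mean(self, chip_panel):
        reg = lt.delayed_start_regime(4, T_plus_1=7)
        gc, _ = lt.ice_gcomp_estimate(chip_panel, reg, 3)
        tm, _ = lt.tmle_estimate(chip_panel, reg, 3)
        marginal = chip_panel.y(3).mean()
        assert gc.psi_hat == pytest.approx(marginal)
        assert tm.psi_hat == pytest.approx(marginal)
        assert gc.se is None and tm.se is not None

    def test_gcomp_reports_no_interval(self, toy2_panel):
        reg = lt.static_regime([1, 1], "always")
        gc, _ = lt.ice_gcomp_estimate(toy2_panel, reg, 2, library=["saturated"])
        assert gc.se is None and gc.ci_low is None and gc.ic is None

    def test_tmle_ic_and_scores_vanish(self, chip_panel, never_feed):
        tm, fits = lt.tmle_estimate(
            chip_panel, never_feed, 4, library=["logit_main"], markov_order=2, seed=2)
        assert abs(tm.ic.mean()) < 1e-8
        for t, score in fits.scores.items():
            assert abs(score) < 1e-8, f"score at step {t}"
        assert 0 <= tm.ci_low <= tm.psi_hat <= tm.ci_high <= 1

    def test_all_estimators_agree_without_confounding(self):
        # Treatment randomized every period.  At t* = 1 the follower subset
        # is an unbiased sample, so all four estimators agree; at later days
        # the naive proportion is still selection-biased (short stays make
        # following easier) while the three adjusted estimators agree with
        # each other and with the counterfactual truth.
        spec = lt.DGPSpec()
        spec.treat = {k: 0.0 for k in spec.treat}
        panel = lt.simulate_chip_like(spec, 8000, seed=21)
        reg = lt.static_regime([0] * 7, "never")

        naive1 = lt.naive_estimate(panel, reg, 1)
        mech = lt.fit_treatment_mechanism(panel, reg, 3, library=["logit_main"])
        iptw1 = lt.iptw_estimate(panel, reg, 1, mech)
        tm1, _ = lt.tmle_estimate(panel, reg, 1, mechanism=mech,
                                  library=["logit_main"], markov_order=2)
        gc1, _ = lt.ice_gcomp_estimate(panel, reg, 1, library=["logit_main"],
                                       markov_order=2)
        psis1 = [naive1.psi_hat, iptw1.psi_hat, gc1.psi_hat, tm1.psi_hat]
        assert max(psis1) - min(psis1) < 3 * naive1.se

        truth3 = lt.true_psi_monte_carlo(spec, reg, 3, n_mc=200_000, seed=5).true_psi
        iptw3 = lt.iptw_estimate(panel, reg, 3, mech)
        gc3, _ = lt.ice_gcomp_estimate(panel, reg, 3, library=["logit_main"],
                                       markov_order=2)
        tm3, _ = lt.tmle_estimate(panel, reg, 3, mechanism=mech,
                                  library=["logit_main"], markov_order=2)
        for est in (iptw3, tm3):
            assert abs(est.psi_hat - truth3) < 3.5 * est.se
        assert abs(gc3.psi_hat - tm3.psi_hat) < 0.02


class TestSurvivalCurve:
    def test_cardinality_and_layout(self, toy2_panel):
        regs = [lt.static_regime([1, 1], "always"), lt.static_regime([0, 0], "never")]
        tab = lt.survival_curve(
            toy2_panel, regs, estimators=("naive", "gcomp", "tmle"),
            t_range=[1, 2], library=["saturated"], g_library=["saturated"],
        )
        assert len(tab) == 2 * 2 * 3
        assert tab.loc[tab.estimator == "gcomp", "se"].isna().all()
        assert tab.loc[tab.estimator == "tmle", "se"].notna().all()

    def test_deterministic_given_seed(self, toy2_panel):
        regs = [lt.static_regime([1, 1], "always")]
        kw = dict(estimators=("tmle",), t_range=[2], library=["logit_main"],
                  g_library=["logit_main"], seed=5)
        a = lt.survival_curve(toy2_panel, regs, **kw)
        b = lt.survival_curve(toy2_panel, regs, **kw)
        pd.testing.assert_frame_equal(a, b)
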