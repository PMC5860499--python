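"""Synthetic study generator, truth oracles and toy enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import longtmle as lt
from longtmle.exceptions import EstimationError


class TestChipLikeGenerator:
    def test_generated_panel_is_valid(self, chip_panel):
        assert lt.validate_panel(chip_panel).passed

    def test_deterministic_given_seed(self):
        a = lt.simulate_chip_like(lt.DGPSpec(), 300, seed=9)
        b = lt.simulate_chip_like(lt.DGPSpec(), 300, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        c = lt.simulate_chip_like(lt.DGPSpec(), 300, seed=10)
        assert not a.frame.equals(c.frame)

    def test_zero_discharge_hazard(self):
        spec = lt.DGPSpec()
        spec.discharge["intercept"] = -np.inf
        spec.discharge["vent"] = 0.0
        panel = lt.simulate_chip_like(spec, 200, seed=2)
        assert panel.y(7).sum() == 0

    def test_flow_structure(self, chip_panel):
        # patient-flow table: the three states partition the cohort each day
        n = chip_panel.n
        for t in range(1, 7):
            assert (
                lt.at_risk_mask(chip_panel, t).sum()
                + chip_panel.y(t).sum()
                + chip_panel.m(t).sum()
            ) == n
        assert 0 < chip_panel.m(6).sum() < 0.05 * n  # deaths rare
        assert chip_panel.y(7).mean() > 0.5  # most children discharged

    def test_time_varying_confounding_present(self, chip_panel):
        # ventilation predicts feeding, and feeding history predicts extubation
        risk = lt.at_risk_mask(chip_panel, 2) == 1
        vent = chip_panel.z(2, "vent")[risk]
        fed = chip_panel.a(2)[risk]
        assert fed[vent == 1].mean() > fed[vent == 0].mean() + 0.1


class TestTruthOracle:
    def test_null_feeding_effect(self, never_feed):
        spec = lt.DGPSpec()
        for block in (spec.discharge, spec.death, spec.vent_off):
            block["feed"] = 0.0
        always = lt.static_regime([1] * 7, "always")
        a = lt.true_psi_monte_carlo(spec, never_feed, 5, n_mc=100_000, seed=3)
        b = lt.true_psi_monte_carlo(spec, always, 5, n_mc=100_000, seed=4)
        assert abs(a.true_psi - b.true_psi) < 3 * np.hypot(a.mc_se, b.mc_se)

    def test_monotone_in_horizon(self, never_feed):
        spec = lt.DGPSpec()
        psis = [
            lt.true_psi_monte_carlo(spec, never_feed, t, n_mc=50_000, seed=6).true_psi
            for t in (1, 4, 7)
        ]
        assert psis[0] <= psis[1] <= psis[2]

    def test_one_period_closed_form(self):
        # only ventilation (constant 1 at entry) and feeding move the hazard:
        # psi(always, 1) = expit(b0 + b_vent + b_feed) exactly
        spec = lt.DGPSpec(T_plus_1=1)
        spec.discharge = {"intercept": -0.3, "vent": -1.0, "age_z": 0.0,
                          "rachs_z": 0.0, "ino_z": 0.0, "feed": 0.5}
        always = lt.static_regime([1], "always")
        rec = lt.true_psi_monte_carlo(spec, always, 1, n_mc=200_000, seed=8)
        assert rec.true_psi == pytest.approx(expit(-0.3 - 1.0 + 0.5), abs=3 * rec.mc_se)

    def test_naive_overstates_never_feed(self, never_feed):
        # confounding direction: unadjusted "never feed" exceeds the truth
        spec = lt.DGPSpec()
        truth = lt.true_psi_monte_carlo(spec, never_feed, 5, n_mc=100_000, seed=12)
        biases = []
        for r in range(3):
            panel = lt.simulate_chip_like(spec, 4000, seed=40 + r)
            biases.append(lt.naive_estimate(panel, never_feed, 5).psi_hat - truth.true_psi)
        assert min(biases) > 0.05

    def test_forced_panel_followers(self, never_feed):
        forced = lt.simulate_under_regime(lt.DGPSpec(), never_feed, 500, seed=13)
        assert (lt.follow_indicator(forced, never_feed, 6) == 1).all()


class TestToyEnumeration:
    def test_enumeration_matches_monte_carlo(self, toy2):
        reg = lt.static_regime([1, 1], "always")
        exact = toy2.true_psi(reg, 2)
        # large observational sample + empirical g-formula as the MC counterpart
        panel = toy2.sample(100_000, seed=14)
        emp = lt.gformula_exhaustive(panel, reg, 2)
        assert emp == pytest.approx(exact, abs=0.01)

    def test_confounded_toy_naive_differs_from_truth(self, toy2):
        reg = lt.static_regime([1, 1], "always")
        panel = toy2.sample(50_000, seed=15)
        naive = lt.naive_estimate(panel, reg, 2).psi_hat
        assert abs(naive - toy2.true_psi(reg, 2)) > 0.02

    def test_degenerate_tables_are_deterministic(self):
        dgp = lt.discrete_toy_dgp(1)
        dgp.p_l0 = 1.0
        dgp.p_a[0] = np.array([0.0, 1.0])
        dgp.p_y[0] = np.array([[0.0, 1.0], [0.0, 1.0]])
        panel = dgp.sample(50, seed=16)
        assert (panel.a(0) == 1).all() and (panel.y(1) == 1).all()

    def test_support_guard(self):
        with pytest.raises(EstimationError):
            lt.discrete_toy_dgp(4)

    def test_no_confounding_collapse(self):
        # outcome law free of treatment: oracle equals the marginal mean
        dgp = lt.discrete_toy_dgp(1)
        dgp.p_y[0] = np.array([[0.3, 0.3], [0.7, 0.7]])
        reg = lt.static_regime([1], "always")
        assert dgp.true_psi(reg, 1) == pytest.approx(0.5 * 0.3 + 0.5 * 0.7)
        panel = dgp.sample(5000, seed=17)
        emp = lt.gformula_exhaustive(panel, reg, 1)
        marg = panel.y(1).mean()
        assert abs(emp - marg) < 0.05


class TestEstimatorConsistency:
    def test_adjusted_estimators_near_truth_at_scale(self, never_feed):
        # large-sample check on the default law with well-specified learners;
        # averaged over a few panels so the check targets bias, not one
        # draw's sampling noise (the per-panel SE is itself close to 0.01)
        spec = lt.DGPSpec()
        truth = lt.true_psi_monte_carlo(spec, never_feed, 5, n_mc=400_000, seed=18)
        psis = {"iptw": [], "gcomp": [], "tmle": []}
        for r in range(4):
            panel = lt.simulate_chip_like(spec, 20_000, seed=19 + r)
            mech = lt.fit_treatment_mechanism(
                panel, never_feed, 5, library=["logit_main"], seed=1)
            psis["iptw"].append(lt.iptw_estimate(panel, never_feed, 5, mech).psi_hat)
            psis["gcomp"].append(lt.ice_gcomp_estimate(
                panel, never_feed, 5, library=["logit_main"], markov_order=2,
                seed=1)[0].psi_hat)
            psis["tmle"].append(lt.tmle_estimate(
                panel, never_feed, 5, mechanism=mech, library=["logit_main"],
                markov_order=2, seed=1)[0].psi_hat)
        for name, vals in psis.items():
            assert abs(np.mean(vals) - truth.true_psi) < 0.01, name
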