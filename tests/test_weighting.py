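"""Censoring-model and weight checks against closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

from ipcwsim.weighting import (MethodSpec, PositivityError,
                               build_censoring_risk_set,
                               compute_stabilised_weights,
                               compute_unstabilised_weights, compute_weights,
                               default_catalogue, fit_pooled_logistic,
                               mismeasure_covariates, parse_method_name,
                               predict_id_probability, _design,
                               _grouped_cumprod)
from ipcwsim.dgm import simulate_trial

from conftest import toy_panel


class TestMethodCatalogue:
    def test_default_catalogue_is_exactly_the_fourteen_methods(self):
        names = [m.name for m in default_catalogue()]
        expected = ["ITT", "PP"] + [
            f"IPCW{u}{s}" for u in "us"
            for s in ["L1L2", "L1", "L2", "L1L3L4L5", "L1L2L3L4L5", "L1*L2*"]]
        assert names == expected

    def test_itt_pp_carry_empty_sets_and_ipcw_nonempty(self):
        for m in default_catalogue():
            if m.kind in ("ITT", "PP"):
                assert m.covariates == ()
            else:
                assert m.covariates and m.baseline == ("B1", "B2", "B3")

    def test_star_flag_parsing(self):
        m = parse_method_name("IPCWsL1*L2*")
        assert m.covariates == ("L1*", "L2*") and m.stabilised

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            MethodSpec("x", "ITT", covariates=("L1",))
        with pytest.raises(ValueError):
            MethodSpec("x", "IPCW")
        with pytest.raises(ValueError):
            parse_method_name("IPCWxL1")


class TestRiskSet:
    def test_no_deviation_panel_keeps_all_followup_visits(self):
        panel = toy_panel([{"id": i, "visit": v} for i in range(3)
                           for v in range(9)])
        rs = build_censoring_risk_set(panel)
        assert len(rs) == 3 * 8 and (rs["visit"] >= 1).all()

    def test_first_deviation_visit_included_then_excluded(self):
        rows = []
        for v in range(6):
            c = 1 if v == 3 else 0
            rows.append({"id": 0, "visit": v, "C": c,
                         "C_to": int(v >= 3),
                         "first_id_visit": 3 if v >= 3 else np.inf})
        rs = build_censoring_risk_set(toy_panel(rows))
        assert list(rs["visit"]) == [1, 2, 3]
        assert list(rs["C"]) == [0, 0, 1]

    def test_row_count_matches_bruteforce_enumeration(self, base_panel):
        rs = build_censoring_risk_set(base_panel)
        count = 0
        for _, g in base_panel.groupby("id"):
            g = g.sort_values("visit")
            for _, r in g[g["visit"] >= 1].iterrows():
                prior = g[(g["visit"] < r["visit"]) & (g["C"] == 1)]
                if len(prior) == 0:
                    count += 1
        assert len(rs) == count

    def test_empty_risk_set_is_an_error(self):
        panel = toy_panel([{"id": 0, "visit": 0}])
        with pytest.raises(ValueError):
            build_censoring_risk_set(panel)


class TestPooledLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_pooled_logistic(np.ones((100, 1)), y)
        assert fit.converged
        assert np.isclose(fit.params[0], logit(0.3), atol=1e-8)

    def test_all_zero_response_flagged_as_separation(self):
        fit = fit_pooled_logistic(np.ones((50, 1)), np.zeros(50))
        assert fit.separation and "degenerate_response" in fit.flags

    def test_matches_independent_optimiser_to_1e6(self):
        """Two-covariate fit vs an independent Newton-type optimiser on the
        raw Bernoulli log-likelihood (n = 500)."""
        rng = np.random.default_rng(17)
        X = np.column_stack([np.ones(500), rng.normal(size=500),
                             rng.normal(size=500)])
        beta_true = np.array([-1.0, 0.8, -0.5])
        y = (rng.random(500) < expit(X @ beta_true)).astype(float)
        fit = fit_pooled_logistic(X, y)

        def nll(b):
            lp = X @ b
            return -(y * lp - np.logaddexp(0, lp)).sum()

        def grad(b):
            return -X.T @ (y - expit(X @ b))

        def hess(b):
            p = expit(X @ b)
            return X.T @ (X * (p * (1 - p))[:, None])

        orc = minimize(nll, np.zeros(3), jac=grad, hess=hess,
                       method="trust-ncg", tol=1e-14)
        assert np.allclose(fit.params, orc.x, atol=1e-6)

    def test_fitted_mean_equals_event_rate(self, base_panel):
        rs = build_censoring_risk_set(base_panel)
        rs = rs[rs["Z"] == 0]
        terms = ["B1", "B2", "B3", "L1", "L2", "visit"]
        fit = fit_pooled_logistic(_design(rs, terms), rs["C"].to_numpy())
        p = predict_id_probability(fit, rs, terms)
        assert p.min() > 0 and p.max() < 1
        assert np.isclose(p.mean(), rs["C"].mean(), atol=1e-8)

    def test_hand_computed_expit_on_three_rows(self):
        fit = fit_pooled_logistic(np.ones((10, 1)), np.r_[np.ones(5), np.zeros(5)])
        fit.params = np.array([0.4])  # fixed coefficients, arithmetic check
        df = pd.DataFrame({"x": [0.0, 1.0, -2.0]})
        fit2 = fit_pooled_logistic(
            np.column_stack([np.ones(4), [0, 1, 2, 3.0]]),
            np.array([0, 1, 0, 1.0]))
        fit2.params = np.array([0.5, -1.0])
        got = predict_id_probability(fit2, df, ["x"])
        assert np.allclose(got, expit(0.5 - 1.0 * df["x"].to_numpy()))


class TestWeights:
    def test_zero_probability_gives_unit_weights(self):
        assert np.array_equal(compute_unstabilised_weights(np.zeros(5)),
                              np.ones(5))

    def test_hand_arithmetic_unstabilised(self):
        assert np.allclose(compute_unstabilised_weights(np.array([0.2, 0.5])),
                           [1.25, 2.5])

    def test_hand_arithmetic_stabilised(self):
        got = compute_stabilised_weights(np.array([0.2, 0.5]),
                                         np.array([0.1, 0.1]))
        assert np.allclose(got, [0.9 / 0.8, (0.9 * 0.9) / (0.8 * 0.5)])

    def test_identical_numerator_denominator_gives_unit_stabilised(self):
        p = np.array([0.1, 0.3, 0.6])
        assert np.allclose(compute_stabilised_weights(p, p), 1.0)

    def test_positivity_violation_raises(self):
        with pytest.raises(PositivityError):
            compute_unstabilised_weights(np.array([0.5, 1.0]))

    @given(st.lists(st.floats(min_value=0, max_value=0.95), min_size=1,
                    max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_cumulative_equals_recursive_form(self, ps):
        p = np.asarray(ps)
        W = compute_unstabilised_weights(p)
        rec = np.empty_like(W)
        acc = 1.0
        for k, pk in enumerate(p):
            acc = acc / (1.0 - pk)
            rec[k] = acc
        assert np.allclose(W, rec, rtol=1e-12)

    @given(st.integers(1, 6), st.integers(1, 5))
    @settings(max_examples=40, deadline=None)
    def test_grouped_cumprod_matches_per_group_loop(self, n_groups, per):
        rng = np.random.default_rng(n_groups * 31 + per)
        x = rng.uniform(0.5, 2.0, size=n_groups * per)
        first = np.zeros(n_groups * per, bool)
        first[::per] = True
        got = _grouped_cumprod(x, first)
        expect = np.concatenate([np.cumprod(x[i * per:(i + 1) * per])
                                 for i in range(n_groups)])
        assert np.allclose(got, expect, rtol=1e-12)

    def test_stabilised_weights_average_near_one(self, base_panel):
        wt = compute_weights(base_panel, parse_method_name("IPCWsL1L2"))
        by_visit = wt.table.groupby("visit")["SW"].mean()
        assert np.all(np.abs(by_visit - 1.0) < 0.1)
        assert (wt.table["W"] >= 1.0 - 1e-12).all()
        assert (wt.table["SW"] > 0).all()

    def test_event_free_arm_gets_unit_weights(self, base_panel):
        wt = compute_weights(base_panel, parse_method_name("IPCWuL1L2"))
        assert wt.arms_with_events == (0,)
        exp_ids = base_panel.loc[base_panel["Z"] == 1, "id"].unique()
        exp_rows = wt.table[wt.table["id"].isin(exp_ids)]
        assert np.allclose(exp_rows["W"], 1.0) and np.allclose(exp_rows["p_hat"], 0)


class TestMismeasurement:
    def test_lag_definition(self):
        rows = [{"id": 0, "visit": v, "L1": float(10 + v), "L2": -float(v)}
                for v in range(4)]
        out = mismeasure_covariates(toy_panel(rows), ("L1", "L2"))
        assert list(out["L1*"]) == [10.0, 10.0, 11.0, 12.0]
        assert list(out["L2*"]) == [0.0, 0.0, -1.0, -2.0]

    def test_constant_trajectory_unchanged(self):
        rows = [{"id": 0, "visit": v, "L1": 3.14} for v in range(5)]
        out = mismeasure_covariates(toy_panel(rows), ("L1",))
        assert np.allclose(out["L1*"], 3.14)

    def test_delayed_covariates_attenuate_deviation_model(self, base_scenario):
        """Regressing deviation on the lagged confounders must attenuate the
        coefficients relative to the concurrent ones (measurement error)."""
        panel = simulate_trial(base_scenario, seed=55, n=60_000)
        work = mismeasure_covariates(panel, ("L1", "L2"))
        rs = build_censoring_risk_set(work)
        rs = rs[rs["Z"] == 0]
        terms_true = ["B1", "B2", "B3", "L1", "L2", "L4", "L5", "visit"]
        terms_star = ["B1", "B2", "B3", "L1*", "L2*", "L4", "L5", "visit"]
        f_true = fit_pooled_logistic(_design(rs, terms_true), rs["C"].to_numpy())
        f_star = fit_pooled_logistic(_design(rs, terms_star), rs["C"].to_numpy())
        i1 = terms_true.index("L1") + 1  # +1 for the intercept column
        assert abs(f_star.params[i1]) < abs(f_true.params[i1])


class TestConfoundingBalance:
    def test_weighting_restores_covariate_balance(self, base_scenario):
        """At each visit the weighted mean of the confounders among the
        uncensored must move toward the no-deviation counterfactual mean
        relative to the unweighted censored mean (control arm, large n)."""
        panel = simulate_trial(base_scenario, seed=77, n=40_000)
        ref = simulate_trial(base_scenario, seed=77, n=40_000, allow_id=False)
        wt = compute_weights(panel, parse_method_name("IPCWsL1L2"))
        ctl = panel[(panel["Z"] == 0) & (panel["C_to"] == 0)
                    & (panel["visit"] >= 1)]
        merged = ctl.merge(wt.table[["id", "visit", "SW"]], on=["id", "visit"])
        ref_ctl = ref[(ref["Z"] == 0) & (ref["visit"] >= 1)]
        improvements = 0
        for v in (4, 6, 8):
            m_ref = ref_ctl.loc[ref_ctl["visit"] == v, "L1"].mean()
            sub = merged[merged["visit"] == v]
            raw = sub["L1"].mean()
            wavg = np.average(sub["L1"], weights=sub["SW"])
            if abs(wavg - m_ref) < abs(raw - m_ref):
                improvements += 1
        assert improvements >= 2


class TestParameterRecovery:
    def test_censoring_model_recovers_generator_coefficients(self, base_scenario):
        """Fitting the deviation model with the generator's covariate set at
        n = 10^5 must recover the confounder coefficients within 3 SEs."""
        p = base_scenario.params
        panel = simulate_trial(p, seed=88, n=100_000)
        rs = build_censoring_risk_set(panel)
        rs = rs[rs["Z"] == 0]
        terms = ["B1", "B2", "B3", "L1", "L2", "L4", "L5", "visit"]
        fit = fit_pooled_logistic(_design(rs, terms), rs["C"].to_numpy(),
                                  columns=["const"] + terms)
        se = np.sqrt(np.diag(fit.cov))
        truth = {
            "const": p.theta0, "B1": p.theta3[0], "B2": p.theta3[1],
            "B3": p.theta3[2], "L1": p.theta4[0], "L2": p.theta4[1],
            "L4": p.theta4[3], "L5": p.theta4[4], "visit": p.theta1,
        }
        for j, name in enumerate(fit.columns):
            assert abs(fit.params[j] - truth[name]) <= 3 * se[j], name
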