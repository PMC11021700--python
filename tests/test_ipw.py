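"""Inverse-probability-weighting machinery, module by module."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from counterrisk import (GeneratorConfig, OutcomeParams, SelectionParams,
                         MSMFit, derive_treatment, eligible,
                         estimate_ipw_rr, expand_person_months,
                         fit_censoring_weights, fit_msm,
                         fit_selection_weights, fit_treatment_weights,
                         generate_cohort, get_scenario, marginal_survival,
                         rr_at_horizon)
from counterrisk._logistic import fit_logistic, rcs_basis
from counterrisk.ipw import SELECTION_COVARIATES


# ---------------------------------------------------------------------------
# the in-package logistic engine against statsmodels (independent oracle)

def test_logistic_engine_matches_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(0)
    n = 4_000
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    beta = np.array([-1.0, 0.5, -0.3, 0.8])
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    w = rng.uniform(0.5, 2.0, n)

    ours = fit_logistic(X, y, weights=w)
    ref = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
    np.testing.assert_allclose(ours.coef, ref.params, atol=1e-7)
    assert ours.llf == pytest.approx(ref.llf, abs=1e-6)
    assert ours.aic == pytest.approx(ref.aic, abs=1e-5)


def test_logistic_grouped_response_equivalence():
    """Collapsing identical covariate rows into weighted proportions leaves
    the ML estimate unchanged."""
    rng = np.random.default_rng(1)
    x = rng.integers(0, 3, 900).astype(float)
    y = (rng.random(900) < expit(-0.5 + 0.4 * x)).astype(float)
    X = np.column_stack([np.ones(900), x])
    full = fit_logistic(X, y)
    agg = pd.DataFrame({"x": x, "y": y}).groupby("x").agg(n=("y", "size"),
                                                          p=("y", "mean"))
    Xa = np.column_stack([np.ones(len(agg)), agg.index.to_numpy(float)])
    grouped = fit_logistic(Xa, agg.p.to_numpy(), weights=agg.n.to_numpy(float))
    np.testing.assert_allclose(full.coef, grouped.coef, atol=1e-9)


def test_rcs_basis_linear_in_tails():
    knots = np.array([0.0, 1.0, 2.0, 3.0])
    B = rcs_basis(np.array([-5.0, -4.0, 7.0, 8.0, 9.0]), knots)
    # below the first knot the basis is exactly 0; above the last it is
    # linear (vanishing second difference on an equally spaced grid)
    assert np.allclose(B[:2], 0.0)
    second_diff = B[4] - 2 * B[3] + B[2]
    assert np.allclose(second_diff, 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# selection weights

class TestSelectionWeights:
    def test_homogeneous_selection_gives_flat_weights(self):
        cfg = GeneratorConfig(n_participants=20_000, seed=31,
                              selection=SelectionParams(strength=0.0))
        c = generate_cohort(cfg)
        b = c.baseline
        included = b.id.isin(c.followups.id).to_numpy()
        _, w = fit_selection_weights(b, included)
        # fitted covariate coefficients are pure noise, so weights cluster
        # tightly around 1/p (bulk within ~10%, all within ~40%)
        flat = 1.0 / included.mean()
        assert w.mean() == pytest.approx(flat, rel=0.02)
        assert np.quantile(np.abs(w / flat - 1.0), 0.95) < 0.12
        assert np.all(np.abs(w / flat - 1.0) < 0.4)

    def test_weighting_restores_balance(self, default_cohort):
        """Weighted covariate means of the included match full-cohort means
        within 3 SEs; unweighted means do not (diabetes direction)."""
        b, f, _ = default_cohort
        included = b.id.isin(f.id).to_numpy()
        _, w = fit_selection_weights(b, included)
        full_diab = b.diabetes.mean()
        inc = b[included]
        raw_diab = inc.diabetes.mean()
        wv = w.to_numpy()
        weighted_diab = np.average(inc.diabetes, weights=wv)
        se = b.diabetes.std() / np.sqrt(len(inc))
        assert raw_diab > full_diab + 3 * se          # selection visible
        assert abs(weighted_diab - full_diab) < 4 * se  # and removed
        for col in ("age", "sbp", "tchdl"):
            se = b[col].std() / np.sqrt(len(inc))
            assert abs(np.average(inc[col], weights=wv) - b[col].mean()) < 4 * se


# ---------------------------------------------------------------------------
# stabilised treatment weights

class TestTreatmentWeights:
    def test_empty_confounder_set_gives_unit_weights(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"age": rng.uniform(30, 74, 200)})
        A = (rng.random(200) < 0.3).astype(float)
        _, sw = fit_treatment_weights(df, A, [])
        assert np.all(sw == 1.0)

    def test_two_stratum_contingency_oracle(self):
        """Saturated one-binary-confounder design: weights equal the
        hand-computed probability ratios.

        Stratum 1: 10 treated of 30; stratum 2: 30 treated of 40. Marginal
        Pr(A)=4/7, so stabilised weights are 12/7 and 9/14 in stratum 1,
        16/21 and 12/7 in stratum 2.
        """
        z = np.repeat([0.0, 1.0], [30, 40])
        A = np.concatenate([np.repeat([1.0, 0.0], [10, 20]),
                            np.repeat([1.0, 0.0], [30, 10])])
        df = pd.DataFrame({"diabetes": z})
        _, sw = fit_treatment_weights(df, A, ["diabetes"])
        expected = np.concatenate([
            np.repeat([(4 / 7) / (1 / 3), (3 / 7) / (2 / 3)], [10, 20]),
            np.repeat([(4 / 7) / (3 / 4), (3 / 7) / (1 / 4)], [30, 10])])
        np.testing.assert_allclose(sw, expected, rtol=1e-6)

    def test_mean_stabilised_weight_near_one(self, powered_cohort):
        b, f, _ = powered_cohort
        spec = get_scenario("I")
        elig = b[eligible(b, spec)].reset_index(drop=True)
        assign = derive_treatment(elig, f, spec)
        inc = elig.merge(assign, on="id").query("included")
        from counterrisk.ipw import CONFOUNDERS
        _, sw = fit_treatment_weights(inc, inc.A.to_numpy(), CONFOUNDERS["I"])
        assert abs(sw.mean() - 1.0) < 0.05

    def test_aic_pair_reported_and_chosen_is_lower(self, powered_cohort):
        b, f, _ = powered_cohort
        spec = get_scenario("I")
        elig = b[eligible(b, spec)].reset_index(drop=True)
        assign = derive_treatment(elig, f, spec)
        inc = elig.merge(assign, on="id").query("included")
        from counterrisk.ipw import CONFOUNDERS
        model, _ = fit_treatment_weights(inc, inc.A.to_numpy(), CONFOUNDERS["I"])
        assert np.isfinite(model.aic_linear) and np.isfinite(model.aic_spline)
        if model.chosen == "linear":
            assert model.aic_linear <= model.aic_spline
        else:
            assert model.aic_spline < model.aic_linear

    def test_positivity_warning_on_near_separation(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-4, 0.3, 200), rng.normal(4, 0.3, 200)])
        A = (x > 0).astype(float)
        A[:3] = 1.0  # avoid perfect separation, keep extreme probabilities
        df = pd.DataFrame({"age": x})
        with pytest.warns(RuntimeWarning, match="positivity|stabilised"):
            fit_treatment_weights(df, A, ["age"])

    def test_single_arm_rejected(self):
        df = pd.DataFrame({"age": np.arange(10.0)})
        with pytest.raises(ValueError, match="non-empty"):
            fit_treatment_weights(df, np.ones(10), ["age"])


# ---------------------------------------------------------------------------
# person-month expansion

class TestExpansion:
    def _frame(self, t_rem, event_type, a=0.0, idx=2.0):
        return pd.DataFrame({"id": np.arange(len(t_rem)), "A": a,
                             "index_time": idx,
                             "event_time": idx + np.asarray(t_rem),
                             "event_type": event_type})

    def test_event_at_month_three(self):
        pm = expand_person_months(self._frame([3.0], ["cvd"]))
        assert pm.k.tolist() == [0, 1, 2]
        assert pm.D.tolist() == [0, 0, 1]
        assert pm.C.tolist() == [0, 0, 0]

    def test_administrative_censoring_at_horizon(self):
        pm = expand_person_months(self._frame([60.0], ["admin_censor"]))
        assert len(pm) == 60 and pm.D.sum() == 0 and pm.C.iloc[-1] == 1

    def test_survivor_past_horizon_has_60_clean_rows(self):
        pm = expand_person_months(self._frame([75.0], ["admin_censor"]))
        assert len(pm) == 60 and pm.D.sum() == 0 and pm.C.sum() == 0

    def test_death_censors_mid_follow_up(self):
        pm = expand_person_months(self._frame([2.5], ["death_other"]))
        assert len(pm) == 3 and pm.C.tolist() == [0, 0, 1] and pm.D.sum() == 0

    def test_row_count_oracle(self, powered_cohort):
        """Total rows equal the independently computed sum of per-person
        month counts."""
        b, f, _ = powered_cohort
        spec = get_scenario("I")
        elig = b[eligible(b, spec)].reset_index(drop=True)
        assign = derive_treatment(elig, f, spec)
        inc = elig.merge(assign, on="id").query("included and event_time > index_time")
        pm = expand_person_months(inc)
        expected = int(np.ceil(np.minimum(
            inc.event_time - inc.index_time, 60)).sum())
        assert len(pm) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            expand_person_months(self._frame([-1.0], ["cvd"]))


# ---------------------------------------------------------------------------
# censoring weights

class TestCensoringWeights:
    def test_no_censoring_gives_exact_ones(self):
        inc = pd.DataFrame({"id": [0, 1], "A": [0.0, 1.0], "index_time": 1.0,
                            "event_time": [30.0, 90.0],
                            "event_type": ["cvd", "admin_censor"]})
        pm = expand_person_months(inc)
        cov = pd.DataFrame({"age": [50.0, 60.0], "diabetes": [0, 1]})
        model, sw = fit_censoring_weights(pm, cov, ["age", "diabetes"])
        assert np.all(sw == 1.0) and model.n_censoring_events == 0

    def test_random_censoring_weights_near_one(self):
        cfg = GeneratorConfig(n_participants=20_000, seed=41,
                              followup_prob_base=0.45,
                              outcome=OutcomeParams(death_rate_5yr=0.10))
        c = generate_cohort(cfg)
        spec = get_scenario("I")
        elig = c.baseline[eligible(c.baseline, spec)].reset_index(drop=True)
        assign = derive_treatment(elig, c.followups, spec)
        inc = elig.merge(assign, on="id").query("included and event_time > index_time")
        pm = expand_person_months(inc.reset_index(drop=True))
        from counterrisk.ipw import CONFOUNDERS
        _, sw = fit_censoring_weights(pm, inc.reset_index(drop=True),
                                      CONFOUNDERS["I"])
        assert sw[pm.k.to_numpy() == 0].min() == 1.0   # month-0 weight exact
        assert abs(sw.mean() - 1.0) < 0.05

    def test_informative_censoring_correction(self):
        """With dropout driven by the deprivation confounder, weighting the
        hazard model moves the untreated survival estimate toward the
        censoring-free truth."""
        kw = dict(
            n_participants=60_000, followup_prob_base=0.45,
            uptake_prob_base={"I": 0.5, "IIa": 0.2, "IIb": 0.25,
                              "IIIa": 0.15, "IIIb": 0.2})
        heavy = OutcomeParams(death_rate_5yr=0.35, death_covariate_coef=1.2,
                              b_nzdep=0.5)
        none = OutcomeParams(death_rate_5yr=1e-9, b_nzdep=0.5)
        spec = get_scenario("I")

        def untreated_survival(outcome, weighted):
            c = generate_cohort(GeneratorConfig(seed=43, outcome=outcome, **kw))
            res = estimate_ipw_rr(c.baseline, c.followups, spec, n_boot=0,
                                  seed=0)
            if not weighted:
                # crude: ignore censoring weights by re-fitting the MSM with
                # selection/treatment weights only
                from counterrisk.ipw import fit_msm as _fit
                elig = c.baseline[eligible(c.baseline, spec)].reset_index(drop=True)
                assign = derive_treatment(elig, c.followups, spec)
                inc = elig.merge(assign, on="id").query(
                    "included and event_time > index_time").reset_index(drop=True)
                pm = expand_person_months(inc)
                fit = _fit(pm, np.ones(len(pm)))
                return marginal_survival(fit, 0).s[-1]
            return res.curves[0].s[-1]

        truth = untreated_survival(none, weighted=True)
        with_w = untreated_survival(heavy, weighted=True)
        without_w = untreated_survival(heavy, weighted=False)
        assert abs(with_w - truth) < abs(without_w - truth)


# ---------------------------------------------------------------------------
# marginal structural model and survival

class TestMSM:
    def _pm_from_hazard(self, rng, n_person_months, betas):
        n_persons = n_person_months // 60
        rows = []
        for pid in range(n_persons):
            a = pid % 2
            for k in range(60):
                p = expit(betas[0] + betas[1] * k + betas[2] * a + betas[3] * a * k)
                d = rng.random() < p
                rows.append((pid, k, float(a), int(d), 0))
                if d:
                    break
        return pd.DataFrame(rows, columns=["id", "k", "A", "D", "C"])

    def test_constant_hazard_recovery(self):
        rng = np.random.default_rng(5)
        h = 0.004
        pm = self._pm_from_hazard(rng, 60_000, [logit(h), 0.0, 0.0, 0.0])
        fit = fit_msm(pm, np.ones(len(pm)))
        se = np.sqrt(np.diag(fit.cov))
        assert abs(fit.beta0 - logit(h)) < 3 * se[0]
        assert abs(fit.beta1) < 3 * se[1]
        assert abs(fit.beta2) < 3 * se[2]

    def test_known_parameter_recovery(self):
        rng = np.random.default_rng(6)
        true = [logit(0.003), 0.004, -0.5, 0.006]
        pm = self._pm_from_hazard(rng, 120_000, true)
        fit = fit_msm(pm, np.ones(len(pm)))
        se = np.sqrt(np.diag(fit.cov))
        for est, tru, s in zip(fit.beta, true, se):
            assert abs(est - tru) < 3 * s

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(7)
        pm = self._pm_from_hazard(rng, 30_000, [logit(0.004), 0.0, -0.3, 0.0])
        f1 = fit_msm(pm, np.ones(len(pm)))
        f2 = fit_msm(pm, np.full(len(pm), 3.7))
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)

    def test_invalid_weights_rejected(self):
        pm = pd.DataFrame({"id": [0], "k": [0], "A": [0.0], "D": [0], "C": [0]})
        with pytest.raises(ValueError, match="positive"):
            fit_msm(pm, np.array([-1.0]))


class TestMarginalSurvival:
    def test_zero_hazard_limit(self):
        fit = MSMFit(-40.0, 0.0, 0.0, 0.0)
        assert np.allclose(marginal_survival(fit, 1).s, 1.0)

    def test_constant_hazard_closed_form(self):
        h = 0.01
        fit = MSMFit(float(logit(h)), 0.0, 0.0, 0.0)
        s = marginal_survival(fit, 0).s
        assert abs(s[-1] - (1 - h) ** 60) < 1e-12

    def test_matches_independent_product_loop(self):
        fit = MSMFit(-5.5, 0.01, -0.4, 0.003)
        for level in (0, 1):
            s = marginal_survival(fit, level).s
            acc, expected = 1.0, [1.0]
            for k in range(60):
                acc *= 1 - expit(-5.5 + 0.01 * k - 0.4 * level + 0.003 * level * k)
                expected.append(acc)
            np.testing.assert_allclose(s, expected, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            fit = MSMFit(rng.uniform(-8, -3), rng.uniform(-0.01, 0.02),
                         rng.uniform(-1, 1), rng.uniform(-0.01, 0.01))
            s = marginal_survival(fit, int(rng.random() < 0.5)).s
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 0)
            assert np.all((s > 0) & (s <= 1))


class TestRRAtHorizon:
    def test_null_treatment_terms_give_rr_one(self):
        fit = MSMFit(-5.0, 0.005, 0.0, 0.0)
        assert rr_at_horizon(fit).rr == pytest.approx(1.0, abs=1e-12)

    def test_time_origin_invariance_under_constant_hazard(self):
        """Relabelling months k -> k + c with a compensating intercept shift
        leaves the RR unchanged only when the time terms vanish."""
        flat = MSMFit(-5.0, 0.0, -0.4, 0.0)
        # same model expressed at a shifted time origin: identical hazards
        assert rr_at_horizon(flat).rr == pytest.approx(
            rr_at_horizon(MSMFit(-5.0, 0.0, -0.4, 0.0)).rr)
        sloped = MSMFit(-5.0, 0.01, -0.4, 0.0)
        shifted = MSMFit(-5.0 + 0.01 * 5, 0.01, -0.4, 0.0)
        assert rr_at_horizon(sloped).rr != pytest.approx(
            rr_at_horizon(shifted).rr, abs=1e-6)

    def test_zero_untreated_risk_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rr_at_horizon(MSMFit(-40.0, 0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# the assembled estimator

class TestPipeline:
    def test_unconfounded_matches_crude_ratio(self):
        """No confounding, no selection, no censoring: the weighted estimate
        equals the crude from-index risk ratio up to hazard-model smoothing."""
        cfg = GeneratorConfig(
            n_participants=40_000, seed=47, confounding_strength=0.0,
            followup_prob_base=0.45,
            selection=SelectionParams(strength=0.0),
            uptake_prob_base={"I": 0.5, "IIa": 0.2, "IIb": 0.25,
                              "IIIa": 0.15, "IIIb": 0.2},
            outcome=OutcomeParams(death_rate_5yr=1e-9),
            admin_censor_months=120)
        c = generate_cohort(cfg)
        spec = get_scenario("I")
        res = estimate_ipw_rr(c.baseline, c.followups, spec, n_boot=0, seed=0)
        elig = c.baseline[eligible(c.baseline, spec)].reset_index(drop=True)
        assign = derive_treatment(elig, c.followups, spec)
        inc = elig.merge(assign, on="id").query("included and event_time > index_time")
        t_rem = inc.event_time - inc.index_time
        ev = ((inc.event_type == "cvd") & (t_rem <= 60)).astype(float)
        crude = ev[inc.A == 1].mean() / ev[inc.A == 0].mean()
        # same data, so the gap (weight noise + hazard-model smoothing)
        # must be well inside one Monte-Carlo SE of the crude log ratio
        e1, e0 = ev[inc.A == 1].sum(), ev[inc.A == 0].sum()
        se_log = np.sqrt(1 / e1 + 1 / e0)
        assert abs(np.log(res.effect.rr) - np.log(crude)) < 0.5 * se_log

    def test_single_binary_confounder_matches_standardization(self):
        """One binary confounder, saturated weight model: the weighted
        estimate agrees with brute-force stratified standardization
        within 0.01."""
        cfg = GeneratorConfig(
            n_participants=60_000, seed=53, confounding_strength=1.5,
            confounder_weights={"diabetes": 1.0},
            followup_prob_base=0.45,
            selection=SelectionParams(strength=0.0),
            uptake_prob_base={"I": 0.4, "IIa": 0.2, "IIb": 0.25,
                              "IIIa": 0.15, "IIIb": 0.2},
            outcome=OutcomeParams(death_rate_5yr=1e-9),
            admin_censor_months=120)
        c = generate_cohort(cfg)
        spec = get_scenario("I")
        elig = c.baseline[eligible(c.baseline, spec)].reset_index(drop=True)
        assign = derive_treatment(elig, c.followups, spec)
        inc = elig.merge(assign, on="id").query(
            "included and event_time > index_time").reset_index(drop=True)

        # brute-force standardization over the binary confounder
        t_rem = inc.event_time - inc.index_time
        ev = ((inc.event_type == "cvd") & (t_rem <= 60)).astype(float)
        risk = {a: 0.0 for a in (0, 1)}
        for z in (0, 1):
            g = inc.diabetes == z
            wz = g.mean()
            for a in (0, 1):
                risk[a] += wz * ev[g & (inc.A == a)].mean()
        standardized = risk[1] / risk[0]

        res = estimate_ipw_rr(c.baseline, c.followups, spec, n_boot=0,
                              seed=0, confounders=["diabetes"],
                              selection_covariates=["diabetes"])
        assert res.effect.rr == pytest.approx(standardized, abs=0.01)

    def test_point_estimate_and_ci_recover_truth(self):
        """A single well-powered replicate: estimate near the embedded true
        RR of 0.70 and a 200-replicate bootstrap interval covering it."""
        from counterrisk.validation import recovery_config
        c = generate_cohort(recovery_config(0.70, seed=59, n=40_000))
        res = estimate_ipw_rr(c.baseline, c.followups, get_scenario("I"),
                              n_boot=200, seed=60)
        assert abs(res.effect.rr - 0.70) < 0.20
        assert res.effect.ci_low <= 0.70 <= res.effect.ci_high
        assert res.diagnostics["mean_sw_treatment"] == pytest.approx(1.0, abs=0.05)

    def test_weight_truncation_changes_weights_only_when_on(self):
        cfg = GeneratorConfig(n_participants=15_000, seed=61,
                              followup_prob_base=0.45,
                              uptake_prob_base={"I": 0.4, "IIa": 0.2, "IIb": 0.25,
                                                "IIIa": 0.15, "IIIb": 0.2})
        c = generate_cohort(cfg)
        spec = get_scenario("I")
        plain = estimate_ipw_rr(c.baseline, c.followups, spec, n_boot=0, seed=0)
        trunc = estimate_ipw_rr(c.baseline, c.followups, spec, n_boot=0, seed=0,
                                truncate_percentiles=(10.0, 90.0))
        assert plain.effect.rr != trunc.effect.rr


def test_write_ipw_result_files(tmp_path):
    from counterrisk import GeneratorConfig, generate_cohort, get_scenario
    from counterrisk.ipw import write_ipw_result
    from counterrisk import estimate_ipw_rr
    import json

    cfg = GeneratorConfig(n_participants=8_000, seed=77, followup_prob_base=0.45,
                          uptake_prob_base={"I": 0.4, "IIa": 0.2, "IIb": 0.25,
                                            "IIIa": 0.15, "IIIb": 0.2})
    c = generate_cohort(cfg)
    res = estimate_ipw_rr(c.baseline, c.followups, get_scenario("I"),
                          n_boot=10, seed=1)
    paths = write_ipw_result(res, str(tmp_path))
    eff = json.loads(open(paths["effect"]).read())
    assert eff["method"] == "ipw" and eff["rr"] > 0
    w = pd.read_csv(paths["weights"])
    assert {"id", "selection_weight", "sw_treatment",
            "sw_censor_final"} <= set(w.columns)
    s = pd.read_csv(paths["survival"])
    assert set(s.level) == {0, 1} and s.month.max() == 60
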