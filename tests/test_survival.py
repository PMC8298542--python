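"""Survival machinery against independent hand-worked and search oracles."""

import numpy as np
import pandas as pd
import pytest

import mcascreen as m
from mcascreen.config import PipelineConfig
from mcascreen.synthetic import default_true_log_hr


class TestKaplanMeier:
    def test_all_censored_flat(self):
        km = m.km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_single_death(self):
        km = m.km_estimate([1, 2, 3, 4], [1, 0, 0, 0])
        assert km.survival_at(1) == pytest.approx(3 / 4)
        assert km.survival_at(0.5) == 1.0

    def test_hand_product_limit(self):
        """times (1+, 2, 3, 3, 4+): S(2) = 4/5 * 3/4 = 3/4 ... wait risk set
        at 2 is 4 (censor at 1 already out): S(2)=3/4; S(3)=3/4 * 1/3 = 1/4."""
        km = m.km_estimate([1, 2, 3, 3, 4], [0, 1, 1, 1, 0])
        assert km.survival_at(2) == pytest.approx(3 / 4)
        assert km.survival_at(3) == pytest.approx(1 / 4)
        assert km.survival_at(3.9) == pytest.approx(1 / 4)

    def test_last_value_equals_naive_product(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        km = m.km_estimate(t, e)
        # naive product over death times
        s = 1.0
        for ti in np.sort(t[e == 1]):
            n_i = np.sum(t >= ti)
            d_i = np.sum((t == ti) & (e == 1))
            s *= 1 - d_i / n_i
        assert km.survival[-1] == pytest.approx(s, abs=1e-10)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            m.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1] * 2
        g = [0] * 4 + [1] * 4
        res = m.logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_worked_example(self):
        """Group A deaths at 1,2; group B deaths at 3,4; O-E and variance
        accumulated per event time give chi-square 1.1667^2/0.4722 = 2.882."""
        res = m.logrank_test([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        assert res.statistic == pytest.approx(2.88, abs=0.01)
        assert res.df == 1

    def test_zero_group_error(self):
        with pytest.raises(ValueError):
            m.logrank_test([1, 2], [1, 1], [0, 0])

    def test_equals_cox_score_test_untied(self):
        """Classical equivalence: the log-rank statistic equals the score
        test of a single binary covariate Cox model at beta=0 (hand-computed
        U(0)^2 / I(0) over the risk sets; no ties)."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 40
            t = rng.exponential(10, n) + rng.random(n) * 1e-6
            e = rng.integers(0, 2, n)
            x = rng.integers(0, 2, n)
            if e.sum() == 0 or len(np.unique(x)) < 2:
                continue
            u = i_info = 0.0
            for ti in t[e == 1]:
                risk = t >= ti
                xb = x[risk].mean()
                xi = x[(t == ti) & (e == 1)][0]
                u += xi - xb
                i_info += x[risk].var()
            if i_info == 0:
                continue
            expected = u**2 / i_info
            res = m.logrank_test(t, e, x)
            assert res.statistic == pytest.approx(expected, rel=1e-6)


def breslow_grid_oracle(times, events, x, grid):
    """1-D grid search of the Breslow partial likelihood (no ties)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    best_b, best_ll = None, -np.inf
    for b in grid:
        ll = 0.0
        for i in range(len(times)):
            if events[i] == 1:
                risk = times >= times[i]
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
        if ll > best_ll:
            best_b, best_ll = b, ll
    return best_b


class TestCox:
    def test_symmetric_groups_hr_one(self):
        df = pd.DataFrame({"os_months": [1, 1, 2, 2], "death": [1, 1, 1, 1],
                           "x": [0, 1, 0, 1]})
        res = m.cox_fit(df, ["x"])
        assert res.hr("x") == pytest.approx(1.0, abs=1e-6)

    def test_toy_against_grid_search_oracle(self):
        """4 subjects, alternating exposure, deaths at 1..4: the partial-
        likelihood maximum is near beta=0.94; the production optimizer must
        match an independent grid search to 1e-3."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, int)
        x = np.array([1, 0, 1, 0])
        oracle = breslow_grid_oracle(t, e, x, np.arange(-0.5, 2.5, 1e-4))
        df = pd.DataFrame({"os_months": t, "death": e, "x": x})
        res = m.cox_fit(df, ["x"])
        beta = float(res.summary.loc["x", "coef"])
        assert beta == pytest.approx(0.94, abs=0.01)
        assert beta == pytest.approx(oracle, abs=1e-3)
        assert res.hr("x") == pytest.approx(np.exp(beta))

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"os_months": rng.exponential(10, 100),
                           "death": 1, "x": rng.integers(0, 2, 100)})
        res = m.cox_fit(df, ["x"])
        row = res.summary.loc["x"]
        assert row.ci_low <= row.hr <= row.ci_high
        assert res.n_events <= res.n

    def test_constant_covariate_named(self):
        df = pd.DataFrame({"os_months": [1, 2, 3], "death": [1, 1, 1],
                           "x": [1, 1, 1]})
        with pytest.raises(ValueError, match="x"):
            m.cox_fit(df, ["x"])


class TestStepwise:
    def _cohort(self, seed=0, n=400, conf_hr=3.0):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame({f"z{i}": rng.integers(0, 2, n) for i in range(5)})
        x["conf"] = rng.integers(0, 2, n)
        lp = np.log(conf_hr) * x["conf"]
        t = rng.exponential(1, n) / (0.05 * np.exp(lp))
        c = rng.uniform(10, 60, n)
        x["os_months"] = np.minimum(t, c)
        x["death"] = (t <= c).astype(int)
        return x

    def test_planted_confounder_selected(self):
        hits = sum("conf" in m.stepwise_select(
            self._cohort(seed=s), ["z0", "z1", "conf", "z2", "z3", "z4"])
            for s in range(10))
        assert hits == 10

    def test_no_candidate_returns_forced(self):
        df = self._cohort(seed=1, conf_hr=1.0)
        out = m.stepwise_select(df, [], forced_terms=["conf"])
        assert out == ["conf"]

    def test_deterministic(self):
        df = self._cohort(seed=2)
        cands = ["z0", "z1", "conf", "z2", "z3", "z4"]
        assert m.stepwise_select(df, cands) == m.stepwise_select(df, cands)


class TestSchoenfeld:
    def test_time_varying_effect_flagged_and_stratified(self):
        """A covariate whose hazard ratio decays over time violates PH; it
        must be flagged and moved to the strata of the refit model."""
        rng = np.random.default_rng(5)
        n = 800
        x = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n)
        # piecewise hazard for x=1: strong early excess, none later
        t = np.where(x == 1,
                     np.where(rng.random(n) < 0.75, rng.exponential(3, n),
                              20 + rng.exponential(30, n)),
                     rng.exponential(25, n))
        df = pd.DataFrame({"os_months": t, "death": 1, "x": x, "z": z})
        res = m.cox_fit(df, ["x", "z"])
        pvals, refit = m.schoenfeld_ph_check(res)
        assert pvals["x"] < 0.05
        assert "x" not in refit.summary.index
        assert any("x" in s for s in refit.strata)

    def test_ph_true_not_always_flagged(self):
        rng = np.random.default_rng(5)
        n = 300
        x = rng.integers(0, 2, n)
        t = rng.exponential(10, n) * np.exp(-0.5 * x)
        df = pd.DataFrame({"os_months": t, "death": 1, "x": x})
        res = m.cox_fit(df, ["x"])
        pvals, refit = m.schoenfeld_ph_check(res)
        assert set(pvals) == {"x"}


class TestCauseSpecificRelapse:
    def test_reduces_to_plain_cox_without_competing_deaths(self):
        rng = np.random.default_rng(6)
        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(10, n) * np.exp(-0.7 * x)
        df = pd.DataFrame({"os_months": 100.0, "death": 0,
                           "relapse_months": t, "relapse": 1, "x": x})
        cs = m.cause_specific_relapse(df, ["x"])
        plain = m.cox_fit(df, ["x"], duration_col="relapse_months",
                          event_col="relapse")
        assert cs.summary.loc["x", "coef"] == pytest.approx(
            plain.summary.loc["x", "coef"])

    def test_zero_relapse_error(self):
        df = pd.DataFrame({"os_months": [1.0, 2.0], "death": [1, 1],
                           "relapse_months": [1.0, 2.0], "relapse": [0, 0],
                           "x": [0, 1]})
        with pytest.raises(ValueError, match="zero relapse"):
            m.cause_specific_relapse(df, ["x"])

    def test_inconsistent_times_rejected(self):
        df = pd.DataFrame({"os_months": [1.0], "death": [1],
                           "relapse_months": [2.0], "relapse": [1], "x": [1]})
        with pytest.raises(ValueError, match="exceeds"):
            m.cause_specific_relapse(df, ["x"])


class TestRunOutcomeAnalysis:
    def test_prognostic_region_reported_with_ci_covering_truth(self):
        _, clin, truth = m.simulate_cohort(
            900, {"CNLOH_13q": 0.06},
            true_log_hr_map=default_true_log_hr({"CNLOH_13q": 1.0}), seed=17)
        mat = truth.indicators.copy()
        mat["n_calls"] = mat.sum(axis=1)
        rep = m.run_outcome_analysis(clin, mat, ["CNLOH_13q"], PipelineConfig(),
                                     candidate_covariates=["age_z", "male",
                                                           "kps_low"])
        os_rows = rep[rep.endpoint == "OS"]
        assert len(os_rows) >= 1
        row = os_rows.iloc[0]
        assert row.ci_low < np.exp(1.0) < row.ci_high

    def test_deterministic_report(self):
        _, clin, truth = m.simulate_cohort(
            400, {"CNLOH_13q": 0.08},
            true_log_hr_map=default_true_log_hr({"CNLOH_13q": 1.2}), seed=18)
        mat = truth.indicators.copy()
        mat["n_calls"] = mat.sum(axis=1)
        args = (clin, mat, ["CNLOH_13q"], PipelineConfig())
        kw = {"candidate_covariates": ["age_z", "kps_low"]}
        assert m.run_outcome_analysis(*args, **kw).equals(
            m.run_outcome_analysis(*args, **kw))

    def test_region_absent_from_stratum_logged_not_fatal(self):
        _, clin, truth = m.simulate_cohort(120, {"CNLOH_13q": 0.0}, seed=19)
        mat = truth.indicators.copy()
        mat["n_calls"] = 0
        rep = m.run_outcome_analysis(clin, mat, ["CNLOH_13q"], PipelineConfig())
        assert rep.empty
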