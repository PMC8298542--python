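"""Outcome machinery: Kaplan–Meier, log-rank screen, stepwise Cox models
with Schoenfeld diagnostics and stratification, and cause-specific relapse
analysis with death as competing risk.

The screening procedure mirrors registry practice for arm-level aberration
indicators: per remission stratum, every eligible region is screened with a
log-rank test on overall survival; significant regions enter a joint Cox
model together with stepwise-selected clinical covariates (entry p < 0.25,
stay p < 0.15, the region indicators never dropped); regions that stay
significant get final overall-survival and cause-specific relapse models,
with covariates violating proportional hazards (Schoenfeld score test)
moved to the stratification set and the model refit once.

Partial-likelihood fitting, the product-limit estimator, the log-rank test
and the Schoenfeld residual score test are delegated to lifelines (Efron
tie handling); tests cross-check them against independent hand-worked and
grid-search oracles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test

from .config import PipelineConfig

log = logging.getLogger("mcascreen")


# --------------------------------------------------------------------------
# Kaplan–Meier
# --------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit survival curve on an event-time grid (months)."""
    times: np.ndarray        # distinct event/censor times, ascending; 0 first
    survival: np.ndarray     # S(t) at those times, S(0) = 1
    at_risk: np.ndarray      # risk-set size just before each time
    n_events: np.ndarray     # deaths at each time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (value of the last step <= t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times, event_flags) -> KmCurve:
    """Kaplan–Meier estimate; censored subjects leave the risk set after
    their censoring time."""
    times = np.asarray(times, float)
    events = np.asarray(event_flags, int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter().fit(times, events)
    tab = kmf.event_table
    grid = np.concatenate([[0.0], tab.index.to_numpy(float)])
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return KmCurve(
        times=grid,
        survival=surv,
        at_risk=np.concatenate([[times.size], tab.at_risk.to_numpy(float)]),
        n_events=np.concatenate([[0], tab.observed.to_numpy(float)]),
        censor_times=np.sort(times[events == 0]),
    )


# --------------------------------------------------------------------------
# Log-rank
# --------------------------------------------------------------------------

@dataclass
class SurvivalTestResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(times, event_flags, group) -> SurvivalTestResult:
    """Two-group log-rank chi-square (1 df), deaths pooled at tied times."""
    times = np.asarray(times, float)
    events = np.asarray(event_flags, int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("log-rank test requires exactly two groups")
    a, b = group == labels[0], group == labels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a group has zero subjects")
    res = _ll_logrank(times[a], times[b], events[a], events[b])
    return SurvivalTestResult(float(res.test_statistic), 1, float(res.p_value))


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxResult:
    """A fitted Cox model: per-covariate estimates plus fit metadata."""
    summary: pd.DataFrame       # index covariate; coef, hr, ci_low, ci_high, p
    n: int
    n_events: int
    strata: tuple[str, ...]
    ties: str
    model: CoxPHFitter = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    duration_col: str = "os_months"
    event_col: str = "death"

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def cox_fit(data: pd.DataFrame, covariates: list[str],
            duration_col: str = "os_months", event_col: str = "death",
            strata: list[str] | None = None, ties: str = "efron") -> CoxResult:
    """Maximum partial-likelihood Cox fit with Wald CIs (Efron ties).

    Raises a non-identifiability error naming any constant covariate; a
    monotone likelihood (perfect separation) is reported as a warning by the
    optimizer and the capped estimate is returned.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    strata = list(strata or [])
    covariates = list(covariates)
    if not covariates:
        raise ValueError("at least one covariate required")
    sub = data[covariates + strata + [duration_col, event_col]].dropna()
    if sub[event_col].sum() < 1:
        raise ValueError("no events in data")
    for c in covariates:
        if sub[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant (non-identifiable)")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(sub, duration_col=duration_col, event_col=event_col,
                    strata=strata or None)
        except ConvergenceError:
            # monotone likelihood: refit with a light ridge to cap the estimate
            log.warning("Cox fit did not converge (possible separation); "
                        "refitting with a small penalizer")
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(sub, duration_col=duration_col, event_col=event_col,
                    strata=strata or None)
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "se": s["se(coef)"],
        "p": s["p"],
    })
    return CoxResult(summary=summary, n=len(sub),
                     n_events=int(sub[event_col].sum()),
                     strata=tuple(strata), ties=ties, model=cph, data=sub,
                     duration_col=duration_col, event_col=event_col)


# --------------------------------------------------------------------------
# Stepwise covariate selection
# --------------------------------------------------------------------------

def stepwise_select(data: pd.DataFrame, candidate_covariates: list[str],
                    p_enter: float = 0.25, p_stay: float = 0.15,
                    forced_terms: list[str] | None = None,
                    duration_col: str = "os_months", event_col: str = "death",
                    strata: list[str] | None = None,
                    max_steps: int = 50) -> list[str]:
    """Bidirectional stepwise Cox selection on Wald p-values.

    Forward step: the candidate with the smallest p below ``p_enter`` (ties
    broken by input order) joins the model; backward step: any selected,
    non-forced term with p above ``p_stay`` is dropped, worst first.
    ``forced_terms`` are always in the model and never dropped.
    Deterministic given the data.
    """
    forced = list(forced_terms or [])
    selected: list[str] = []
    candidates = [c for c in candidate_covariates if c not in forced]
    seen_states: set[frozenset] = set()

    def fit_p(cov_list: list[str]) -> CoxResult | None:
        try:
            return cox_fit(data, cov_list, duration_col, event_col, strata)
        except (ValueError, ConvergenceError):
            return None

    for _ in range(max_steps):
        state = frozenset(selected)
        if state in seen_states:   # enter/drop oscillation: stop
            break
        seen_states.add(state)
        changed = False
        # forward
        best: tuple[float, str] | None = None
        for c in candidates:
            if c in selected:
                continue
            res = fit_p(forced + selected + [c])
            if res is None:
                continue
            p = res.p(c)
            if p < p_enter and (best is None or p < best[0]):
                best = (p, c)
        if best is not None:
            selected.append(best[1])
            changed = True
        # backward
        while selected:
            res = fit_p(forced + selected)
            if res is None:
                selected.pop()
                changed = True
                continue
            ps = {c: res.p(c) for c in selected}
            worst = max(selected, key=lambda c: ps[c])
            if ps[worst] > p_stay:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return forced + selected


# --------------------------------------------------------------------------
# Proportional-hazards diagnostics
# --------------------------------------------------------------------------

def schoenfeld_ph_check(result: CoxResult, alpha_ph: float = 0.05,
                        protected: tuple[str, ...] = (),
                        ) -> tuple[dict[str, float], CoxResult]:
    """Score test on scaled Schoenfeld residuals vs. time, per covariate.

    Covariates with p < ``alpha_ph`` move from the covariate list to the
    stratification set (continuous ones are binned into quartiles first)
    and the model is refit once.  ``protected`` covariates (the exposure
    whose hazard ratio the model exists to estimate) are never moved.
    Returns (per-covariate p-values, model — refit if anything was flagged).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        test = proportional_hazard_test(result.model, result.data,
                                        time_transform="rank")
    pvals = {str(i): float(p) for i, p in test.summary["p"].items()}
    flagged = [c for c, p in pvals.items() if p < alpha_ph and c not in protected]
    if not flagged:
        return pvals, result
    covs = [c for c in result.summary.index if c not in flagged]
    if not covs:
        log.warning("all covariates flagged by PH check; keeping original model")
        return pvals, result
    data = result.data.copy()
    new_strata = list(result.strata)
    for c in flagged:
        if data[c].nunique() > 5:
            data[c + "_strat"] = pd.qcut(data[c], 4, labels=False, duplicates="drop")
            new_strata.append(c + "_strat")
        else:
            new_strata.append(c)
    refit = cox_fit(data, covs, result.duration_col, result.event_col,
                    strata=new_strata, ties=result.ties)
    return pvals, refit


# --------------------------------------------------------------------------
# Cause-specific relapse
# --------------------------------------------------------------------------

def cause_specific_relapse(data: pd.DataFrame, covariates: list[str],
                           strata: list[str] | None = None) -> CoxResult:
    """Cause-specific Cox model for relapse with death as competing risk.

    Relapse is the event; death without prior relapse censors at the death
    time; everyone else is administratively censored.  Requires the columns
    relapse / relapse_months (and os_months for consistency checks).
    """
    df = data.copy()
    if int(df["relapse"].sum()) == 0:
        raise ValueError("zero relapse events")
    bad = df[(df.relapse == 1) & (df.relapse_months > df.os_months + 1e-9)]
    if len(bad):
        raise ValueError("relapse_months exceeds os_months for a relapser")
    return cox_fit(df, covariates, duration_col="relapse_months",
                   event_col="relapse", strata=strata)


# --------------------------------------------------------------------------
# Full outcome screen (per-region hazard-ratio report)
# --------------------------------------------------------------------------

def _region_counts(sub: pd.DataFrame, region: str, event_col: str) -> dict:
    present = sub[sub[region] == 1]
    absent = sub[sub[region] == 0]
    return {
        "n_event_present": int(present[event_col].sum()),
        "n_present": len(present),
        "n_event_absent": int(absent[event_col].sum()),
        "n_absent": len(absent),
    }


def run_outcome_analysis(cohort: pd.DataFrame, indicator_matrix: pd.DataFrame,
                         eligible_regions: list[str],
                         config: PipelineConfig | None = None,
                         candidate_covariates: list[str] | None = None,
                         strata_col: str = "cr_status") -> pd.DataFrame:
    """Screen eligible regions for association with OS and relapse, per
    remission stratum; returns the final report table.

    Steps per stratum: (1) log-rank screen of each eligible region on OS
    (univariate Cox if configured); (2) significant regions enter a joint
    Cox model with the other significant regions and stepwise-selected
    clinical covariates; (3) regions still significant get final OS and
    cause-specific relapse models with Schoenfeld-driven stratification.
    """
    cfg = config or PipelineConfig()
    mat = indicator_matrix.drop(columns=["n_calls"], errors="ignore")
    overlap = [c for c in mat.columns if c in cohort.columns]
    df = cohort.drop(columns=overlap).merge(
        mat, left_on="patient_id", right_index=True, how="left")
    for r in eligible_regions:
        if r not in df.columns:
            df[r] = 0
        df[r] = df[r].fillna(0).astype(int)

    if candidate_covariates is None:
        default = ["age_z", "male", "kps_low", "graft_pb", "reduced_intensity",
                   "cmv_mismatch", "donor_age", "donor_male", "cohort",
                   "year_late", "tbi"]
        candidate_covariates = [c for c in default if c in df.columns]

    rows = []
    for stratum in sorted(df[strata_col].dropna().unique()):
        sub = df[df[strata_col] == stratum].reset_index(drop=True)
        # (1) univariate screen
        screen_p: dict[str, float] = {}
        for region in eligible_regions:
            carriers = int(sub[region].sum())
            if carriers == 0 or carriers == len(sub):
                log.info("stratum %s: region %s degenerate (carriers=%d), skipped",
                         stratum, region, carriers)
                continue
            try:
                if cfg.univariate_screen == "cox":
                    p = cox_fit(sub, [region]).p(region)
                else:
                    p = logrank_test(sub.os_months, sub.death, sub[region]).p_value
            except ValueError as exc:
                log.info("stratum %s: screen failed for %s (%s)", stratum, region, exc)
                continue
            screen_p[region] = p
        significant = [r for r, p in screen_p.items() if p < cfg.screen_alpha]
        if not significant:
            log.info("stratum %s: no region passed the univariate screen", stratum)
            continue

        # (2) joint model with clinical covariates
        usable_cands = [c for c in candidate_covariates if sub[c].nunique() > 1]
        if cfg.covariate_mode == "stepwise":
            selected = stepwise_select(sub, usable_cands, cfg.p_enter, cfg.p_stay,
                                       forced_terms=significant)
            clinical_covs = [c for c in selected if c not in significant]
        else:
            clinical_covs = usable_cands
        try:
            joint = cox_fit(sub, significant + clinical_covs)
        except ValueError as exc:
            log.warning("stratum %s: joint model failed (%s)", stratum, exc)
            continue
        surviving = [r for r in significant if joint.p(r) < cfg.screen_alpha]

        # (3) final per-region models
        for region in surviving:
            covs = [region] + clinical_covs
            os_fit = cox_fit(sub, covs)
            _, os_fit = schoenfeld_ph_check(os_fit, cfg.alpha_ph,
                                            protected=(region,))
            counts = _region_counts(sub, region, "death")
            rows.append({
                "stratum": stratum, "region": region, "endpoint": "OS",
                **counts,
                "hr": os_fit.hr(region),
                "ci_low": float(os_fit.summary.loc[region, "ci_low"]),
                "ci_high": float(os_fit.summary.loc[region, "ci_high"]),
                "p": os_fit.p(region),
                "screen_p": screen_p[region],
                "strata": ",".join(os_fit.strata),
            })
            try:
                rel_fit = cause_specific_relapse(sub, covs)
                _, rel_fit = schoenfeld_ph_check(rel_fit, cfg.alpha_ph,
                                                 protected=(region,))
                counts = _region_counts(sub, region, "relapse")
                rows.append({
                    "stratum": stratum, "region": region, "endpoint": "relapse",
                    **counts,
                    "hr": rel_fit.hr(region),
                    "ci_low": float(rel_fit.summary.loc[region, "ci_low"]),
                    "ci_high": float(rel_fit.summary.loc[region, "ci_high"]),
                    "p": rel_fit.p(region),
                    "screen_p": screen_p[region],
                    "strata": ",".join(rel_fit.strata),
                })
            except ValueError as exc:
                log.warning("stratum %s region %s: relapse model failed (%s)",
                            stratum, region, exc)
    cols = ["stratum", "region", "endpoint", "n_event_present", "n_present",
            "n_event_absent", "n_absent", "hr", "ci_low", "ci_high", "p",
            "screen_p", "strata"]
    return pd.DataFrame(rows, columns=cols)
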