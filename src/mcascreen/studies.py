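"""Reproducible simulation studies exercising the whole pipeline.

Each study generates data with the synthetic module's default study
conditions (array noise lrr_sd 0.15 / baf_sd 0.03, het rate 0.30, the
cell-fraction distribution with median 0.49), runs the production code
path, and reports operating characteristics against the known truth.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .config import PipelineConfig
from .pipeline import detect_cohort
from .survival import cox_fit, logrank_test, run_outcome_analysis, schoenfeld_ph_check
from .synthetic import (EventSpec, default_true_log_hr, make_arm_map,
                        make_probe_map, sample_cell_fraction, simulate_cohort,
                        simulate_sample, stable_seed)


def detection_study(n_samples: int = 100, n_chromosomes: int = 22,
                    probes_per_chromosome: int = 2000,
                    chrom_length_bp: int = 100_000_000,
                    seed: int = 0, config: PipelineConfig | None = None) -> dict:
    """Plant 1-3 mosaic events per sample (length 10-40 Mb, type uniform,
    cell fraction from the cohort distribution) and measure recovery.

    Returns sensitivity / false-call rate / type accuracy for scoreable
    events (f >= 0.2, >= 2 Mb, >= 50 AB probes), cell-fraction errors for
    recovered events with true f in [0.2, 0.9], and the median recovered
    cell fraction.
    """
    cfg = config or PipelineConfig(seed=seed)
    rng = np.random.default_rng(stable_seed(seed, "detection"))
    pm = make_probe_map(n_chromosomes, probes_per_chromosome, chrom_length_bp,
                        seed=stable_seed(seed, "probes"))
    amap = make_arm_map(n_chromosomes, chrom_length_bp)
    truth: dict[str, list[EventSpec]] = {}
    signals = []
    for i in range(n_samples):
        sid = f"S{i:04d}"
        n_ev = int(rng.integers(1, 4))
        chroms = rng.choice(np.arange(1, n_chromosomes + 1), n_ev, replace=False)
        evs = []
        for ch in chroms:
            length = int(rng.uniform(10e6, 40e6))
            start = int(rng.integers(1, chrom_length_bp - length))
            evs.append(EventSpec(str(ch), start, start + length - 1,
                                 str(rng.choice(synthetic.EVENT_TYPES)),
                                 float(sample_cell_fraction(rng, 1)[0])))
        truth[sid] = evs
        signals.append(simulate_sample(pm, evs, seed=stable_seed(seed, sid),
                                       sample_id=sid))
    calls = detect_cohort(signals, amap, cfg)
    res = synthetic.evaluate_detection(truth, calls,
                                       {s.sample_id: s for s in signals})
    fhat = [c.cell_fraction for cl in calls.values() for c in cl]
    res["median_recovered_cell_fraction"] = float(np.median(fhat)) if fhat else float("nan")
    res["n_samples"] = n_samples
    return res


def endpoint_recovery_study(n_replicates: int = 100, n_patients: int = 1000,
                            prevalence: float = 0.05, true_log_hr: float = 1.0,
                            seed: int = 0,
                            config: PipelineConfig | None = None) -> dict:
    """Replicate cohorts with one prognostic region; success = the region
    reaches the final report with an OS confidence interval covering the
    true hazard ratio.  Single remission stratum, so one report row per
    replicate.  Also reports the relapse-model CI coverage."""
    cfg = config or PipelineConfig()
    cov_model = synthetic.default_covariate_model()
    cov_model["advanced"] = {"type": "bernoulli", "p": 0.0}   # one stratum
    region = "CNLOH_13q"
    hr_true = float(np.exp(true_log_hr))
    n_cover = n_reported = 0
    n_cover_rel = n_reported_rel = 0
    cands = ["age_z", "male", "kps_low", "graft_pb", "cmv_mismatch"]
    for r in range(n_replicates):
        _, clin, truth = simulate_cohort(
            n_patients, {region: prevalence}, covariate_model=cov_model,
            true_log_hr_map=default_true_log_hr({region: true_log_hr}),
            seed=stable_seed(seed, "e2e", r))
        mat = truth.indicators.copy()
        mat["n_calls"] = mat.sum(axis=1)
        rep = run_outcome_analysis(clin, mat, [region], cfg,
                                   candidate_covariates=cands)
        os_rows = rep[(rep.endpoint == "OS") & (rep.region == region)]
        if len(os_rows):
            n_reported += 1
            row = os_rows.iloc[0]
            if row.ci_low <= hr_true <= row.ci_high:
                n_cover += 1
        rel_rows = rep[(rep.endpoint == "relapse") & (rep.region == region)]
        if len(rel_rows):
            n_reported_rel += 1
            row = rel_rows.iloc[0]
            if row.ci_low <= hr_true <= row.ci_high:
                n_cover_rel += 1
    return {
        "n_replicates": n_replicates,
        "reported_rate": n_reported / n_replicates,
        "coverage_rate": n_cover / n_replicates,
        "relapse_coverage_rate": (n_cover_rel / n_reported_rel
                                  if n_reported_rel else float("nan")),
    }


def null_screen_study(n_replicates: int = 100, n_patients: int = 500,
                      n_regions: int = 4, prevalence: float = 0.08,
                      seed: int = 0,
                      config: PipelineConfig | None = None) -> dict:
    """Cohorts where no region affects survival: the univariate log-rank
    screen should pass about ``screen_alpha`` of the region tests."""
    cfg = config or PipelineConfig()
    cov_model = synthetic.default_covariate_model()
    cov_model["advanced"] = {"type": "bernoulli", "p": 0.0}
    regions = [f"CNLOH_{c}q" for c in range(1, n_regions + 1)]
    log_hr = default_true_log_hr({r: 0.0 for r in regions})
    n_tests = n_pass = 0
    for r in range(n_replicates):
        _, clin, truth = simulate_cohort(
            n_patients, {r_: prevalence for r_ in regions},
            covariate_model=cov_model, true_log_hr_map=log_hr,
            seed=stable_seed(seed, "null", r))
        for region in regions:
            carriers = int(clin[region].sum())
            if carriers < cfg.min_patients or carriers == n_patients:
                continue
            p = logrank_test(clin.os_months, clin.death, clin[region]).p_value
            n_tests += 1
            n_pass += p < cfg.screen_alpha
    return {"n_tests": n_tests, "pass_rate": n_pass / n_tests}


def ph_calibration_study(n_replicates: int = 200, n_patients: int = 200,
                         alpha_ph: float = 0.05, seed: int = 0) -> dict:
    """Data generated under exact proportional hazards: the Schoenfeld
    score test should flag about ``alpha_ph`` of covariates."""
    n_tests = n_flag = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(stable_seed(seed, "ph", r))
        import pandas as pd
        x = rng.integers(0, 2, n_patients)
        z = rng.normal(0, 1, n_patients)
        t = rng.exponential(10, n_patients) * np.exp(-(0.5 * x + 0.3 * z))
        c = rng.uniform(5, 40, n_patients)
        df = pd.DataFrame({"os_months": np.minimum(t, c),
                           "death": (t <= c).astype(int), "x": x, "z": z})
        try:
            res = cox_fit(df, ["x", "z"])
            pvals, _ = schoenfeld_ph_check(res, alpha_ph=0.0)  # p-values only
        except ValueError:
            continue
        for p in pvals.values():
            n_tests += 1
            n_flag += p < alpha_ph
    return {"n_tests": n_tests, "flag_rate": n_flag / n_tests}
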