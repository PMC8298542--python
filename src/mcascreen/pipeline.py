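"""End-to-end orchestration: detect -> aggregate -> characteristics ->
survival, with a reproducible run manifest and a JSON-lines audit trail."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, event_calling, signal_io, signal_processing, survival
from .config import PipelineConfig
from .synthetic import (SampleSignal, make_arm_map, make_probe_map,
                        simulate_cohort, stable_seed)

log = logging.getLogger("mcascreen")


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

def detect_sample(signal: SampleSignal, arm_map: pd.DataFrame,
                  config: PipelineConfig | None = None,
                  lrr: np.ndarray | None = None,
                  audit: list | None = None) -> list[event_calling.AberrationCall]:
    """Run the per-sample detection chain: GC-wave correction, mirrored-BAF
    deviation, segmentation, classification, cell fraction, size/QC filter
    and arm annotation.  ``lrr`` overrides the sample's raw LRR (used after
    across-sample quantile normalization)."""
    cfg = config or PipelineConfig()
    raw = signal.lrr if lrr is None else np.asarray(lrr, float)
    gc = signal.probe_map.table.gc_fraction.to_numpy(float)
    corrected = signal_processing.gc_wave_correct(raw, gc, cfg.gc_method, cfg.gc_window)
    work = SampleSignal(signal.sample_id, corrected, signal.baf,
                        signal.genotype, signal.probe_map)
    series = signal_processing.build_deviation_series(work, min_het=cfg.min_het)
    breakpoints = {}
    for chrom, ds in series.items():
        if ds.low_information:
            continue
        breakpoints[chrom] = signal_processing.segment_series(
            ds.delta, ds.positions, alpha=cfg.seg_alpha,
            min_points=cfg.seg_min_points, n_permutations=cfg.seg_permutations,
            seed=stable_seed(cfg.seed, signal.sample_id, chrom))
    segments = signal_processing.summarize_segments(work, series, breakpoints)
    calls = event_calling.call_segments(segments, cfg)
    calls = event_calling.filter_calls(calls, cfg.min_length_bp, cfg.min_het,
                                       cfg.min_snps_lrr_only, audit=audit)
    for c in calls:
        event_calling.annotate_arm(c, arm_map)
    return calls


def detect_cohort(signals: list[SampleSignal], arm_map: pd.DataFrame,
                  config: PipelineConfig | None = None,
                  audit: list | None = None) -> dict[str, list]:
    """Detect events for every sample, after across-sample LRR quantile
    normalization (identity with a single sample)."""
    cfg = config or PipelineConfig()
    if len(signals) >= 2:
        mat = signal_processing.quantile_normalize_lrr(
            np.vstack([s.lrr for s in signals]))
    else:
        mat = np.vstack([s.lrr for s in signals])
    return {s.sample_id: detect_sample(s, arm_map, cfg, lrr=mat[i], audit=audit)
            for i, s in enumerate(signals)}


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_categoricals(df: pd.DataFrame) -> pd.DataFrame:
    """Presentation categories for characteristic comparisons, derived from
    the numeric covariates the generator emits."""
    out = df.copy()
    if "male" in out:
        out["sex"] = np.where(out.male == 1, "M", "F")
    if "kps_low" in out:
        out["kps_category"] = np.where(out.kps_low == 1, "<90", "90-100")
    if "graft_pb" in out:
        out["graft_type"] = np.where(out.graft_pb == 1, "PB", "BM")
    if "reduced_intensity" in out:
        out["conditioning_intensity"] = np.where(out.reduced_intensity == 1, "RIC", "MA")
    if "age" in out:
        out["age_group"] = pd.cut(out.age, [0, 18, 40, 60, 120],
                                  labels=["<=18", "18-40", "40-60", ">60"]).astype(str)
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and write the artifact directory.

    With no ``signal_dir`` configured, a synthetic cohort is simulated first
    (simulate-then-analyze mode).  Artifacts: signals/ (simulate mode),
    calls/, tables/, report/, manifest.txt and audit.jsonl.
    """
    cfg = config
    out = Path(cfg.out_dir)
    for sub in ("signals", "calls", "tables", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    audit_records: list[dict] = []

    def audit_event(stage: str, **counts) -> None:
        audit_records.append({"stage": stage, **counts})

    # --- inputs -------------------------------------------------------
    if cfg.signal_dir:
        arm_map = signal_io.read_arm_map(cfg.arm_map_path)
        clinical = signal_io.read_clinical(cfg.clinical_path)
        signals = []
        for p in sorted(Path(cfg.signal_dir).glob("*.tsv")):
            sig, _ = signal_io.read_signal_table(p)
            signals.append(sig)
        if not signals:
            raise FileNotFoundError(f"no signal TSVs under {cfg.signal_dir}")
    else:
        probe_map = make_probe_map(n_chromosomes=4, probes_per_chromosome=500,
                                   chrom_length_bp=80_000_000,
                                   seed=stable_seed(cfg.seed, "probes"))
        arm_map = make_arm_map(4, 80_000_000)
        signals, clinical, truth = simulate_cohort(
            n_patients=50,
            region_prevalences={"CNLOH_2q": 0.15, "LOSS_1p": 0.12},
            seed=stable_seed(cfg.seed, "cohort"),
            probe_map=probe_map, arm_map=arm_map)
        for s in signals:
            signal_io.write_signal_table(s, out / "signals" / f"{s.sample_id}.tsv")
        signal_io.write_arm_map(arm_map, out / "tables" / "arm_map.tsv")
        signal_io.write_clinical(clinical, out / "tables" / "clinical.csv")
    audit_event("input", n_samples=len(signals), n_probes=len(signals[0].probe_map),
                n_patients=len(clinical))

    # --- detection ----------------------------------------------------
    removed: list = []
    calls_by_patient = detect_cohort(signals, arm_map, cfg, audit=removed)
    n_calls = sum(len(v) for v in calls_by_patient.values())
    audit_event("detect", n_calls=n_calls, n_filtered_out=len(removed))
    for sid, calls in calls_by_patient.items():
        signal_io.write_calls_bed(calls, out / "calls" / f"{sid}.bed")

    # --- aggregation --------------------------------------------------
    matrix = cohort_stats.build_indicator_matrix(calls_by_patient)
    eligible = cohort_stats.screen_regions(matrix, cfg.min_patients)
    audit_event("aggregate", n_regions=len(matrix.columns) - 1,
                n_eligible=len(eligible))
    matrix.to_csv(out / "tables" / "indicators.csv", lineterminator="\n")
    freq = matrix.drop(columns="n_calls").sum(axis=0).rename("n_patients")
    freq.to_csv(out / "tables" / "frequency.csv", lineterminator="\n")
    bins = cohort_stats.count_bins(matrix.n_calls)
    bins.to_csv(out / "tables" / "bins.csv", index=False, lineterminator="\n")

    # --- characteristics ---------------------------------------------
    clin = _derive_categoricals(clinical)
    clin["aberration_present"] = clin.patient_id.map(
        (matrix.n_calls > 0).astype(int)).fillna(0).astype(int)
    characteristics = [c for c in ("age_group", "sex", "kps_category", "cr_status",
                                   "graft_type", "conditioning_intensity")
                       if c in clin.columns and clin[c].nunique() > 1]
    if clin.aberration_present.nunique() > 1 and characteristics:
        tests = cohort_stats.compare_characteristics(
            clin, "aberration_present", characteristics)
        rows = [{"characteristic": ch, "test": t.test, "statistic": t.statistic,
                 "p_value": t.p_value} for ch, t in tests.items()]
        pd.DataFrame(rows).to_csv(out / "tables" / "characteristics.csv",
                                  index=False, lineterminator="\n")
        audit_event("characteristics", n_tested=len(rows))

    # --- survival -----------------------------------------------------
    report = survival.run_outcome_analysis(clin, matrix, eligible, cfg)
    report.to_csv(out / "report" / "report.csv", index=False,
                  float_format="%.6g", lineterminator="\n")
    audit_event("survival", n_report_rows=len(report))
    for _, row in report[report.endpoint == "OS"].iterrows():
        sub = clin[clin.cr_status == row.stratum].merge(
            matrix[[row.region]], left_on="patient_id", right_index=True, how="left")
        sub[row.region] = sub[row.region].fillna(0).astype(int)
        for flag, tag in ((1, "present"), (0, "absent")):
            grp = sub[sub[row.region] == flag]
            if grp.empty:
                continue
            km = survival.km_estimate(grp.os_months, grp.death)
            pd.DataFrame({"time": km.times, "survival": km.survival,
                          "at_risk": km.at_risk}).to_csv(
                out / "report" / f"km_{row.stratum}_{row.region}_{tag}.csv",
                index=False, float_format="%.6g", lineterminator="\n")

    # --- manifest -----------------------------------------------------
    with open(out / "audit.jsonl", "w", encoding="utf-8", newline="\n") as fh:
        for rec in audit_records:
            fh.write(json.dumps(rec) + "\n")
    lines = ["[config]"]
    lines += [f"{k} = {v}" for k, v in sorted(config.to_dict().items())]
    lines.append("[checksums]")
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.txt":
            lines.append(f"{p.relative_to(out)} = {_sha256(p)}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out
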