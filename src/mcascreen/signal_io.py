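"""On-disk formats: array signal TSV, clinical CSV, arm map TSV, calls BED.

Coordinate conventions: signal tables and in-memory events are 1-based
inclusive; the calls BED output is 0-based half-open.  All text is UTF-8
with LF line endings.  Chromosome labels are normalized by stripping a
leading "chr"; only autosomes 1..22 are retained.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import AUTOSOMES, ProbeMap, SampleSignal

log = logging.getLogger("mcascreen")

SIGNAL_COLUMNS = ["SNP Name", "Chr", "Position", "B Allele Freq", "Log R Ratio"]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
               "n_snps", "n_het", "delta", "median_lrr", "cell_fraction", "arm"]

#: Categorical level inventory of the clinical table (unknown levels -> "missing").
CLINICAL_LEVELS = {
    "sex": {"M", "F"},
    "race": {"Caucasian", "African-American", "Asian", "Other", "missing"},
    "kps_category": {"90-100", "<90", "missing"},
    "cr_status": {"CR", "advanced"},
    "graft_type": {"BM", "PB"},
    "conditioning_intensity": {"MA", "RIC"},
    "gvhd_prophylaxis": {"TAC_MMF", "TAC_other", "CSA", "other_none"},
    "cmv_match": {"neg/neg", "neg/pos", "pos/pos", "pos/neg", "missing"},
    "donor_sex": {"M", "F"},
    "year_group": {"2000-2002", "2003-2005", "2006-2008", "2009-2011"},
}


def normalize_chrom(values) -> pd.Series:
    s = pd.Series(values, dtype="string").str.strip()
    return s.str.replace(r"^chr", "", regex=True, case=False)


# --------------------------------------------------------------------------
# Signal tables
# --------------------------------------------------------------------------

def read_signal_table(path, dialect: str = "auto") -> tuple[SampleSignal, pd.DataFrame]:
    """Read a GenomeStudio-final-report-like signal TSV.

    Accepts a bare TSV (header on line 1) or a "[Data]"-sectioned export;
    ``dialect`` may force "bare"/"sectioned".  Returns the sample signal and
    the probe-scaffold fragment (probe_id, chromosome, position) it carries.
    Non-autosomal rows are dropped (logged); BAF is clipped to [0, 1] with
    the out-of-range count logged; a missing GType column yields NC.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if dialect == "auto":
        dialect = "sectioned" if text.lstrip().startswith("[") else "bare"
    if dialect == "sectioned":
        lines = text.splitlines()
        try:
            start = next(i for i, ln in enumerate(lines) if ln.strip().lower() == "[data]")
        except StopIteration:
            raise ValueError(f"{path}: no [Data] section found")
        text = "\n".join(lines[start + 1:])
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"Chr": "string"})
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    bad = df[pd.to_numeric(df["Position"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"{path}: unparseable Position at line {bad.index[0] + 2}")
    for col in ("B Allele Freq", "Log R Ratio"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")]
        if len(bad):
            raise ValueError(f"{path}: unparseable {col} at line {bad.index[0] + 2}")
        df[col] = coerced

    df["Chr"] = normalize_chrom(df["Chr"])
    n0 = len(df)
    df = df[df["Chr"].isin(AUTOSOMES)].copy()
    if len(df) < n0:
        log.info("%s: dropped %d non-autosomal rows", path.name, n0 - len(df))
    df["Position"] = df["Position"].astype(np.int64)
    df["_chrnum"] = df["Chr"].astype(int)
    df = df.sort_values(["_chrnum", "Position"], kind="mergesort").reset_index(drop=True)

    baf = df["B Allele Freq"].to_numpy(float)
    n_clip = int(np.sum((baf < 0) | (baf > 1)))
    if n_clip:
        log.info("%s: clipped %d out-of-range BAF values", path.name, n_clip)
    baf = np.clip(baf, 0.0, 1.0)

    gtype = (df["GType"].fillna("NC").astype(str).to_numpy()
             if "GType" in df.columns else np.full(len(df), "NC"))

    probes = pd.DataFrame({
        "probe_id": df["SNP Name"].astype(str),
        "chromosome": df["Chr"].astype(str),
        "position": df["Position"],
        "gc_fraction": df["gc_fraction"].astype(float) if "gc_fraction" in df.columns else 0.5,
    })
    pm = ProbeMap(probes, min_probes=1)
    sig = SampleSignal(path.stem, df["Log R Ratio"].to_numpy(float), baf, gtype, pm)
    return sig, probes[["probe_id", "chromosome", "position"]]


def write_signal_table(signal: SampleSignal, path, sectioned: bool = False) -> None:
    """Write a sample as a signal TSV (optionally with a [Data] header section)."""
    pm = signal.probe_map.table
    df = pd.DataFrame({
        "SNP Name": pm.probe_id,
        "Chr": pm.chromosome,
        "Position": pm.position,
        "B Allele Freq": np.round(signal.baf, 6),
        "Log R Ratio": np.round(signal.lrr, 6),
        "GType": signal.genotype,
        "gc_fraction": np.round(pm.gc_fraction, 6),
    })
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if sectioned:
            fh.write("[Header]\nContent\tmcascreen signal export\n[Data]\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n", na_rep="")


# --------------------------------------------------------------------------
# Calls BED
# --------------------------------------------------------------------------

def write_calls_bed(calls, path) -> None:
    """Write aberration calls as a BED-like TSV (0-based half-open)."""
    rows = []
    for c in calls:
        rows.append({
            "chrom": str(c.chromosome),
            "start": int(c.start_bp) - 1,
            "end": int(c.end_bp),
            "name": c.event_type,
            "score": int(round(1000 * c.cell_fraction)),
            "strand": ".",
            "n_snps": int(c.n_snps),
            "n_het": int(c.n_het),
            "delta": round(float(c.delta), 6),
            "median_lrr": round(float(c.median_lrr), 6),
            "cell_fraction": round(float(c.cell_fraction), 6),
            "arm": ",".join(c.arm_labels),
        })
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    if len(df):
        df["_c"] = df.chrom.astype(int)
        df = df.sort_values(["_c", "start"], kind="mergesort").drop(columns="_c")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_calls_bed(path) -> pd.DataFrame:
    """Read a calls BED back into a table with 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": "string", "arm": "string"})
    df["start_bp"] = df["start"].astype(np.int64) + 1
    df["end_bp"] = df["end"].astype(np.int64)
    return df


# --------------------------------------------------------------------------
# Clinical table
# --------------------------------------------------------------------------

def read_clinical(path) -> pd.DataFrame:
    """Read and validate the clinical CSV (one row per patient).

    Categorical levels outside the documented inventory map to "missing"
    with a warning; duplicate patient ids and negative times are errors.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError("clinical table must have a patient_id column")
    dup = df.patient_id[df.patient_id.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id: {dup.iloc[0]}")
    for col in ("os_months", "relapse_months"):
        if col in df.columns and (df[col] < 0).any():
            raise ValueError(f"negative times in {col}")
    for col in ("death", "relapse"):
        if col in df.columns and not df[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
    if "cr_status" in df.columns and df["cr_status"].isna().any():
        raise ValueError("cr_status must be non-missing")
    for col, levels in CLINICAL_LEVELS.items():
        if col not in df.columns:
            continue
        vals = df[col].astype("string").fillna("missing")
        unknown = set(vals.unique()) - levels - {"missing"}
        if unknown:
            log.warning("clinical %s: unknown levels %s mapped to 'missing'",
                        col, sorted(unknown))
            vals = vals.where(vals.isin(levels), "missing")
        df[col] = vals
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# Arm map
# --------------------------------------------------------------------------

def read_arm_map(path) -> pd.DataFrame:
    """Read the arm definition TSV: chromosome, centromere_bp, length_bp."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": "string"})
    for col in ("chromosome", "centromere_bp", "length_bp"):
        if col not in df.columns:
            raise ValueError(f"arm map missing column {col!r}")
    df["chromosome"] = normalize_chrom(df["chromosome"])
    bad = df[(df.centromere_bp <= 0) | (df.centromere_bp >= df.length_bp)]
    if len(bad):
        raise ValueError(f"invalid centromere on chr{bad.chromosome.iloc[0]}")
    return df


def write_arm_map(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
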