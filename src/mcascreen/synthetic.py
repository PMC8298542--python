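"""Synthetic SNP-array signal and cohort generator with known truth.

Forward model
-------------
Mosaic events are simulated under the standard allelic-dosage mixture: a
fraction ``f`` of cells carries the event, the rest are diploid
heterozygous/homozygous.  At a heterozygous (AB) probe the expected B-allele
frequency (BAF) is the ratio of B-allele copies to total copies averaged
over the cell mixture, and the expected log R ratio (LRR) is log2 of total
copy number over 2:

==========  =============================  =====================
event       AB-probe BAF (one haplotype)   LRR
==========  =============================  =====================
CNLOH       (1 ± f)/2                      0
copy loss   1/(2-f)  or (1-f)/(2-f)        log2((2-f)/2)
copy gain   (1+f)/(2+f)  or  1/(2+f)       log2((2+f)/2)
==========  =============================  =====================

Which haplotype is affected is drawn per probe (no phasing), so the two BAF
bands are populated symmetrically; detection works on the mirrored
deviation |BAF - 0.5| and is insensitive to the sign.

The cohort generator draws arm-level event indicators per patient, plants
matching events in the array signal, and simulates overall survival and
relapse as two independent cause-specific exponential hazards under a
proportional-hazards linear predictor, with independent censoring.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_TYPES = ("GAIN", "LOSS", "CNLOH")

AUTOSOMES = tuple(str(c) for c in range(1, 23))


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GcWaveParams:
    """Shape of the synthetic local-GC track along each chromosome."""
    baseline: float = 0.41
    amplitude: float = 0.06
    period_bp: float = 3e6
    noise_sd: float = 0.02


@dataclass
class ProbeMap:
    """Ordered autosomal SNP scaffold shared by all samples.

    ``table`` has columns probe_id, chromosome, position, gc_fraction and is
    sorted by (chromosome number, position) with strictly increasing
    positions within each chromosome.
    """
    table: pd.DataFrame
    min_probes: int = 2   # fragments read from partial files may relax to 1

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "chromosome", "position", "gc_fraction"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"probe map missing columns: {sorted(missing)}")
        if ((t.gc_fraction < 0) | (t.gc_fraction > 1)).any():
            raise ValueError("gc_fraction outside [0, 1]")
        for chrom, sub in t.groupby("chromosome", sort=False):
            if len(sub) < self.min_probes:
                raise ValueError(f"chromosome {chrom} has < {self.min_probes} probes")
            if not np.all(np.diff(sub.position.to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on chr{chrom}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table.chromosome))

    def chrom_index(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero((self.table.chromosome == str(chromosome)).to_numpy())


@dataclass(frozen=True)
class EventSpec:
    """A planted mosaic event: closed 1-based interval and cell fraction."""
    chromosome: str
    start_bp: int
    end_bp: int
    event_type: str
    cell_fraction: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.start_bp < self.end_bp:
            raise ValueError("start_bp must be < end_bp")
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must lie in (0, 1]")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SampleSignal:
    """Per-probe LRR/BAF/genotype for one sample, aligned to a ProbeMap."""
    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray
    genotype: np.ndarray   # elements of {"AA","AB","BB","NC"}
    probe_map: ProbeMap

    def __post_init__(self) -> None:
        n = len(self.probe_map)
        if not (len(self.lrr) == len(self.baf) == len(self.genotype) == n):
            raise ValueError("signal arrays must match probe map length")


@dataclass
class CohortTruth:
    """Ground truth attached to a simulated cohort."""
    events_by_patient: dict[str, list[EventSpec]]
    indicators: pd.DataFrame        # patients x region columns, 0/1
    params: dict
    seed: int


# --------------------------------------------------------------------------
# Closed forms of the dosage model (shared with event_calling's inversion)
# --------------------------------------------------------------------------

def expected_baf_shift(event_type: str, f: float) -> float:
    """Noiseless mean deviation |BAF - 0.5| of in-event AB probes."""
    if event_type == "CNLOH":
        return f / 2.0
    if event_type == "LOSS":
        return f / (2.0 * (2.0 - f))
    if event_type == "GAIN":
        return f / (2.0 * (2.0 + f))
    raise ValueError(f"unknown event type {event_type!r}")


def expected_lrr(event_type: str, f: float, attenuation: float = 1.0) -> float:
    """Noiseless mean LRR inside an event at cell fraction ``f``."""
    if event_type == "CNLOH":
        return 0.0
    if event_type == "LOSS":
        return attenuation * math.log2((2.0 - f) / 2.0)
    if event_type == "GAIN":
        return attenuation * math.log2((2.0 + f) / 2.0)
    raise ValueError(f"unknown event type {event_type!r}")


# --------------------------------------------------------------------------
# Probe scaffold
# --------------------------------------------------------------------------

def make_probe_map(n_chromosomes: int = 22,
                   probes_per_chromosome: int = 2000,
                   chrom_length_bp: int = 100_000_000,
                   gc_wave_params: GcWaveParams | None = None,
                   seed: int = 0) -> ProbeMap:
    """Random-but-deterministic probe scaffold for ``n_chromosomes`` autosomes.

    Positions are uniform within each chromosome then sorted (duplicates
    nudged apart); gc_fraction is a smooth sinusoid of position plus noise,
    clipped to [0, 1].
    """
    if not 1 <= n_chromosomes <= 22:
        raise ValueError("n_chromosomes must be in [1, 22]")
    if probes_per_chromosome < 2:
        raise ValueError("probes_per_chromosome must be >= 2")
    if chrom_length_bp < probes_per_chromosome:
        raise ValueError("chrom_length_bp too small for probe count")
    gcp = gc_wave_params or GcWaveParams()
    rng = np.random.default_rng(seed)
    frames = []
    for ci in range(1, n_chromosomes + 1):
        pos = np.sort(rng.integers(1, chrom_length_bp + 1, size=probes_per_chromosome))
        # enforce strict increase (duplicates nudged forward)
        for _ in range(3):
            dup = np.flatnonzero(np.diff(pos) <= 0)
            if dup.size == 0:
                break
            pos[dup + 1] = pos[dup] + 1
        gc = (gcp.baseline
              + gcp.amplitude * np.sin(2 * np.pi * pos / gcp.period_bp)
              + rng.normal(0.0, gcp.noise_sd, size=pos.size))
        frames.append(pd.DataFrame({
            "probe_id": [f"rs{ci}_{i}" for i in range(pos.size)],
            "chromosome": str(ci),
            "position": pos.astype(np.int64),
            "gc_fraction": np.clip(gc, 0.0, 1.0),
        }))
    return ProbeMap(pd.concat(frames, ignore_index=True))


def make_arm_map(n_chromosomes: int = 22,
                 chrom_length_bp: int = 100_000_000,
                 centromere_frac: float = 0.4) -> pd.DataFrame:
    """Synthetic chromosome-arm definition table (chromosome, centromere, length)."""
    return pd.DataFrame({
        "chromosome": [str(c) for c in range(1, n_chromosomes + 1)],
        "centromere_bp": int(centromere_frac * chrom_length_bp),
        "length_bp": int(chrom_length_bp),
    })


# --------------------------------------------------------------------------
# Per-sample signal
# --------------------------------------------------------------------------

def _check_events(events: list[EventSpec], probe_map: ProbeMap) -> None:
    by_chrom: dict[str, list[EventSpec]] = {}
    chroms = set(probe_map.chromosomes)
    lengths = probe_map.table.groupby("chromosome").position.max()
    for ev in events:
        if ev.chromosome not in chroms:
            raise ValueError(f"event on chr{ev.chromosome} outside probe scaffold")
        if ev.start_bp < 1 or ev.end_bp > int(lengths[ev.chromosome]) * 2:
            raise ValueError(f"event {ev} outside scaffold coordinates")
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start_bp)
        for a, b in zip(evs, evs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(f"overlapping events on chr{chrom}: {a} / {b}")


def simulate_sample(probe_map: ProbeMap,
                    events: list[EventSpec] | None = None,
                    het_rate: float = 0.30,
                    lrr_sd: float = 0.15,
                    baf_sd: float = 0.03,
                    seed: int = 0,
                    sample_id: str = "S0",
                    lrr_attenuation: float = 1.0,
                    nc_rate: float = 0.0) -> SampleSignal:
    """Simulate one sample's LRR/BAF track with the planted ``events``.

    Genotypes are drawn AB with probability ``het_rate`` (AA/BB equally
    otherwise, NC with ``nc_rate``); Gaussian noise is added to both tracks
    and BAF is clipped to [0, 1].  Deterministic for a fixed seed.
    """
    events = list(events or [])
    if not 0 < het_rate < 1:
        raise ValueError("het_rate must be in (0, 1)")
    if lrr_sd < 0 or baf_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    _check_events(events, probe_map)

    rng = np.random.default_rng(seed)
    n = len(probe_map)
    chrom = probe_map.table.chromosome.to_numpy()
    pos = probe_map.table.position.to_numpy()

    u = rng.random(n)
    genotype = np.where(u < het_rate, "AB", np.where(u < het_rate + (1 - het_rate) / 2, "AA", "BB"))
    if nc_rate > 0:
        genotype[rng.random(n) < nc_rate] = "NC"

    baf_mean = np.where(genotype == "AB", 0.5, np.where(genotype == "BB", 1.0, 0.0))
    lrr_mean = np.zeros(n)

    for ev in events:
        mask = (chrom == ev.chromosome) & (pos >= ev.start_bp) & (pos <= ev.end_bp)
        lrr_mean[mask] = expected_lrr(ev.event_type, ev.cell_fraction, lrr_attenuation)
        het = mask & (genotype == "AB")
        idx = np.flatnonzero(het)
        b_affected = rng.random(idx.size) < 0.5   # which haplotype, per probe
        f = ev.cell_fraction
        if ev.event_type == "CNLOH":
            hi, lo = (1 + f) / 2, (1 - f) / 2
        elif ev.event_type == "LOSS":
            hi, lo = 1 / (2 - f), (1 - f) / (2 - f)
        else:  # GAIN
            hi, lo = (1 + f) / (2 + f), 1 / (2 + f)
        baf_mean[idx] = np.where(b_affected, hi, lo)

    lrr = lrr_mean + (rng.normal(0.0, lrr_sd, n) if lrr_sd > 0 else 0.0)
    baf = baf_mean + (rng.normal(0.0, baf_sd, n) if baf_sd > 0 else 0.0)
    baf = np.clip(baf, 0.0, 1.0)
    baf[genotype == "NC"] = np.nan
    return SampleSignal(sample_id, np.asarray(lrr, float), baf, genotype, probe_map)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

#: Quantile anchors of the planted cell-fraction distribution (u -> f).
CELL_FRACTION_QUANTILES = ((0.0, 0.20), (0.25, 0.29), (0.50, 0.49),
                           (0.75, 0.79), (1.0, 0.95))


def sample_cell_fraction(rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw cell fractions from the empirical-quantile model (median 0.49)."""
    q = np.array([a for a, _ in CELL_FRACTION_QUANTILES])
    v = np.array([b for _, b in CELL_FRACTION_QUANTILES])
    return np.interp(rng.random(size), q, v)


def region_column(arm_label: str, event_type: str) -> str:
    """Canonical indicator-column name for a (arm, event type) region."""
    return f"{event_type}_{arm_label}"


def default_covariate_model() -> dict:
    """Covariate generators emulating the clinical mix of an adult AML
    transplant registry cohort (ages, performance status, graft and
    conditioning distributions)."""
    return {
        "age": {"type": "normal", "mean": 48.0, "sd": 13.0, "lo": 1.0, "hi": 78.0},
        "male": {"type": "bernoulli", "p": 0.53},
        "kps_low": {"type": "bernoulli", "p": 0.29},
        "advanced": {"type": "bernoulli", "p": 0.27},
        "graft_pb": {"type": "bernoulli", "p": 0.69},
        "reduced_intensity": {"type": "bernoulli", "p": 0.30},
        "cmv_mismatch": {"type": "bernoulli", "p": 0.45},
        "tbi": {"type": "bernoulli", "p": 0.38},
        "donor_age": {"type": "normal", "mean": 34.0, "sd": 8.0, "lo": 18.0, "hi": 60.0},
        "donor_male": {"type": "bernoulli", "p": 0.67},
        "cohort": {"type": "bernoulli", "p": 0.5},
        "year_late": {"type": "bernoulli", "p": 0.6},
    }


def default_true_log_hr(region_log_hr: dict[str, float] | None = None) -> dict:
    """Cause-specific true log hazard ratios: clinical effects plus any
    region-indicator effects supplied by the caller."""
    base_os = {"advanced": math.log(2.2), "kps_low": math.log(1.5), "age_z": 0.20}
    base_rel = {"advanced": math.log(2.5), "kps_low": math.log(1.2)}
    for col, lhr in (region_log_hr or {}).items():
        base_os[col] = lhr
        base_rel[col] = lhr
    return {"os": base_os, "relapse": base_rel}


def _draw_covariates(n: int, model: dict, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, spec in model.items():
        kind = spec["type"]
        if kind == "normal":
            x = rng.normal(spec["mean"], spec["sd"], n)
            x = np.clip(x, spec.get("lo", -np.inf), spec.get("hi", np.inf))
        elif kind == "bernoulli":
            x = (rng.random(n) < spec["p"]).astype(int)
        else:
            raise ValueError(f"unknown covariate type {kind!r}")
        cols[name] = x
    df = pd.DataFrame(cols)
    if "age" in df:
        df["age_z"] = (df["age"] - df["age"].mean()) / max(df["age"].std(ddof=0), 1e-9)
    return df


def _linear_predictor(df: pd.DataFrame, log_hr: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(df))
    for col, b in log_hr.items():
        if col not in df.columns:
            raise KeyError(f"log-HR references unknown column {col!r}")
        lp += b * df[col].to_numpy(float)
    return lp


def _plant_events(indicators: pd.Series, arm_map: pd.DataFrame,
                  rng: np.random.Generator,
                  min_len: float = 5e6) -> list[EventSpec]:
    """Place one event per positive region indicator inside the named arm."""
    events: list[EventSpec] = []
    arm_rows = arm_map.set_index("chromosome")
    taken: dict[str, list[tuple[int, int]]] = {}
    for col, flag in indicators.items():
        if not flag:
            continue
        etype, arm = col.split("_", 1)
        chrom, side = arm[:-1], arm[-1]
        cen = int(arm_rows.loc[chrom, "centromere_bp"])
        length = int(arm_rows.loc[chrom, "length_bp"])
        lo, hi = (1, cen) if side == "p" else (cen + 1, length)
        span = hi - lo
        for _ in range(20):
            ev_len = int(rng.uniform(min_len, 0.8 * span))
            start = int(rng.integers(lo, hi - ev_len))
            end = start + ev_len - 1
            if all(end < s or start > e for s, e in taken.get(chrom, [])):
                break
        else:
            continue
        taken.setdefault(chrom, []).append((start, end))
        f = float(sample_cell_fraction(rng, 1)[0])
        events.append(EventSpec(chrom, start, end, etype, f))
    return events


def simulate_cohort(n_patients: int,
                    region_prevalences: dict[str, float],
                    covariate_model: dict | None = None,
                    true_log_hr_map: dict | None = None,
                    baseline_hazard: float = 0.022,
                    censoring_model: dict | None = None,
                    competing_risk_params: dict | None = None,
                    seed: int = 0,
                    probe_map: ProbeMap | None = None,
                    arm_map: pd.DataFrame | None = None,
                    signal_kwargs: dict | None = None,
                    ) -> tuple[list[SampleSignal], pd.DataFrame, CohortTruth]:
    """Simulate a transplant cohort with arm-level aberration indicators.

    Death and relapse times come from two independent cause-specific
    exponential hazards (rates ``baseline_hazard`` and
    ``competing_risk_params['relapse_baseline_hazard']``, in events/month)
    scaled by exp(linear predictor) from ``true_log_hr_map['os']`` /
    ``['relapse']``.  Relapse is observed only if it precedes death and
    censoring; death without prior relapse is the competing event.  Array
    signals are generated only when ``probe_map`` is given.

    Returns (signals, patients table, truth).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if true_log_hr_map is not None and not true_log_hr_map:
        raise ValueError("true_log_hr_map must not be empty")
    for k, p in region_prevalences.items():
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence for {k} outside [0, 1]")

    rng = np.random.default_rng(seed)
    cov_model = covariate_model or default_covariate_model()
    df = _draw_covariates(n_patients, cov_model, rng)
    df.insert(0, "patient_id", [f"P{i:05d}" for i in range(n_patients)])

    region_cols = list(region_prevalences)
    for col in region_cols:
        df[col] = (rng.random(n_patients) < region_prevalences[col]).astype(int)

    log_hr = true_log_hr_map or default_true_log_hr(
        {c: 0.0 for c in region_cols})
    lp_os = _linear_predictor(df, log_hr.get("os", {}))
    lp_rel = _linear_predictor(df, log_hr.get("relapse", {}))

    crp = competing_risk_params or {}
    relapse_rate = float(crp.get("relapse_baseline_hazard", 0.018))
    t_death = rng.exponential(1.0, n_patients) / (baseline_hazard * np.exp(lp_os))
    t_relapse = rng.exponential(1.0, n_patients) / (relapse_rate * np.exp(lp_rel))

    cm = censoring_model or {"type": "uniform", "lo": 60.0, "hi": 220.0}
    kind = cm.get("type", "none")
    if kind == "none":
        t_cens = np.full(n_patients, np.inf)
    elif kind == "uniform":
        t_cens = rng.uniform(cm.get("lo", 60.0), cm.get("hi", 220.0), n_patients)
    elif kind == "exponential":
        t_cens = rng.exponential(1.0 / cm["rate"], n_patients)
    elif kind == "immediate":
        t_cens = np.zeros(n_patients)
    else:
        raise ValueError(f"unknown censoring model {kind!r}")

    os_months = np.minimum(t_death, t_cens)
    death = (t_death <= t_cens).astype(int)
    relapse = ((t_relapse < t_death) & (t_relapse <= t_cens)).astype(int)
    relapse_months = np.where(relapse == 1, t_relapse, os_months)

    df["os_months"] = os_months
    df["death"] = death
    df["relapse_months"] = relapse_months
    df["relapse"] = relapse
    df["cr_status"] = np.where(df.get("advanced", 0) == 1, "advanced", "CR")

    signals: list[SampleSignal] = []
    events_by_patient: dict[str, list[EventSpec]] = {}
    if probe_map is not None:
        amap = arm_map if arm_map is not None else make_arm_map(
            n_chromosomes=len(probe_map.chromosomes),
            chrom_length_bp=int(probe_map.table.position.max() * 1.02))
        skw = dict(signal_kwargs or {})
        for i, pid in enumerate(df.patient_id):
            evs = _plant_events(df.loc[i, region_cols], amap, rng) if region_cols else []
            events_by_patient[pid] = evs
            sub_seed = int(rng.integers(0, 2**31 - 1))
            signals.append(simulate_sample(probe_map, evs, seed=sub_seed,
                                           sample_id=pid, **skw))
        # indicators reflect what was actually planted
        for col in region_cols:
            etype, arm = col.split("_", 1)
            chrom, side = arm[:-1], arm[-1]
            planted = [
                any(e.chromosome == chrom and e.event_type == etype for e in evs)
                for evs in events_by_patient.values()]
            df[col] = np.asarray(planted, int)

    truth = CohortTruth(
        events_by_patient=events_by_patient,
        indicators=df.set_index("patient_id")[region_cols].copy() if region_cols
        else pd.DataFrame(index=df.patient_id),
        params={
            "region_prevalences": dict(region_prevalences),
            "true_log_hr_map": {k: dict(v) for k, v in log_hr.items()},
            "baseline_hazard": baseline_hazard,
            "relapse_baseline_hazard": relapse_rate,
            "censoring_model": dict(cm),
        },
        seed=seed,
    )
    return signals, df, truth


# --------------------------------------------------------------------------
# Detection evaluation against planted truth
# --------------------------------------------------------------------------

def evaluate_detection(truth_by_sample: dict[str, list[EventSpec]],
                       calls_by_sample: dict[str, list],
                       signals: dict[str, SampleSignal] | None = None,
                       min_f: float = 0.2,
                       min_length_bp: float = 2e6,
                       min_het_probes: int = 50) -> dict:
    """Score calls against planted events.

    An event is *scoreable* if f >= min_f, length >= min_length_bp and (when
    signals are given) it spans >= min_het_probes AB probes.  A call matches
    an event when they share a chromosome and the overlap covers >= 50% of
    the event.  A call is false when its overlap with every planted event
    (any type, any size) covers < 50% of the call.

    Returns sensitivity, false calls per sample, type accuracy among
    matches, and the per-match cell-fraction errors.
    """
    n_scoreable = n_recovered = n_type_ok = n_false = 0
    f_errors: list[float] = []
    f_pairs: list[tuple[float, float]] = []
    n_samples = max(len(calls_by_sample), 1)
    for sid, events in truth_by_sample.items():
        calls = calls_by_sample.get(sid, [])
        sig = signals.get(sid) if signals else None
        for ev in events:
            if ev.cell_fraction < min_f or ev.length_bp < min_length_bp:
                continue
            if sig is not None:
                pm = sig.probe_map.table
                in_ev = ((pm.chromosome == ev.chromosome)
                         & (pm.position >= ev.start_bp)
                         & (pm.position <= ev.end_bp)).to_numpy()
                if int((sig.genotype[in_ev] == "AB").sum()) < min_het_probes:
                    continue
            n_scoreable += 1
            best = None
            for c in calls:
                if str(c.chromosome) != ev.chromosome:
                    continue
                ov = min(c.end_bp, ev.end_bp) - max(c.start_bp, ev.start_bp) + 1
                if ov >= 0.5 * ev.length_bp and (best is None or ov > best[0]):
                    best = (ov, c)
            if best is not None:
                n_recovered += 1
                call = best[1]
                if call.event_type == ev.event_type:
                    n_type_ok += 1
                    f_errors.append(abs(call.cell_fraction - ev.cell_fraction))
                    f_pairs.append((ev.cell_fraction, call.cell_fraction))
        for c in calls:
            clen = c.end_bp - c.start_bp + 1
            ok = any(
                str(c.chromosome) == ev.chromosome
                and min(c.end_bp, ev.end_bp) - max(c.start_bp, ev.start_bp) + 1
                >= 0.5 * clen
                for ev in events)
            if not ok:
                n_false += 1
    return {
        "n_scoreable": n_scoreable,
        "sensitivity": n_recovered / n_scoreable if n_scoreable else float("nan"),
        "type_accuracy": n_type_ok / n_recovered if n_recovered else float("nan"),
        "false_calls_per_sample": n_false / n_samples,
        "cell_fraction_errors": f_errors,
        "cell_fraction_pairs": f_pairs,
    }


def stable_seed(*parts) -> int:
    """Deterministic sub-seed (< 2**31) derived from arbitrary parts."""
    h = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
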