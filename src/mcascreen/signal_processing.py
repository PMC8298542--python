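"""LRR normalization, GC-wave correction and mirrored-BAF segmentation.

The detection signal for allelic imbalance is the mirrored B-allele
frequency deviation Δ_i = |BAF_i - 0.5| at heterozygous (AB) probes, which
folds the two symmetric BAF bands of a mosaic event onto one axis.  The Δ
series of each chromosome is segmented by recursive binary segmentation: a
candidate split maximizes the two-sample t statistic over all positions and
is accepted when its permutation p-value falls below ``alpha`` and both
children retain ``min_points`` probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import SampleSignal

log = logging.getLogger("mcascreen")


# --------------------------------------------------------------------------
# Quantile normalization of LRR across samples
# --------------------------------------------------------------------------

def quantile_normalize_lrr(lrr_matrix: np.ndarray) -> np.ndarray:
    """Map each sample's LRR values to the across-sample mean order statistics.

    Rows are samples, columns probes.  With a single sample the transform is
    the identity (logged); after normalization every sample shares the same
    sorted value vector.
    """
    m = np.asarray(lrr_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a samples x probes matrix")
    if m.shape[0] < 2:
        log.info("quantile normalization skipped: single sample (identity)")
        return m.copy()
    order = np.argsort(m, axis=1, kind="stable")
    ref = np.sort(m, axis=1).mean(axis=0)
    out = np.empty_like(m)
    rows = np.arange(m.shape[0])[:, None]
    out[rows, order] = ref[None, :]
    return out


# --------------------------------------------------------------------------
# GC / CpG wave correction
# --------------------------------------------------------------------------

def gc_wave_correct(lrr: np.ndarray, gc_fraction: np.ndarray,
                    method: str = "lowess", window: int = 1001) -> np.ndarray:
    """Remove the GC-dependent LRR wave: corrected = lrr - ĝ(gc).

    ``ĝ`` is a smooth fit of LRR on local GC content — a LOWESS
    (local-linear) smoother with a ``window``-probe span by default, or a
    global linear fit (``method="linear"``).  Constant GC degenerates to
    centering on the global mean.
    """
    lrr = np.asarray(lrr, float)
    gc = np.asarray(gc_fraction, float)
    if lrr.shape != gc.shape:
        raise ValueError("lrr and gc_fraction must be aligned")
    if np.nanmin(gc) < 0 or np.nanmax(gc) > 1:
        raise ValueError("gc_fraction outside [0, 1]")
    if np.ptp(gc) < 1e-12:
        return lrr - np.nanmean(lrr)
    if method == "linear":
        b1, b0 = np.polyfit(gc, lrr, 1)
        return lrr - (b0 + b1 * gc)
    if method == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess
        frac = min(1.0, window / len(lrr))
        ghat = lowess(lrr, gc, frac=frac, it=1,
                      delta=0.005 * np.ptp(gc), return_sorted=False)
        return lrr - ghat
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# Mirrored-BAF deviation series
# --------------------------------------------------------------------------

@dataclass
class DeviationSeries:
    """Δ = |BAF - 0.5| at the informative (AB) probes of one chromosome."""
    chromosome: str
    probe_indices: np.ndarray   # global indices into the probe map
    positions: np.ndarray       # base-pair positions of those probes
    delta: np.ndarray           # values in [0, 0.5]
    low_information: bool = False

    def __len__(self) -> int:
        return len(self.delta)


def build_deviation_series(sample: SampleSignal, het_source: str = "gtype",
                           min_het: int = 10) -> dict[str, DeviationSeries]:
    """Per-chromosome Δ series from the sample's AB probes.

    ``het_source`` selects heterozygous probes from the genotype column
    (default) or by BAF in [0.25, 0.75] (``"baf"``; unreliable for high-f
    events).  Chromosomes with fewer than ``min_het`` AB probes are flagged
    low-information and carry an empty series.
    """
    pm = sample.probe_map.table
    if het_source == "gtype":
        het = sample.genotype == "AB"
    elif het_source == "baf":
        het = (sample.baf >= 0.25) & (sample.baf <= 0.75)
    else:
        raise ValueError(f"unknown het_source {het_source!r}")
    het = het & ~np.isnan(sample.baf) & (sample.genotype != "NC")
    out: dict[str, DeviationSeries] = {}
    chrom_arr = pm.chromosome.to_numpy()
    pos_arr = pm.position.to_numpy()
    for chrom in sample.probe_map.chromosomes:
        on = chrom_arr == chrom
        idx = np.flatnonzero(on & het)
        low = idx.size < min_het
        if low:
            log.info("sample %s chr%s: %d AB probes (<%d) — low information",
                     sample.sample_id, chrom, idx.size, min_het)
        out[chrom] = DeviationSeries(
            chromosome=chrom,
            probe_indices=idx,
            positions=pos_arr[idx],
            delta=np.abs(sample.baf[idx] - 0.5),
            low_information=low,
        )
    return out


# --------------------------------------------------------------------------
# Recursive binary segmentation with permutation testing
# --------------------------------------------------------------------------

def _split_scan(v: np.ndarray, min_points: int) -> tuple[int, float]:
    """Argmax of the pooled two-sample t statistic over all admissible splits.

    Returns (k, |t|) where the left child is v[:k].  (-1, 0.0) when no
    admissible split exists.
    """
    n = v.size
    if n < 2 * min_points:
        return -1, 0.0
    cs = np.cumsum(v)
    css = np.cumsum(v * v)
    k = np.arange(min_points, n - min_points + 1)
    nl, nr = k, n - k
    ml = cs[k - 1] / nl
    mr = (cs[-1] - cs[k - 1]) / nr
    ssl = css[k - 1] - nl * ml**2
    ssr = (css[-1] - css[k - 1]) - nr * mr**2
    pooled = np.maximum(ssl + ssr, 0.0) / max(n - 2, 1)
    denom = np.sqrt(np.maximum(pooled * (1.0 / nl + 1.0 / nr), 1e-300))
    t = np.abs(ml - mr) / denom
    j = int(np.argmax(t))
    return int(k[j]), float(t[j])


def _perm_pvalue(v: np.ndarray, t_obs: float, min_points: int,
                 n_permutations: int, alpha: float,
                 rng: np.random.Generator, block: int = 250) -> float:
    """Permutation p-value of the max-|t| split statistic.

    Permutations run in blocks; iteration stops as soon as the exceedance
    count already forces the final p-value to be >= alpha (the accept/reject
    decision is identical to running all permutations).
    """
    n = v.size
    exceed = 0
    done = 0
    reject_bound = alpha * (1 + n_permutations) - 1  # exceed > bound => p >= alpha
    k = np.arange(min_points, n - min_points + 1)
    nl = k.astype(float)
    nr = (n - k).astype(float)
    inv = 1.0 / nl + 1.0 / nr
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perm = rng.permuted(np.broadcast_to(v, (b, n)).copy(), axis=1)
        cs = np.cumsum(perm, axis=1)
        css = np.cumsum(perm * perm, axis=1)
        ml = cs[:, k - 1] / nl
        mr = (cs[:, -1:] - cs[:, k - 1]) / nr
        ssl = css[:, k - 1] - nl * ml**2
        ssr = (css[:, -1:] - css[:, k - 1]) - nr * mr**2
        pooled = np.maximum(ssl + ssr, 0.0) / max(n - 2, 1)
        t = np.abs(ml - mr) / np.sqrt(np.maximum(pooled * inv, 1e-300))
        exceed += int(np.sum(t.max(axis=1) >= t_obs))
        done += b
        if exceed > reject_bound:
            return 1.0  # decision-equivalent: p would be >= alpha
    return (1 + exceed) / (1 + n_permutations)


def segment_series(values: np.ndarray, positions: np.ndarray | None = None,
                   alpha: float = 0.01, min_points: int = 10,
                   n_permutations: int = 1000, seed: int = 0) -> list[int]:
    """Breakpoints of a Δ series by recursive binary segmentation.

    Each breakpoint ``k`` starts a new segment at series index ``k``.  A
    split is accepted iff its permutation p-value < ``alpha`` and both
    children keep at least ``min_points`` points.  Deterministic for a
    fixed seed.
    """
    v = np.asarray(values, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("series values must be finite")
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    rng = np.random.default_rng(seed)
    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = v[lo:hi]
        k, t_obs = _split_scan(seg, min_points)
        if k < 0 or t_obs <= 0:
            return
        p = _perm_pvalue(seg, t_obs, min_points, n_permutations, alpha, rng)
        if p < alpha:
            breakpoints.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, v.size)
    return sorted(breakpoints)


# --------------------------------------------------------------------------
# Segment summaries
# --------------------------------------------------------------------------

@dataclass
class Segment:
    """A contiguous chromosome piece with its BAF/LRR summaries."""
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int        # all probes spanned
    n_het: int         # AB probes spanned
    delta: float       # mean Δ over AB probes (0 when none)
    median_lrr: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.n_het > self.n_snps:
            raise ValueError("n_het cannot exceed n_snps")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def summarize_segments(sample: SampleSignal,
                       series: dict[str, DeviationSeries],
                       breakpoints: dict[str, list[int]]) -> list[Segment]:
    """Turn per-chromosome breakpoints into contiguous Segment summaries.

    Segment boundaries sit on probe positions: a breakpoint at series index
    k starts a segment at the position of that AB probe, and the previous
    segment ends at the last probe before it.  Low-information chromosomes
    yield one whole-chromosome segment with delta = 0 (eligible only for
    LRR-only rules downstream).
    """
    pm = sample.probe_map.table
    chrom_arr = pm.chromosome.to_numpy()
    pos_arr = pm.position.to_numpy()
    segments: list[Segment] = []
    for chrom in sample.probe_map.chromosomes:
        on = np.flatnonzero(chrom_arr == chrom)
        cpos = pos_arr[on]
        ds = series.get(chrom)
        bps = [] if ds is None or ds.low_information else sorted(breakpoints.get(chrom, []))
        if ds is None or ds.low_information or len(ds) == 0:
            lrr = sample.lrr[on]
            n_het = int(len(ds)) if ds is not None else 0
            segments.append(Segment(chrom, int(cpos[0]), int(cpos[-1]),
                                    int(on.size), n_het, 0.0,
                                    float(np.median(lrr))))
            continue
        cuts = [0] + bps + [len(ds)]
        for a, b in zip(cuts[:-1], cuts[1:]):
            if a == b:
                continue
            if a == 0:
                start = int(cpos[0])
            else:
                start = int(ds.positions[a])
            if b == len(ds):
                end = int(cpos[-1])
            else:
                # last probe strictly before the next segment's first AB probe
                nxt = ds.positions[b]
                end = int(cpos[np.searchsorted(cpos, nxt) - 1])
            span = on[(cpos >= start) & (cpos <= end)]
            lrr = sample.lrr[span]
            segments.append(Segment(
                chromosome=chrom,
                start_bp=start,
                end_bp=end,
                n_snps=int(span.size),
                n_het=int(b - a),
                delta=float(np.mean(ds.delta[a:b])),
                median_lrr=float(np.median(lrr)),
            ))
    return segments
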