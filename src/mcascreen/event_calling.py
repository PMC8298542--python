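"""Classify segments into GAIN / LOSS / CNLOH, estimate clonal cell
fraction, apply the size filter and annotate chromosome arms.

Classification follows the LRR/BAF logic of array-based mosaic event
detection: allelic imbalance (mean Δ above ``delta_min``) with neutral LRR
is copy-neutral LOH; imbalance with raised LRR is a gain; depressed LRR is
a loss (callable from LRR alone when heterozygous support is missing, as
happens when a near-complete clone removes AB probes).

The cell fraction f is the inverse of the allelic-dosage forward model:

    CNLOH:  f = 2Δ          LOSS:  f = 4Δ/(1+2Δ)        GAIN:  f = 4Δ/(1-2Δ)

with Δ the mean |BAF - 0.5| of in-event AB probes; estimates are clipped to
(0, 1].  For LRR-only loss calls f is inverted from the LRR level instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .signal_processing import Segment

log = logging.getLogger("mcascreen")


@dataclass
class AberrationCall:
    """A classified mosaic aberration with cell fraction and arm labels."""
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    delta: float
    median_lrr: float
    event_type: str
    cell_fraction: float
    arm_labels: tuple[str, ...] = ()

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def classify_segment(segment: Segment, config: PipelineConfig | None = None) -> str:
    """Decide GAIN/LOSS/CNLOH/NORMAL for one segment.

    Rules, in order: (a) Δ >= delta_min with |median LRR| <= lambda_neutral
    -> CNLOH; (b) Δ >= delta_min with median LRR >= lambda_gain -> GAIN;
    (c) median LRR <= -lambda_loss -> LOSS (no BAF support required);
    (d) NORMAL.  Segments below ``min_het`` AB probes may only take the
    LRR-only loss route (c).
    """
    cfg = config or PipelineConfig()
    baf_informative = segment.n_het >= cfg.min_het
    if baf_informative and segment.delta >= cfg.delta_min:
        if abs(segment.median_lrr) <= cfg.lambda_neutral:
            return "CNLOH"
        if segment.median_lrr >= cfg.lambda_gain:
            return "GAIN"
    if segment.median_lrr <= -cfg.lambda_loss:
        return "LOSS"
    return "NORMAL"


def estimate_cell_fraction(event_type: str, delta: float) -> float:
    """Invert the dosage model: mean AB-probe deviation Δ -> cell fraction."""
    if not 0 <= delta <= 0.5:
        raise ValueError("delta must lie in [0, 0.5]")
    if delta == 0:
        raise ValueError("cell fraction undefined at delta = 0")
    if event_type == "CNLOH":
        f = 2.0 * delta
    elif event_type == "LOSS":
        f = 4.0 * delta / (1.0 + 2.0 * delta)
    elif event_type == "GAIN":
        f = 1.0 if delta >= 1.0 / 6.0 else 4.0 * delta / (1.0 - 2.0 * delta)
    else:
        raise ValueError(f"unknown event type {event_type!r}")
    return min(max(f, 1e-9), 1.0)


def estimate_cell_fraction_from_lrr(event_type: str, median_lrr: float) -> float:
    """Cell fraction from the LRR level alone (used for LRR-only loss calls)."""
    if event_type == "LOSS":
        f = 2.0 * (1.0 - 2.0 ** median_lrr)
    elif event_type == "GAIN":
        f = 2.0 * (2.0 ** median_lrr - 1.0)
    else:
        raise ValueError("LRR-based fraction only defined for LOSS/GAIN")
    if f <= 0:
        raise ValueError("LRR level inconsistent with the called type")
    return min(f, 1.0)


def call_segments(segments: list[Segment],
                  config: PipelineConfig | None = None) -> list[AberrationCall]:
    """Classify every segment and attach a cell-fraction estimate."""
    cfg = config or PipelineConfig()
    calls: list[AberrationCall] = []
    for seg in segments:
        etype = classify_segment(seg, cfg)
        if etype == "NORMAL":
            continue
        if etype == "LOSS" and seg.n_het < cfg.min_het:
            f = estimate_cell_fraction_from_lrr("LOSS", seg.median_lrr)
        else:
            f = estimate_cell_fraction(etype, seg.delta)
        calls.append(AberrationCall(
            chromosome=seg.chromosome, start_bp=seg.start_bp, end_bp=seg.end_bp,
            n_snps=seg.n_snps, n_het=seg.n_het, delta=seg.delta,
            median_lrr=seg.median_lrr, event_type=etype, cell_fraction=f))
    return calls


def filter_calls(calls: list[AberrationCall],
                 min_length_bp: int = 2_000_000,
                 min_het: int = 10,
                 min_snps_lrr_only: int = 30,
                 audit: list | None = None) -> list[AberrationCall]:
    """Apply the size filter and the automated QC surrogates for manual review.

    Calls shorter than ``min_length_bp`` are removed; BAF-supported calls
    need ``min_het`` AB probes ("low_het_support"); LRR-only loss calls need
    ``min_snps_lrr_only`` spanned probes ("low_probe_support").  Removals
    are logged with their reason (and appended to ``audit`` when given).
    """
    kept: list[AberrationCall] = []
    for c in calls:
        reason = None
        if c.length_bp < min_length_bp:
            reason = "short"
        elif c.event_type in ("CNLOH", "GAIN") and c.n_het < min_het:
            reason = "low_het_support"
        elif c.event_type == "LOSS" and c.n_het < min_het and c.n_snps < min_snps_lrr_only:
            reason = "low_probe_support"
        if reason is None:
            kept.append(c)
        else:
            log.info("filtered %s chr%s:%d-%d (%s)", c.event_type, c.chromosome,
                     c.start_bp, c.end_bp, reason)
            if audit is not None:
                audit.append((c, reason))
    return kept


def annotate_arm(call: AberrationCall, arm_map: pd.DataFrame) -> tuple[str, ...]:
    """Label the arm(s) a call touches: p, q, or both when it spans the
    centromere (such a call counts toward both arm indicators downstream)."""
    rows = arm_map.loc[arm_map.chromosome == str(call.chromosome)]
    if rows.empty:
        raise KeyError(f"chromosome {call.chromosome} not in arm map")
    cen = int(rows.centromere_bp.iloc[0])
    chrom = str(call.chromosome)
    if call.end_bp <= cen:
        labels = (f"{chrom}p",)
    elif call.start_bp > cen:
        labels = (f"{chrom}q",)
    else:
        labels = (f"{chrom}p", f"{chrom}q")
    call.arm_labels = labels
    return labels
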