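"""Patient-level aggregation: region indicator matrix, eligibility screen,
event-count bins and baseline-characteristic comparison tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import region_column


def build_indicator_matrix(calls_by_patient: dict[str, list],
                           region_keys: list[tuple[str, str]] | None = None,
                           ) -> pd.DataFrame:
    """Binary patients x regions matrix plus a per-patient total call count.

    A region is a (arm label, event type) pair; entry (p, k) is 1 iff the
    patient carries at least one filtered call of that type whose arm
    labels include that arm (a centromere-spanning call therefore sets both
    arms).  When ``region_keys`` is None, the observed regions are used.
    """
    if region_keys is None:
        seen: set[tuple[str, str]] = set()
        for calls in calls_by_patient.values():
            for c in calls:
                for arm in c.arm_labels:
                    seen.add((arm, c.event_type))
        region_keys = sorted(seen)
    cols = [region_column(arm, etype) for arm, etype in region_keys]
    rows = []
    for pid, calls in calls_by_patient.items():
        row = dict.fromkeys(cols, 0)
        for c in calls:
            for arm in c.arm_labels:
                col = region_column(arm, c.event_type)
                if col in row:
                    row[col] = 1
        row["n_calls"] = len(calls)
        rows.append(pd.Series(row, name=pid))
    mat = pd.DataFrame(rows, columns=cols + ["n_calls"]).fillna(0).astype(int)
    mat.index.name = "patient_id"
    return mat


def screen_regions(matrix: pd.DataFrame, min_patients: int = 10) -> list[str]:
    """Region columns carried by at least ``min_patients`` patients
    (computed on the full cohort, before any stratification)."""
    cols = [c for c in matrix.columns if c != "n_calls"]
    if not cols:
        return []
    sums = matrix[cols].sum(axis=0)
    return [c for c in cols if sums[c] >= min_patients]


def count_bins(per_patient_counts) -> pd.DataFrame:
    """Fractions of aberration-positive patients with 1, 2-4, >=5 events."""
    counts = np.asarray(list(per_patient_counts), int)
    counts = counts[counts >= 1]
    if counts.size == 0:
        return pd.DataFrame(columns=["bin", "n", "fraction"])
    bins = {
        "1": int(np.sum(counts == 1)),
        "2-4": int(np.sum((counts >= 2) & (counts <= 4))),
        ">=5": int(np.sum(counts >= 5)),
    }
    total = counts.size
    return pd.DataFrame({"bin": list(bins), "n": list(bins.values()),
                         "fraction": [v / total for v in bins.values()]})


@dataclass
class CharacteristicTest:
    characteristic: str
    table: pd.DataFrame          # levels x groups counts
    percentages: pd.DataFrame    # column percentages
    test: str                    # "chi-square" | "fisher" | "degenerate"
    statistic: float
    p_value: float


def _run_test(table: np.ndarray) -> tuple[str, float, float]:
    if min(table.shape) < 2:
        return "degenerate", float("nan"), float("nan")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        if table.shape == (2, 2):
            res = stats.fisher_exact(table)
        else:
            # RxC exact test is resampled; seed it for reproducible reports
            res = stats.fisher_exact(table, method=stats.MonteCarloMethod(
                n_resamples=20000, rng=np.random.default_rng(0)))
        return "fisher", float("nan"), float(res.pvalue)
    return "chi-square", float(chi2), float(p)


def compare_characteristics(clinical: pd.DataFrame,
                            group_col: str,
                            characteristics: list[str],
                            include_missing: bool = True,
                            ) -> dict[str, CharacteristicTest]:
    """Compare categorical characteristics between groups.

    Pearson chi-square without continuity correction by default; Fisher's
    exact test when any expected cell is below 5 (the textbook rule).
    ``include_missing=False`` drops "missing" rows from the test statistic
    (they always remain in the printed table).  A characteristic with a
    single observed level is reported degenerate with p = NA.
    """
    if clinical[group_col].nunique() < 2:
        raise ValueError("need at least two groups")
    out: dict[str, CharacteristicTest] = {}
    for ch in characteristics:
        vals = clinical[ch].astype("string").fillna("missing")
        table = pd.crosstab(vals, clinical[group_col])
        pct = 100 * table / table.sum(axis=0)
        test_table = table if include_missing else table.loc[table.index != "missing"]
        name, statistic, p = _run_test(test_table.to_numpy())
        out[ch] = CharacteristicTest(ch, table, pct, name, statistic, p)
    return out


def compare_counts_2x2(present_group1: int, total_group1: int,
                       present_group2: int, total_group2: int) -> dict:
    """Prevalence comparison from a 2x2 of carrier counts by group.

    Returns each group's carrier percentage and the Pearson chi-square
    (no continuity correction) with its p-value.
    """
    a, b = present_group1, total_group1 - present_group1
    c, d = present_group2, total_group2 - present_group2
    table = np.array([[a, b], [c, d]], float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "pct_group1": 100.0 * a / total_group1,
        "pct_group2": 100.0 * c / total_group2,
        "chi2": float(chi2),
        "p_value": float(p),
    }
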