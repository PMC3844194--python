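"""Derived report tables and scalar summaries.

Empirical base quality is the Phred scaling of the observed reference
mismatch rate, -10*log10(mismatches / (matches + mismatches)), computed
from counts that already exclude known variant sites and N bases.  A bin
with zero mismatches has an unbounded estimate and is reported *censored*
at a documented ceiling (one above the largest reported quality seen) so
tables stay serialisable and plots bounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import QcAccumulator


def empirical_quality(matches: int, mismatches: int, ceiling: float = 94.0) -> float:
    """Phred-scaled mismatch rate; ``ceiling`` is returned when no
    mismatches were observed (censored estimate)."""
    total = matches + mismatches
    if total <= 0:
        raise ValueError("empirical quality undefined with zero bases")
    if mismatches == 0:
        return float(ceiling)
    return -10.0 * math.log10(mismatches / total)


@dataclass
class QualityConcordanceTable:
    """Per reported-quality bin: base count and empirical quality."""

    frame: pd.DataFrame  # reported_q, n_matches, n_mismatches, n_bases, empirical_q, censored
    ceiling: float


@dataclass
class CycleTable:
    """Per machine cycle: quality and base-composition diagnostics."""

    frame: pd.DataFrame  # cycle, n_bases, empirical_q, censored, mean_reported_q, frac_A..frac_N
    ceiling: float


@dataclass
class InsertSizeSummary:
    """Histogram-exact insert statistics for one read group.

    Mean/median/sd/mode are computed over in-range sizes (1..cap); the
    overflow pool is reported as a fraction only, since the individual
    sizes above the cap are not retained.  Mode ties break toward the
    smaller insert.
    """

    read_group: str
    histogram: np.ndarray  # index = insert size, 1..cap; [cap+1] = overflow
    cap: int
    n_pairs: int
    mode: int
    mean: float
    median: float
    sd: float
    overflow_fraction: float


@dataclass
class CoverageSummary:
    mean_depth: float
    mapped_fraction: float
    duplicate_fraction: float
    paired_fraction: float
    analysis_span: int
    total_aligned_bases: int
    records_seen: int
    mapq_histogram: np.ndarray


def _ceiling(acc: QcAccumulator) -> float:
    return float(acc.max_q_seen + 1)


def concordance_table(acc: QcAccumulator) -> QualityConcordanceTable:
    """One row per reported quality with any scored bases."""
    m = acc.pq_matches
    mm = acc.pq_mismatches
    total = m + mm
    qs = np.nonzero(total)[0]
    ceil = _ceiling(acc)
    rows = {
        "reported_q": qs,
        "n_matches": m[qs],
        "n_mismatches": mm[qs],
        "n_bases": total[qs],
        "empirical_q": [
            empirical_quality(int(m[q]), int(mm[q]), ceil) for q in qs
        ],
        "censored": mm[qs] == 0,
    }
    return QualityConcordanceTable(pd.DataFrame(rows), ceil)


def quality_mse(table: QualityConcordanceTable) -> float:
    """Base-count-weighted mean squared difference between empirical and
    reported quality over uncensored bins; the scalar concordance summary."""
    df = table.frame[~table.frame["censored"]]
    if df.empty:
        raise ValueError("all quality bins are censored (no mismatches observed)")
    w = df["n_bases"].to_numpy(dtype=float)
    w = w / w.sum()
    d = df["empirical_q"].to_numpy(dtype=float) - df["reported_q"].to_numpy(dtype=float)
    return float(np.sum(w * d * d))


def cycle_table(acc: QcAccumulator) -> CycleTable:
    n_cy = acc.max_cycle_seen
    ceil = _ceiling(acc)
    rows = []
    for c0 in range(n_cy):
        n = int(acc.cy_n_bases[c0])
        if n == 0:
            continue
        m, mm = int(acc.cy_matches[c0]), int(acc.cy_mismatches[c0])
        comp = acc.cy_composition[c0] / n
        rows.append(
            {
                "cycle": c0 + 1,
                "n_bases": n,
                "n_matches": m,
                "n_mismatches": mm,
                "empirical_q": empirical_quality(m, mm, ceil) if m + mm > 0 else np.nan,
                "censored": (m + mm > 0) and mm == 0,
                "mean_reported_q": float(acc.cy_sum_reported_q[c0]) / n,
                "frac_A": comp[0],
                "frac_C": comp[1],
                "frac_G": comp[2],
                "frac_T": comp[3],
                "frac_N": comp[4],
            }
        )
    return CycleTable(pd.DataFrame(rows), ceil)


def _hist_stats(hist: np.ndarray, cap: int) -> tuple[int, float, float, float]:
    sizes = np.arange(cap + 1)
    counts = hist[: cap + 1].astype(np.int64)
    n = int(counts.sum())
    mode = int(np.argmax(counts))  # argmax takes the first (smallest) maximum
    mean = float(np.sum(sizes * counts) / n)
    var = float(np.sum(counts * (sizes - mean) ** 2) / n)
    # histogram median: smallest size with cumulative count >= n/2 (lower tie-break)
    cum = np.cumsum(counts)
    median = float(np.searchsorted(cum, (n + 1) // 2))
    return mode, mean, median, math.sqrt(var)


def insert_summary(acc: QcAccumulator) -> dict[str, InsertSizeSummary]:
    """Per-read-group insert-size statistics; groups with no counted pairs
    are omitted."""
    out: dict[str, InsertSizeSummary] = {}
    for rg in sorted(acc.insert_hist):
        hist = acc.insert_hist[rg]
        total = int(hist.sum())
        if total == 0:
            continue
        overflow = int(hist[acc.insert_cap + 1])
        in_range = total - overflow
        if in_range > 0:
            mode, mean, median, sd = _hist_stats(hist, acc.insert_cap)
        else:
            mode, mean, median, sd = 0, float("nan"), float("nan"), float("nan")
        out[rg] = InsertSizeSummary(
            read_group=rg,
            histogram=hist.copy(),
            cap=acc.insert_cap,
            n_pairs=total,
            mode=mode,
            mean=mean,
            median=median,
            sd=sd,
            overflow_fraction=overflow / total,
        )
    return out


def coverage_summary(acc: QcAccumulator, analysis_span: int) -> CoverageSummary:
    """Global coverage/flag summary over ``analysis_span`` bp of analysed
    sequence (genome, target, or sampled span)."""
    if analysis_span <= 0:
        raise ValueError("analysis_span must be positive")
    seen = acc.records_seen
    return CoverageSummary(
        mean_depth=acc.total_aligned_bases / analysis_span,
        mapped_fraction=acc.mapped / seen if seen else 0.0,
        duplicate_fraction=acc.duplicates / seen if seen else 0.0,
        paired_fraction=acc.paired / seen if seen else 0.0,
        analysis_span=analysis_span,
        total_aligned_bases=acc.total_aligned_bases,
        records_seen=seen,
        mapq_histogram=acc.mapq_hist.copy(),
    )
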