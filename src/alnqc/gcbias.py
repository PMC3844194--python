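"""GC-bias diagnostics.

The genome (or the target regions of a capture experiment) is tiled into
fixed-size windows; each window gets an integer GC bin 0-100 (percent G+C of
its non-N bases).  Mean depth of coverage per bin, normalised by the
expected depth implied by the total aligned bases, yields a curve whose
departure from 1 exposes GC-dependent representation bias; a single
genome-weighted mean squared deviation from 1 summarises it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .engine import QcAccumulator
from .io import ReferenceGenome, TargetRegions

_GC_CODES = frozenset((ord("G"), ord("C")))


class GcWindow(NamedTuple):
    chrom: str
    start_0based: int
    end_exclusive: int
    gc_bin: int
    usable: bool


@dataclass
class GcWindowSchema:
    """Non-overlapping windows tiling the analysis space, with GC bins.

    Terminal partial windows shorter than half the window size are dropped;
    windows with more than 50% N bases (or no non-N bases) are kept but
    flagged unusable and excluded from ``usable_span``.
    """

    window_bp: int
    windows: list[GcWindow]

    @property
    def usable_span(self) -> int:
        return sum(w.end_exclusive - w.start_0based for w in self.windows if w.usable)


@dataclass
class GcBiasCurve:
    """Per-bin depth summary.  Bins with no usable windows are marked
    absent (``occupied`` False), not zero."""

    n_windows: np.ndarray  # (101,) usable window counts
    mean_depth: np.ndarray  # (101,) float, nan where absent
    normalized_depth: np.ndarray  # (101,) float, nan where absent
    genome_bin_weights: np.ndarray  # (101,) usable-length fraction per bin
    expected_depth: float  # aligned bases per usable bp

    @property
    def occupied(self) -> np.ndarray:
        return self.n_windows > 0

    def to_frame(self):
        import pandas as pd

        occ = self.occupied
        return pd.DataFrame(
            {
                "gc_bin": np.arange(101)[occ],
                "n_windows": self.n_windows[occ],
                "weight": self.genome_bin_weights[occ],
                "mean_depth": self.mean_depth[occ],
                "normalized_depth": self.normalized_depth[occ],
            }
        )


def _window_gc_bin(codes: np.ndarray) -> tuple[int, bool]:
    n_n = int((codes == ord("N")).sum())
    length = len(codes)
    denom = length - n_n
    if denom == 0 or n_n * 2 > length:
        return 0, False
    gc = int(((codes == ord("G")) | (codes == ord("C"))).sum())
    # round half up for determinism across platforms
    return int(math.floor(100.0 * gc / denom + 0.5)), True


def build_window_schema(
    ref: ReferenceGenome,
    window_bp: int = 100,
    targets: TargetRegions | None = None,
) -> GcWindowSchema:
    """Tile each contig (or each target interval) left to right into
    ``window_bp`` windows and assign GC bins from the reference."""
    if window_bp < 10:
        raise ValueError(f"window_bp must be >= 10, got {window_bp}")
    if not ref.contigs:
        raise ValueError("empty reference")
    if targets is None:
        spaces = [(c, 0, n) for c, n in ref.lengths.items()]
    else:
        spaces = [
            (c, s, e) for c, ivs in targets.intervals.items() for s, e in ivs
        ]
    windows: list[GcWindow] = []
    half = window_bp / 2.0
    for chrom, lo, hi in spaces:
        arr = ref.array(chrom)
        if hi > len(arr):
            raise ValueError(
                f"target {chrom}:{lo}-{hi} outside contig of length {len(arr)}"
            )
        for start in range(lo, hi, window_bp):
            end = min(start + window_bp, hi)
            if end - start < half:
                continue  # drop short terminal fragment
            gc_bin, usable = _window_gc_bin(arr[start:end])
            windows.append(GcWindow(chrom, start, end, gc_bin, usable))
    return GcWindowSchema(window_bp=window_bp, windows=windows)


def gc_curve(acc: QcAccumulator, schema: GcWindowSchema) -> GcBiasCurve:
    """Aggregate the accumulator's base-resolution depth over the schema.

    mean_depth[b] is total depth over total length of the usable windows in
    bin b; expected_depth is total aligned bases in usable windows per
    usable bp, so the length-weighted mean of normalized_depth is exactly 1.
    """
    usable_span = schema.usable_span
    if usable_span == 0:
        raise ValueError("no usable windows in schema")
    # prefix sums make window depth lookups O(1)
    csums = {c: np.concatenate(([0], np.cumsum(d))) for c, d in acc.depth.items()}
    depth_sum = np.zeros(101, dtype=np.float64)
    len_sum = np.zeros(101, dtype=np.int64)
    n_windows = np.zeros(101, dtype=np.int64)
    for w in schema.windows:
        if not w.usable:
            continue
        cs = csums[w.chrom]
        d = float(cs[w.end_exclusive] - cs[w.start_0based])
        depth_sum[w.gc_bin] += d
        len_sum[w.gc_bin] += w.end_exclusive - w.start_0based
        n_windows[w.gc_bin] += 1
    total_usable_depth = float(depth_sum.sum())
    expected_depth = total_usable_depth / usable_span
    if expected_depth == 0.0:
        raise ValueError("no aligned bases in usable windows; expected depth is zero")
    occ = n_windows > 0
    mean_depth = np.full(101, np.nan)
    mean_depth[occ] = depth_sum[occ] / len_sum[occ]
    normalized = np.full(101, np.nan)
    normalized[occ] = mean_depth[occ] / expected_depth
    weights = len_sum / float(usable_span)
    return GcBiasCurve(
        n_windows=n_windows,
        mean_depth=mean_depth,
        normalized_depth=normalized,
        genome_bin_weights=weights,
        expected_depth=expected_depth,
    )


def gc_bias_score(curve: GcBiasCurve) -> float:
    """Genome-weighted mean squared deviation of normalised depth from
    uniform coverage (1); zero iff coverage is perfectly uniform across GC
    bins.  Scale-free: invariant to total read count."""
    occ = curve.occupied
    if not occ.any():
        raise ValueError("curve has no occupied bins")
    w = curve.genome_bin_weights[occ]
    w = w / w.sum()
    dev = curve.normalized_depth[occ] - 1.0
    return float(np.sum(w * dev * dev))
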