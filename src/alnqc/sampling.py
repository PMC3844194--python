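"""Random genomic subsampling and extrapolation.

Very large alignments can be evaluated quickly by accumulating QC counts
only over randomly drawn genomic segments; pure totals are then scaled up
by genome_span / sampled_span while rate and ratio statistics (empirical
quality, normalised GC depth, insert distribution, mean depth, fractions)
are scale-free and pass through unchanged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .engine import QcAccumulator, ReadFilterPolicy
from .io import AlignedRead, KnownSiteMask, ReferenceGenome, TargetRegions, read_alignments


@dataclass
class SamplingPlan:
    """The randomly chosen segments plus the extrapolation scale factor."""

    seed: int
    segment_bp: int
    segments: list[tuple[str, int, int]]  # (chrom, start_0based, end_exclusive)
    genome_span: int

    @property
    def sampled_span(self) -> int:
        return sum(e - s for _, s, e in self.segments)

    @property
    def scale_factor(self) -> float:
        return self.genome_span / self.sampled_span

    def as_targets(self) -> TargetRegions:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.segments:
            by_chrom.setdefault(c, []).append((s, e))
        return TargetRegions(by_chrom)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#seed\t{self.seed}\n#segment_bp\t{self.segment_bp}\n")
            for c, s, e in self.segments:
                fh.write(f"{c}\t{s}\t{e}\n")

    @classmethod
    def read(cls, path: str | os.PathLike, genome_span: int) -> "SamplingPlan":
        seed = segment_bp = 0
        segments: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "#seed":
                    seed = int(parts[1])
                elif parts[0] == "#segment_bp":
                    segment_bp = int(parts[1])
                elif parts[0].startswith("#") or not parts[0]:
                    continue
                else:
                    segments.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(seed=seed, segment_bp=segment_bp, segments=segments, genome_span=genome_span)


def _overlaps(seg: tuple[str, int, int], others: list[tuple[str, int, int]]) -> bool:
    c, s, e = seg
    return any(c == oc and s < oe and e > os_ for oc, os_, oe in others)


def draw_plan(
    ref: ReferenceGenome,
    total_sample_bp: int,
    segment_bp: int,
    seed: int,
) -> SamplingPlan:
    """Draw ceil(total_sample_bp / segment_bp) non-overlapping segments.

    Contigs are chosen with probability proportional to their length; the
    start is uniform over positions where the segment fits.  Overlapping
    draws are rejection-resampled; if rejection cannot place a segment
    (near-saturating requests), remaining segments are placed
    deterministically left-to-right in the free gaps.  Deterministic given
    the seed.
    """
    genome_span = ref.genome_span
    if total_sample_bp > genome_span:
        raise ValueError(f"requested {total_sample_bp} bp > genome span {genome_span}")
    if segment_bp > total_sample_bp:
        raise ValueError("segment_bp exceeds total_sample_bp")
    n_segments = -(-total_sample_bp // segment_bp)
    rng = np.random.default_rng(seed)
    names = list(ref.contigs)
    lengths = np.array([ref.lengths[c] for c in names], dtype=np.float64)
    eligible = [i for i, c in enumerate(names) if ref.lengths[c] >= segment_bp]
    if not eligible:
        raise ValueError(f"no contig can hold a {segment_bp} bp segment")
    p = lengths[eligible] / lengths[eligible].sum()
    segments: list[tuple[str, int, int]] = []
    for _k in range(n_segments):
        placed = False
        for _ in range(1000):
            i = eligible[int(rng.choice(len(eligible), p=p))]
            chrom = names[i]
            start = int(rng.integers(0, ref.lengths[chrom] - segment_bp + 1))
            seg = (chrom, start, start + segment_bp)
            if not _overlaps(seg, segments):
                segments.append(seg)
                placed = True
                break
        if not placed:
            # near-saturating request: free space is fragmented below
            # segment_bp; fall back to drawing grid-aligned tiles without
            # replacement (still seeded, covers the genome at saturation)
            segments = _sample_tiles(ref, n_segments, segment_bp, rng)
            break
    segments.sort()
    plan = SamplingPlan(
        seed=seed, segment_bp=segment_bp, segments=segments, genome_span=genome_span
    )
    if len(plan.segments) < n_segments:
        raise ValueError(
            f"could not place {n_segments} segments of {segment_bp} bp "
            f"(genome too fragmented)"
        )
    return plan


def _sample_tiles(
    ref: ReferenceGenome,
    n_segments: int,
    segment_bp: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Draw segments without replacement from the grid tiling of every
    contig (fallback when free-start rejection cannot place a segment)."""
    tiles = [
        (c, s, s + segment_bp)
        for c, clen in ref.lengths.items()
        for s in range(0, clen - segment_bp + 1, segment_bp)
    ]
    if len(tiles) < n_segments:
        return tiles
    idx = rng.choice(len(tiles), size=n_segments, replace=False)
    return [tiles[i] for i in sorted(idx)]


def full_genome_plan(ref: ReferenceGenome, seed: int = 0) -> SamplingPlan:
    """A saturating plan: one segment per contig covering it entirely."""
    segments = [(c, 0, n) for c, n in ref.lengths.items()]
    return SamplingPlan(
        seed=seed,
        segment_bp=max(ref.lengths.values()),
        segments=sorted(segments),
        genome_span=ref.genome_span,
    )


def run_sampled(
    files: str | os.PathLike | list,
    ref: ReferenceGenome,
    mask: KnownSiteMask,
    plan: SamplingPlan,
    policy: ReadFilterPolicy | None = None,
    insert_cap: int = 2000,
) -> QcAccumulator:
    """Accumulate only reads whose leftmost aligned base lies inside a plan
    segment (each read processed once, with all its bases, even those
    outside the segment).  Files must be coordinate-sorted and indexed."""
    if policy is None:
        policy = ReadFilterPolicy()
    if isinstance(files, (str, os.PathLike)):
        files = [files]
    acc = QcAccumulator(ref.lengths, insert_cap)
    for path in files:
        for chrom, start, end in plan.segments:
            for read in read_alignments(path, region=(chrom, start, end)):
                if read.unmapped or not (start <= read.pos_0based < end):
                    continue
                acc.add_record(read, ref, mask, policy)
    return acc


@dataclass
class ExtrapolatedTotals:
    """Genome-wide totals scaled up from a sampled accumulator.

    Only pure totals are scaled; every rate/ratio statistic is scale-free
    and must be read from the sampled report directly.
    """

    sampled_span: int
    genome_span: int
    scale_factor: float
    total_aligned_bases: float
    records_seen: float
    mapped: float
    passed: float
    duplicates: float


def extrapolate(acc: QcAccumulator, plan: SamplingPlan) -> ExtrapolatedTotals:
    if plan.sampled_span == 0:
        raise ValueError("empty sampling plan")
    for chrom, _s, _e in plan.segments:
        if chrom not in acc.ref_lengths:
            raise ValueError(f"plan contig {chrom!r} unknown to accumulator")
    f = plan.scale_factor
    return ExtrapolatedTotals(
        sampled_span=plan.sampled_span,
        genome_span=plan.genome_span,
        scale_factor=f,
        total_aligned_bases=acc.total_aligned_bases * f,
        records_seen=acc.records_seen * f,
        mapped=acc.mapped * f,
        passed=acc.passed * f,
        duplicates=acc.duplicates * f,
    )
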