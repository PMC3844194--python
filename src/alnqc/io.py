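"""Readers for the standard formats the tool touches.

SAM/BAM alignments, FASTA references, known-site lists (VCF or plain
chrom/pos text) and BED target regions are parsed into small domain types
with explicit coordinate conventions: SAM/VCF positions are 1-based, BED is
0-based half-open, and all *internal* interval arithmetic is 0-based
half-open, converted once at the parser boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pysam
from Bio import SeqIO

#: CIGAR operations that consume query bases.
QUERY_CONSUMING = frozenset("MIS=X")
#: CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("MDN=X")

_CIGAR_OPS = "MIDNSHP=X"


@dataclass(eq=False)
class AlignedRead:
    """One alignment record, decoded from SAM/BAM.

    ``seq`` is stored exactly as in the file (reference-forward orientation
    for reverse-strand reads); ``quals`` are integer Phred scores of the same
    length.  A record stored with ``*`` sequence keeps ``seq == ""`` and an
    empty quality array.  ``tlen`` is the signed template length (the insert
    size carrier for paired-end data).
    """

    query_name: str
    chrom: str | None
    pos_1based: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    quals: np.ndarray
    paired: bool
    proper_pair: bool
    unmapped: bool
    mate_unmapped: bool
    reverse_strand: bool
    read1: bool
    read2: bool
    secondary: bool
    qc_fail: bool
    duplicate: bool
    supplementary: bool
    tlen: int
    read_group: str = "ungrouped"

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"{self.query_name}: seq length {len(self.seq)} != "
                f"quals length {len(self.quals)}"
            )
        if self.seq and not self.unmapped:
            qlen = sum(n for op, n in self.cigar if op in QUERY_CONSUMING)
            if qlen != len(self.seq):
                raise ValueError(
                    f"{self.query_name}: CIGAR consumes {qlen} query bases "
                    f"but seq has {len(self.seq)}"
                )

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def ref_span(self) -> int:
        """Reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def pos_0based(self) -> int:
        return self.pos_1based - 1

    def __eq__(self, other: object) -> bool:  # field-by-field, array-aware
        if not isinstance(other, AlignedRead):
            return NotImplemented
        for f in self.__dataclass_fields__:
            a, b = getattr(self, f), getattr(other, f)
            if f == "quals":
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class ReferenceGenome:
    """A reference genome held fully in memory, uppercased."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        self.contigs = {name: s.upper() for name, s in self.contigs.items()}
        self._arrays: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.contigs.items()}

    @property
    def genome_span(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def seq(self, chrom: str, start_0based: int, end_exclusive: int) -> str:
        s = self.contigs.get(chrom)
        if s is None:
            raise KeyError(f"unknown contig {chrom!r}")
        if start_0based < 0 or end_exclusive > len(s) or start_0based > end_exclusive:
            raise IndexError(
                f"{chrom}:{start_0based}-{end_exclusive} outside contig "
                f"of length {len(s)}"
            )
        return s[start_0based:end_exclusive]

    def array(self, chrom: str) -> np.ndarray:
        """Contig as a uint8 array of ASCII codes (cached)."""
        arr = self._arrays.get(chrom)
        if arr is None:
            s = self.contigs.get(chrom)
            if s is None:
                raise KeyError(f"unknown contig {chrom!r}")
            arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            self._arrays[chrom] = arr
        return arr


class KnownSiteMask:
    """Set of catalogued variant positions excluded from mismatch counting.

    Positions are 1-based on construction and query (matching VCF); stored
    internally 0-based as sorted arrays per contig for vectorised lookup.
    """

    def __init__(self, sites: Sequence[tuple[str, int]] = ()) -> None:
        by_chrom: dict[str, set[int]] = {}
        for chrom, pos1 in sites:
            if pos1 < 1:
                raise ValueError(f"position must be >= 1, got {pos1}")
            by_chrom.setdefault(chrom, set()).add(pos1 - 1)
        self._pos0: dict[str, np.ndarray] = {
            c: np.array(sorted(p), dtype=np.int64) for c, p in by_chrom.items()
        }

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, pos1 = site
        arr = self._pos0.get(chrom)
        if arr is None or not len(arr):
            return False
        i = np.searchsorted(arr, pos1 - 1)
        return i < len(arr) and arr[i] == pos1 - 1

    def __len__(self) -> int:
        return sum(len(a) for a in self._pos0.values())

    def hits(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of 0-based positions."""
        arr = self._pos0.get(chrom)
        if arr is None or not len(arr):
            return np.zeros(len(pos0), dtype=bool)
        i = np.searchsorted(arr, pos0)
        i = np.minimum(i, len(arr) - 1)
        return arr[i] == pos0


@dataclass
class TargetRegions:
    """Sorted, merged 0-based half-open intervals per contig (BED semantics)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in self.intervals.items():
            out: list[tuple[int, int]] = []
            for s, e in sorted(ivs):
                if s < 0:
                    raise ValueError(f"negative coordinate {s} on {chrom}")
                if s >= e:
                    raise ValueError(f"empty/inverted interval {chrom}:{s}-{e}")
                if out and s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            merged[chrom] = out
        self.intervals = merged

    @property
    def total_span(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def read_alignments(
    path: str | os.PathLike,
    region: tuple[str, int, int] | None = None,
) -> Iterator[AlignedRead]:
    """Stream alignment records from a SAM/BAM file.

    With ``region`` (chrom, start_0based, end_exclusive) the file must be
    coordinate-sorted and indexed; records with any aligned base overlapping
    the region are yielded in file order.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with pysam.AlignmentFile(path, check_sq=False) as af:
        rg_default = "ungrouped"
        if region is None:
            it = af.fetch(until_eof=True) if af.has_index() else af
            for seg in it:
                yield _from_pysam(seg, rg_default)
        else:
            chrom, start, end = region
            if not af.has_index():
                raise ValueError(
                    f"{path}: region query requires a coordinate-sorted, "
                    f"indexed file (missing index)"
                )
            if chrom not in af.references:
                raise ValueError(f"{path}: contig {chrom!r} not in header")
            for seg in af.fetch(chrom, start, end):
                yield _from_pysam(seg, rg_default)


def read_groups_in_header(path: str | os.PathLike) -> list[str]:
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as af:
        return [rg["ID"] for rg in af.header.to_dict().get("RG", [])]


def _from_pysam(seg: pysam.AlignedSegment, rg_default: str) -> AlignedRead:
    seq = seg.query_sequence
    quals = seg.query_qualities
    if seq is None or quals is None:
        # "*" sequence or qualities: kept for flag statistics, excluded from
        # base-level metrics by the empty-seq marker.
        seq, quals = "", np.zeros(0, dtype=np.int16)
    else:
        quals = np.asarray(quals, dtype=np.int16)
    cigar = tuple(
        (_CIGAR_OPS[op], n) for op, n in (seg.cigartuples or ())
    )
    try:
        rg = seg.get_tag("RG")
    except KeyError:
        rg = rg_default
    return AlignedRead(
        query_name=seg.query_name or "",
        chrom=seg.reference_name,
        pos_1based=(seg.reference_start + 1) if seg.reference_start is not None and seg.reference_start >= 0 else 0,
        mapq=seg.mapping_quality,
        cigar=cigar,
        seq=seq,
        quals=quals,
        paired=seg.is_paired,
        proper_pair=seg.is_proper_pair,
        unmapped=seg.is_unmapped,
        mate_unmapped=seg.mate_is_unmapped if seg.is_paired else False,
        reverse_strand=seg.is_reverse,
        read1=seg.is_read1,
        read2=seg.is_read2,
        secondary=seg.is_secondary,
        qc_fail=seg.is_qcfail,
        duplicate=seg.is_duplicate,
        supplementary=seg.is_supplementary,
        tlen=seg.template_length,
        read_group=str(rg),
    )


def load_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA reference; contig names are the first header token."""
    path = os.fspath(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"{path}: no sequences found")
    return ReferenceGenome(contigs)


def load_known_sites(path: str | os.PathLike) -> KnownSiteMask:
    """Load known variant sites from a VCF or a two-column chrom/pos file.

    For VCF rows only CHROM/POS/REF are used; a REF allele of length k masks
    k consecutive positions.
    """
    path = os.fspath(path)
    with open(path) as fh:
        head = fh.read(16)
    if head.startswith("##fileformat=VCF"):
        sites: list[tuple[str, int]] = []
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                for off in range(len(rec.ref or "N")):
                    sites.append((rec.chrom, rec.pos + off))
        return KnownSiteMask(sites)
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom pos'")
            try:
                pos = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {parts[1]!r}") from exc
            sites.append((parts[0], pos))
    return KnownSiteMask(sites)


def load_targets(path: str | os.PathLike) -> TargetRegions:
    """Load target-enrichment regions from a 3+ column BED file."""
    path = os.fspath(path)
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s < 0:
                raise ValueError(f"{path}:{lineno}: negative start {s}")
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start {s} >= end {e}")
            intervals.setdefault(chrom, []).append((s, e))
    return TargetRegions(intervals)
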