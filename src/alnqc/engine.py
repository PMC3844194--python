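"""Per-read QC computation and the mergeable accumulator.

The engine walks each alignment's CIGAR against the reference, classifying
every aligned base as match or mismatch (skipping known variant sites and N
bases), assigns bases to *machine cycles* (query offsets are reversed for
reverse-strand reads, since SAM stores them reference-forward), and folds
everything into a :class:`QcAccumulator` whose merge is field-wise addition.

Two equivalent paths exist: :func:`walk_alignment` +
:func:`accumulate_read` produce and consume explicit :class:`BaseEvent`
records (the reference semantics, convenient to test), while
:meth:`QcAccumulator.add_record` is the fused vectorised path used by the
pipeline.  A property test holds them equal on random inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io import AlignedRead, KnownSiteMask, ReferenceGenome

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

# base code -> index 0..4 (A,C,G,T,N); anything unexpected counts as N
_BASE_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_IDX[ord(_b)] = _i

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in ((_A, _T), (_C, _G)):
    _COMPLEMENT[_x], _COMPLEMENT[_y] = _y, _x

#: order in which filter criteria are reported
FILTER_ORDER = ("unmapped", "secondary", "supplementary", "duplicate", "qc_fail", "mapq")


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Which alignment records are admitted to the QC counts.

    Defaults follow prevailing QC practice: unmapped, secondary,
    supplementary, duplicate and QC-fail records are excluded so that
    mismatch rates reflect genuine sequencing error rather than artefacts;
    everything is configurable.
    """

    exclude_unmapped: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = True
    exclude_qc_fail: bool = True
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 255:
            raise ValueError(f"min_mapq must be in [0, 255], got {self.min_mapq}")


def passes_filter(read: AlignedRead, policy: ReadFilterPolicy) -> tuple[bool, str]:
    """Return (admitted, reason); reason names the first failing criterion
    in the fixed order unmapped, secondary, supplementary, duplicate,
    qc_fail, mapq."""
    if policy.exclude_unmapped and read.unmapped:
        return False, "unmapped"
    if policy.exclude_secondary and read.secondary:
        return False, "secondary"
    if policy.exclude_supplementary and read.supplementary:
        return False, "supplementary"
    if policy.exclude_duplicates and read.duplicate:
        return False, "duplicate"
    if policy.exclude_qc_fail and read.qc_fail:
        return False, "qc_fail"
    if not read.unmapped and read.mapq < policy.min_mapq:
        return False, "mapq"
    return True, ""


@dataclass(frozen=True)
class BaseEvent:
    """One aligned query base (an M/=/X CIGAR position) and its verdict."""

    cycle_1based: int
    reported_q: int
    kind: str  # match | mismatch | skipped_known_site | skipped_N
    ref_pos_1based: int
    read_base: str
    ref_base: str


def _machine_cycle0(read: AlignedRead, query_offset: int) -> int:
    """0-based machine cycle for a query offset; reverse-strand reads are
    stored reference-forward, so their offsets are reversed."""
    if read.reverse_strand:
        return read.read_length - 1 - query_offset
    return query_offset


def walk_alignment(
    read: AlignedRead, ref: ReferenceGenome, mask: KnownSiteMask
) -> list[BaseEvent]:
    """Classify every aligned base of one mapped read.

    Exactly one event is emitted per query base consumed by an M/=/X CIGAR
    op.  Insertions and soft clips advance the machine cycle but emit no
    events; deletions and reference skips advance the reference only.
    """
    if read.unmapped or not read.seq:
        raise ValueError(f"{read.query_name}: walk requires a mapped read with sequence")
    contig = ref.contigs.get(read.chrom)
    if contig is None:
        raise KeyError(f"unknown contig {read.chrom!r}")
    if read.pos_0based + read.ref_span > len(contig):
        raise ValueError(
            f"{read.query_name}: alignment extends past end of {read.chrom} "
            f"({read.pos_0based + read.ref_span} > {len(contig)})"
        )
    events: list[BaseEvent] = []
    qoff = 0
    rpos = read.pos_0based
    for op, n in read.cigar:
        if op in ("M", "=", "X"):
            for k in range(n):
                rb = read.seq[qoff + k]
                fb = contig[rpos + k]
                if (read.chrom, rpos + k + 1) in mask:
                    kind = "skipped_known_site"
                elif rb == "N" or fb == "N":
                    kind = "skipped_N"
                elif rb == fb:
                    kind = "match"
                else:
                    kind = "mismatch"
                events.append(
                    BaseEvent(
                        cycle_1based=_machine_cycle0(read, qoff + k) + 1,
                        reported_q=int(read.quals[qoff + k]),
                        kind=kind,
                        ref_pos_1based=rpos + k + 1,
                        read_base=rb,
                        ref_base=fb,
                    )
                )
            qoff += n
            rpos += n
        elif op in ("I", "S"):
            qoff += n
        elif op in ("D", "N"):
            rpos += n
        # H, P consume neither
    return events


class QcAccumulator:
    """All raw counting state, mergeable across regions and files.

    Depth is stored at base resolution per contig so the accumulator is
    independent of any GC window schema; window aggregation happens in the
    gcbias module.  Quality and cycle arrays auto-grow.
    """

    def __init__(self, ref_lengths: Mapping[str, int], insert_cap: int = 2000):
        self.ref_lengths = dict(ref_lengths)
        self.insert_cap = int(insert_cap)
        self.pq_matches = np.zeros(64, dtype=np.int64)
        self.pq_mismatches = np.zeros(64, dtype=np.int64)
        self.cy_matches = np.zeros(0, dtype=np.int64)
        self.cy_mismatches = np.zeros(0, dtype=np.int64)
        self.cy_sum_reported_q = np.zeros(0, dtype=np.int64)
        self.cy_n_bases = np.zeros(0, dtype=np.int64)
        self.cy_composition = np.zeros((0, 5), dtype=np.int64)  # A C G T N
        self.depth: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=np.int64) for c, n in self.ref_lengths.items()
        }
        self.insert_hist: dict[str, np.ndarray] = {}
        self.skipped_known_site = 0
        self.skipped_n = 0
        self.total_aligned_bases = 0
        self.records_seen = 0
        self.passed = 0
        self.mapped = 0
        self.paired = 0
        self.proper_pair = 0
        self.duplicates = 0
        self.qc_fail = 0
        self.filtered_by_reason: dict[str, int] = {r: 0 for r in FILTER_ORDER}
        self.mapq_hist = np.zeros(256, dtype=np.int64)

    # -- growth helpers -------------------------------------------------
    def _ensure_q(self, q: int) -> None:
        if q >= len(self.pq_matches):
            n = max(q + 1, 2 * len(self.pq_matches))
            self.pq_matches = _grown(self.pq_matches, n)
            self.pq_mismatches = _grown(self.pq_mismatches, n)

    def _ensure_cycle(self, c0: int) -> None:
        if c0 >= len(self.cy_matches):
            n = max(c0 + 1, 2 * len(self.cy_matches), 8)
            self.cy_matches = _grown(self.cy_matches, n)
            self.cy_mismatches = _grown(self.cy_mismatches, n)
            self.cy_sum_reported_q = _grown(self.cy_sum_reported_q, n)
            self.cy_n_bases = _grown(self.cy_n_bases, n)
            comp = np.zeros((n, 5), dtype=np.int64)
            comp[: len(self.cy_composition)] = self.cy_composition
            self.cy_composition = comp

    def _insert_array(self, read_group: str) -> np.ndarray:
        arr = self.insert_hist.get(read_group)
        if arr is None:
            # index i = insert size i for 1..cap; index cap+1 = overflow pool
            arr = np.zeros(self.insert_cap + 2, dtype=np.int64)
            self.insert_hist[read_group] = arr
        return arr

    @property
    def max_q_seen(self) -> int:
        occ = np.nonzero(self.pq_matches + self.pq_mismatches)[0]
        return int(occ[-1]) if len(occ) else 0

    @property
    def max_cycle_seen(self) -> int:
        occ = np.nonzero(self.cy_n_bases)[0]
        return int(occ[-1]) + 1 if len(occ) else 0

    # -- bookkeeping shared by both paths -------------------------------
    def admit(self, read: AlignedRead, policy: ReadFilterPolicy) -> tuple[bool, str]:
        """Count flags, apply the filter policy; True iff base-level
        processing should proceed."""
        self.records_seen += 1
        if not read.unmapped:
            self.mapped += 1
            self.mapq_hist[read.mapq] += 1
        if read.paired:
            self.paired += 1
        if read.proper_pair:
            self.proper_pair += 1
        if read.duplicate:
            self.duplicates += 1
        if read.qc_fail:
            self.qc_fail += 1
        ok, reason = passes_filter(read, policy)
        if not ok:
            self.filtered_by_reason[reason] += 1
            return False, reason
        self.passed += 1
        return True, ""

    def _count_insert(self, read: AlignedRead) -> None:
        # once per template: only the leftmost mate (tlen > 0) of a proper pair
        if read.paired and read.proper_pair and read.tlen > 0:
            arr = self._insert_array(read.read_group)
            if read.tlen <= self.insert_cap:
                arr[read.tlen] += 1
            else:
                arr[self.insert_cap + 1] += 1

    # -- fused vectorised path ------------------------------------------
    def add_record(
        self,
        read: AlignedRead,
        ref: ReferenceGenome,
        mask: KnownSiteMask,
        policy: ReadFilterPolicy,
    ) -> bool:
        """Admit one record and fold its bases in; returns admission."""
        ok, _ = self.admit(read, policy)
        if not ok:
            return False
        self._count_insert(read)
        if read.unmapped or not read.seq:
            return True
        ref_arr = ref.array(read.chrom)
        if read.pos_0based + read.ref_span > len(ref_arr):
            raise ValueError(
                f"{read.query_name}: alignment extends past end of {read.chrom}"
            )
        seq_b = np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)
        quals = np.asarray(read.quals, dtype=np.int64)
        L = read.read_length
        self._ensure_cycle(L - 1)
        depth = self.depth[read.chrom]
        qoff = 0
        rpos = read.pos_0based
        for op, n in read.cigar:
            if op in ("M", "=", "X"):
                readb = seq_b[qoff : qoff + n]
                refb = ref_arr[rpos : rpos + n]
                q = quals[qoff : qoff + n]
                offs = np.arange(qoff, qoff + n)
                cyc0 = (L - 1 - offs) if read.reverse_strand else offs
                pos0 = np.arange(rpos, rpos + n)
                masked = mask.hits(read.chrom, pos0)
                is_n = (readb == _N) | (refb == _N)
                scored = ~masked & ~is_n
                is_match = scored & (readb == refb)
                is_mm = scored & (readb != refb)
                self.skipped_known_site += int(masked.sum())
                self.skipped_n += int((is_n & ~masked).sum())
                if is_match.any() or is_mm.any():
                    self._ensure_q(int(q[scored].max()))
                np.add.at(self.pq_matches, q[is_match], 1)
                np.add.at(self.pq_mismatches, q[is_mm], 1)
                np.add.at(self.cy_matches, cyc0[is_match], 1)
                np.add.at(self.cy_mismatches, cyc0[is_mm], 1)
                np.add.at(self.cy_sum_reported_q, cyc0, q)
                np.add.at(self.cy_n_bases, cyc0, 1)
                seen = _COMPLEMENT[readb] if read.reverse_strand else readb
                np.add.at(self.cy_composition, (cyc0, _BASE_IDX[seen]), 1)
                depth[rpos : rpos + n] += 1
                self.total_aligned_bases += n
                qoff += n
                rpos += n
            elif op in ("I", "S"):
                qoff += n
            elif op in ("D", "N"):
                rpos += n
        return True

    def copy(self) -> "QcAccumulator":
        return merge(self, QcAccumulator(self.ref_lengths, self.insert_cap))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QcAccumulator):
            return NotImplemented
        return _state(self) == _state(other)


def _grown(arr: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n, dtype=arr.dtype)
    out[: len(arr)] = arr
    return out


def _state(acc: QcAccumulator):
    def trim(a):
        return tuple(np.trim_zeros(np.asarray(a).ravel(), "b").tolist())

    return (
        acc.ref_lengths,
        acc.insert_cap,
        trim(acc.pq_matches),
        trim(acc.pq_mismatches),
        trim(acc.cy_matches),
        trim(acc.cy_mismatches),
        trim(acc.cy_sum_reported_q),
        trim(acc.cy_n_bases),
        {c: tuple(d.tolist()) for c, d in acc.depth.items()},
        tuple(sorted((g, tuple(h.tolist())) for g, h in acc.insert_hist.items() if h.any())),
        _comp_state(acc),
        acc.skipped_known_site,
        acc.skipped_n,
        acc.total_aligned_bases,
        acc.records_seen,
        acc.passed,
        acc.mapped,
        acc.paired,
        acc.proper_pair,
        acc.duplicates,
        acc.qc_fail,
        tuple(sorted(acc.filtered_by_reason.items())),
        tuple(acc.mapq_hist.tolist()),
    )


def _comp_state(acc: QcAccumulator):
    c = acc.cy_composition[: acc.max_cycle_seen]
    return tuple(map(tuple, c.tolist()))


def accumulate_read(
    acc: QcAccumulator,
    read: AlignedRead,
    events: Iterable[BaseEvent],
    policy: ReadFilterPolicy,
) -> QcAccumulator:
    """Event-driven accumulation: the reference path equivalent to
    :meth:`QcAccumulator.add_record` given ``events`` from
    :func:`walk_alignment` on the same read.  Mutates and returns ``acc``."""
    ok, _ = acc.admit(read, policy)
    if not ok:
        return acc
    acc._count_insert(read)
    for ev in events:
        c0 = ev.cycle_1based - 1
        acc._ensure_cycle(c0)
        acc._ensure_q(ev.reported_q)
        if ev.kind == "match":
            acc.pq_matches[ev.reported_q] += 1
            acc.cy_matches[c0] += 1
        elif ev.kind == "mismatch":
            acc.pq_mismatches[ev.reported_q] += 1
            acc.cy_mismatches[c0] += 1
        elif ev.kind == "skipped_known_site":
            acc.skipped_known_site += 1
        elif ev.kind == "skipped_N":
            acc.skipped_n += 1
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        acc.cy_sum_reported_q[c0] += ev.reported_q
        acc.cy_n_bases[c0] += 1
        base = ev.read_base
        if read.reverse_strand:
            base = {"A": "T", "T": "A", "C": "G", "G": "C"}.get(base, base)
        acc.cy_composition[c0, int(_BASE_IDX[ord(base)])] += 1
        acc.depth[read.chrom][ev.ref_pos_1based - 1] += 1
        acc.total_aligned_bases += 1
    return acc


def merge(a: QcAccumulator, b: QcAccumulator) -> QcAccumulator:
    """Field-wise sum of two accumulators over the same reference and
    insert cap; the empty accumulator is the identity."""
    if a.ref_lengths != b.ref_lengths:
        raise ValueError("cannot merge accumulators over different references")
    if a.insert_cap != b.insert_cap:
        raise ValueError("cannot merge accumulators with different insert caps")
    out = QcAccumulator(a.ref_lengths, a.insert_cap)
    nq = max(len(a.pq_matches), len(b.pq_matches))
    out.pq_matches = _grown(a.pq_matches, nq) + _grown(b.pq_matches, nq)
    out.pq_mismatches = _grown(a.pq_mismatches, nq) + _grown(b.pq_mismatches, nq)
    nc = max(len(a.cy_matches), len(b.cy_matches))
    for name in ("cy_matches", "cy_mismatches", "cy_sum_reported_q", "cy_n_bases"):
        setattr(out, name, _grown(getattr(a, name), nc) + _grown(getattr(b, name), nc))
    comp = np.zeros((nc, 5), dtype=np.int64)
    comp[: len(a.cy_composition)] += a.cy_composition
    comp[: len(b.cy_composition)] += b.cy_composition
    out.cy_composition = comp
    for c in out.depth:
        out.depth[c] = a.depth[c] + b.depth[c]
    for g in set(a.insert_hist) | set(b.insert_hist):
        out.insert_hist[g] = (
            a.insert_hist.get(g, np.zeros(a.insert_cap + 2, dtype=np.int64))
            + b.insert_hist.get(g, np.zeros(a.insert_cap + 2, dtype=np.int64))
        )
    for name in (
        "skipped_known_site",
        "skipped_n",
        "total_aligned_bases",
        "records_seen",
        "passed",
        "mapped",
        "paired",
        "proper_pair",
        "duplicates",
        "qc_fail",
    ):
        setattr(out, name, getattr(a, name) + getattr(b, name))
    out.filtered_by_reason = {
        r: a.filtered_by_reason.get(r, 0) + b.filtered_by_reason.get(r, 0)
        for r in set(a.filtered_by_reason) | set(b.filtered_by_reason)
    }
    out.mapq_hist = a.mapq_hist + b.mapq_hist
    return out
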