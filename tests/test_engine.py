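"""CIGAR walk, base classification, accumulation and merging."""

import numpy as np
import pytest

from alnqc import (
    KnownSiteMask,
    QcAccumulator,
    ReadFilterPolicy,
    ReferenceGenome,
    accumulate_read,
    merge,
    passes_filter,
    read_alignments,
    walk_alignment,
)
from alnqc.simulate import random_alignment_fixture

from conftest import make_read

POLICY = ReadFilterPolicy()
EMPTY_MASK = KnownSiteMask()


# -- filter policy ----------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs,policy,expect",
    [
        ({"duplicate": True}, POLICY, (False, "duplicate")),
        ({"mapq": 30}, POLICY, (True, "")),
        ({"mapq": 5}, ReadFilterPolicy(min_mapq=10), (False, "mapq")),
        ({"unmapped": True, "duplicate": True}, POLICY, (False, "unmapped")),
        ({"secondary": True, "qc_fail": True}, POLICY, (False, "secondary")),
        ({"duplicate": True}, ReadFilterPolicy(exclude_duplicates=False), (True, "")),
    ],
)
def test_passes_filter_first_failing_reason(kwargs, policy, expect):
    read = make_read("ACGT", [("M", 4)], **kwargs)
    assert passes_filter(read, policy) == expect


def test_filter_policy_rejects_bad_mapq_bound():
    with pytest.raises(ValueError):
        ReadFilterPolicy(min_mapq=300)


# -- walk_alignment ---------------------------------------------------------

def test_perfect_match_walk():
    ref = ReferenceGenome({"c1": "ACGT"})
    events = walk_alignment(make_read("ACGT", [("M", 4)]), ref, EMPTY_MASK)
    assert [e.kind for e in events] == ["match"] * 4
    assert [e.cycle_1based for e in events] == [1, 2, 3, 4]
    assert [e.ref_pos_1based for e in events] == [1, 2, 3, 4]


def test_single_mismatch_matches_string_comparison_oracle():
    ref = ReferenceGenome({"c1": "ACGA"})
    events = walk_alignment(make_read("ACGT", [("M", 4)]), ref, EMPTY_MASK)
    expect = ["match" if a == b else "mismatch" for a, b in zip("ACGT", "ACGA")]
    assert [e.kind for e in events] == expect
    assert events[3].ref_pos_1based == 4 and events[3].kind == "mismatch"


def test_masked_site_is_skipped_not_mismatched():
    ref = ReferenceGenome({"c1": "ACGA"})
    mask = KnownSiteMask([("c1", 4)])
    events = walk_alignment(make_read("ACGT", [("M", 4)]), ref, mask)
    kinds = [e.kind for e in events]
    assert kinds == ["match", "match", "match", "skipped_known_site"]


def test_soft_clip_consumes_cycles_but_emits_no_events():
    ref = ReferenceGenome({"c1": "ACGT"})
    events = walk_alignment(make_read("AACGT", [("S", 1), ("M", 4)]), ref, EMPTY_MASK)
    assert [e.cycle_1based for e in events] == [2, 3, 4, 5]
    assert [e.kind for e in events] == ["match"] * 4


def test_reverse_strand_cycles_are_machine_order():
    ref = ReferenceGenome({"c1": "ACGT"})
    events = walk_alignment(make_read("ACGT", [("M", 4)], reverse=True), ref, EMPTY_MASK)
    assert [e.cycle_1based for e in events] == [4, 3, 2, 1]


def test_n_bases_are_neither_match_nor_mismatch():
    ref = ReferenceGenome({"c1": "ANGT"})
    events = walk_alignment(make_read("NCGT", [("M", 4)]), ref, EMPTY_MASK)
    assert [e.kind for e in events] == ["skipped_N", "skipped_N", "match", "match"]


def test_insertion_and_deletion_bookkeeping():
    # 2M 1I 2M: query ACXGT against ref ACGT; 2M 2D 2M: ref gap
    ref = ReferenceGenome({"c1": "ACGTTT"})
    ev = walk_alignment(make_read("ACAGT", [("M", 2), ("I", 1), ("M", 2)]), ref, EMPTY_MASK)
    assert [(e.cycle_1based, e.ref_pos_1based) for e in ev] == [(1, 1), (2, 2), (4, 3), (5, 4)]
    ev = walk_alignment(make_read("ACTT", [("M", 2), ("D", 2), ("M", 2)]), ref, EMPTY_MASK)
    assert [(e.cycle_1based, e.ref_pos_1based) for e in ev] == [(1, 1), (2, 2), (3, 5), (4, 6)]


def test_walk_rejects_overhanging_alignment():
    ref = ReferenceGenome({"c1": "ACG"})
    with pytest.raises(ValueError, match="past end"):
        walk_alignment(make_read("ACGT", [("M", 4)]), ref, EMPTY_MASK)


def test_cigar_seq_length_disagreement_rejected_at_construction():
    with pytest.raises(ValueError, match="CIGAR"):
        make_read("ACGT", [("M", 5)])


def test_event_count_equals_query_bases_consumed_by_aligned_ops(tmp_path):
    _sam, _fa, ref = random_alignment_fixture(tmp_path, seed=2, n_reads=50)
    for read in read_alignments(str(tmp_path / "reads.sam")):
        if read.unmapped or not read.seq:
            continue
        events = walk_alignment(read, ref, EMPTY_MASK)
        expect = sum(n for op, n in read.cigar if op in ("M", "=", "X"))
        assert len(events) == expect


# -- accumulation -----------------------------------------------------------

def _acc(ref, **kw):
    return QcAccumulator(ref.lengths, **kw)


def test_matches_land_in_reported_quality_bin():
    ref = ReferenceGenome({"c1": "ACGT"})
    read = make_read("ACGT", [("M", 4)], quals=30)
    acc = _acc(ref)
    accumulate_read(acc, read, walk_alignment(read, ref, EMPTY_MASK), POLICY)
    assert (int(acc.pq_matches[30]), int(acc.pq_mismatches[30])) == (4, 0)
    assert acc.total_aligned_bases == 4


def test_insert_counted_once_per_template():
    ref = ReferenceGenome({"c1": "A" * 1000})
    acc = _acc(ref)
    r1 = make_read("AAAA", [("M", 4)], pos_1based=1, paired=True, proper=True, tlen=300)
    r2 = make_read("AAAA", [("M", 4)], pos_1based=297, paired=True, proper=True, tlen=-300, reverse=True)
    for r in (r1, r2):
        acc.add_record(r, ref, EMPTY_MASK, POLICY)
    assert int(acc.insert_hist["rg1"][300]) == 1
    assert int(acc.insert_hist["rg1"].sum()) == 1


def test_oversize_insert_pools_into_overflow_bin():
    ref = ReferenceGenome({"c1": "A" * 10})
    acc = QcAccumulator(ref.lengths, insert_cap=500)
    r = make_read("AAAA", [("M", 4)], paired=True, proper=True, tlen=9999)
    acc.add_record(r, ref, EMPTY_MASK, POLICY)
    assert int(acc.insert_hist["rg1"][501]) == 1


def test_fused_and_event_paths_agree(tmp_path):
    sam, _fa, ref = random_alignment_fixture(tmp_path, seed=3, n_reads=120)
    mask = KnownSiteMask([("c1", p) for p in range(1, 2500, 37)])
    fused = QcAccumulator(ref.lengths)
    eventwise = QcAccumulator(ref.lengths)
    for read in read_alignments(sam):
        fused.add_record(read, ref, mask, POLICY)
        ok, _ = passes_filter(read, POLICY)
        events = (
            walk_alignment(read, ref, mask) if ok and not read.unmapped and read.seq else []
        )
        accumulate_read(eventwise, read, events, POLICY)
    assert fused == eventwise


def test_split_accumulation_equals_single_pass(tmp_path):
    sam, _fa, ref = random_alignment_fixture(tmp_path, seed=11, n_reads=90)
    reads = list(read_alignments(sam))
    whole = QcAccumulator(ref.lengths)
    for r in reads:
        whole.add_record(r, ref, EMPTY_MASK, POLICY)
    parts = [QcAccumulator(ref.lengths) for _ in range(3)]
    for i, r in enumerate(reads):
        parts[i % 3].add_record(r, ref, EMPTY_MASK, POLICY)
    assert merge(merge(parts[0], parts[1]), parts[2]) == whole


def test_merge_identity_and_commutativity(tmp_path):
    sam, _fa, ref = random_alignment_fixture(tmp_path, seed=13, n_reads=40)
    a = QcAccumulator(ref.lengths)
    b = QcAccumulator(ref.lengths)
    for i, r in enumerate(read_alignments(sam)):
        (a if i % 2 else b).add_record(r, ref, EMPTY_MASK, POLICY)
    empty = QcAccumulator(ref.lengths)
    assert merge(a, empty) == a
    assert merge(a, b) == merge(b, a)


def test_merge_rejects_incompatible_schemas():
    a = QcAccumulator({"c1": 10})
    b = QcAccumulator({"c1": 20})
    with pytest.raises(ValueError, match="reference"):
        merge(a, b)
    c = QcAccumulator({"c1": 10}, insert_cap=100)
    with pytest.raises(ValueError, match="cap"):
        merge(a, c)


def test_enlarging_mask_never_increases_mismatches_or_changes_depth(tmp_path):
    sam, _fa, ref = random_alignment_fixture(tmp_path, seed=17, n_reads=80)
    reads = list(read_alignments(sam))
    masks = [
        KnownSiteMask(),
        KnownSiteMask([("c1", p) for p in range(1, 2500, 11)]),
        KnownSiteMask(
            [("c1", p) for p in range(1, 2500, 11)]
            + [("c2", p) for p in range(1, 2500, 5)]
        ),
    ]
    accs = []
    for mask in masks:
        acc = QcAccumulator(ref.lengths)
        for r in reads:
            acc.add_record(r, ref, mask, POLICY)
        accs.append(acc)
    mm = [int(a.pq_mismatches.sum()) for a in accs]
    assert mm[0] >= mm[1] >= mm[2]
    for a in accs[1:]:
        for c in ref.lengths:
            assert np.array_equal(a.depth[c], accs[0].depth[c])


def test_tightening_mapq_never_increases_any_count(tmp_path):
    sam, _fa, ref = random_alignment_fixture(tmp_path, seed=19, n_reads=80)
    reads = list(read_alignments(sam))
    prev = None
    for min_mapq in (0, 20, 40, 61):
        acc = QcAccumulator(ref.lengths)
        pol = ReadFilterPolicy(min_mapq=min_mapq)
        for r in reads:
            acc.add_record(r, ref, EMPTY_MASK, pol)
        cur = (
            acc.total_aligned_bases,
            int(acc.pq_matches.sum()),
            int(acc.pq_mismatches.sum()),
            sum(int(h.sum()) for h in acc.insert_hist.values()),
            sum(int(d.sum()) for d in acc.depth.values()),
        )
        if prev is not None:
            assert all(c <= p for c, p in zip(cur, prev))
        prev = cur


def test_base_count_conservation(tmp_path):
    """Scored + skipped bases account exactly for all aligned M bases."""
    sam, _fa, ref = random_alignment_fixture(tmp_path, seed=23, n_reads=100)
    mask = KnownSiteMask([("c2", p) for p in range(1, 2500, 13)])
    acc = QcAccumulator(ref.lengths)
    for r in read_alignments(sam):
        acc.add_record(r, ref, mask, POLICY)
    scored = int(acc.pq_matches.sum() + acc.pq_mismatches.sum())
    assert scored + acc.skipped_known_site + acc.skipped_n == acc.total_aligned_bases
    assert acc.total_aligned_bases == sum(int(d.sum()) for d in acc.depth.values())
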