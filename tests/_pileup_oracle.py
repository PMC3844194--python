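"""Independent brute-force pileup used as the oracle for the engine.

Deliberately naive: pure-Python nested loops over reads and positions,
dicts and strings only, parsing SAM directly with pysam.  Shares no code
with alnqc's vectorised accumulator.
"""

from collections import defaultdict

import pysam

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_OPS = "MIDNSHP=X"


def brute_force_pileup(
    sam_path,
    ref_contigs,
    mask_sites=frozenset(),
    min_mapq=0,
    exclude_duplicates=True,
    exclude_qc_fail=True,
    insert_cap=2000,
):
    """Replays default engine semantics base by base.

    mask_sites: set of (chrom, pos_1based).  Returns a dict of plain
    counters: depth per (chrom, pos0), matches/mismatches per reported q
    and per machine cycle, cycle base counts/composition, insert histogram
    per read group, and flag totals.
    """
    depth = defaultdict(int)
    per_q = defaultdict(lambda: [0, 0])  # q -> [matches, mismatches]
    per_cycle = defaultdict(lambda: [0, 0])
    cycle_n = defaultdict(int)
    cycle_comp = defaultdict(lambda: defaultdict(int))
    insert = defaultdict(lambda: defaultdict(int))
    counters = defaultdict(int)
    skipped_known = 0
    skipped_n = 0
    total_aligned = 0

    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for rec in af.fetch(until_eof=True) if af.has_index() else af:
            counters["records_seen"] += 1
            if not rec.is_unmapped:
                counters["mapped"] += 1
            if rec.is_paired:
                counters["paired"] += 1
            if rec.is_duplicate:
                counters["duplicates"] += 1
            if rec.is_qcfail:
                counters["qc_fail"] += 1
            if rec.is_unmapped:
                continue
            if rec.is_secondary or rec.is_supplementary:
                continue
            if exclude_duplicates and rec.is_duplicate:
                continue
            if exclude_qc_fail and rec.is_qcfail:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            try:
                rg = rec.get_tag("RG")
            except KeyError:
                rg = "ungrouped"
            if rec.is_paired and rec.is_proper_pair and rec.template_length > 0:
                size = rec.template_length
                insert[rg][min(size, insert_cap + 1)] += 1
            seq = rec.query_sequence
            quals = rec.query_qualities
            if seq is None or quals is None:
                continue
            chrom = rec.reference_name
            contig = ref_contigs[chrom]
            L = len(seq)
            qoff = 0
            rpos = rec.reference_start
            for op_i, n in rec.cigartuples:
                op = _OPS[op_i]
                if op in "M=X":
                    for k in range(n):
                        read_b = seq[qoff + k]
                        ref_b = contig[rpos + k]
                        cycle = (L - (qoff + k)) if rec.is_reverse else (qoff + k + 1)
                        q = quals[qoff + k]
                        depth[(chrom, rpos + k)] += 1
                        total_aligned += 1
                        cycle_n[cycle] += 1
                        seen_b = _COMP.get(read_b, read_b) if rec.is_reverse else read_b
                        if seen_b not in "ACGT":
                            seen_b = "N"
                        cycle_comp[cycle][seen_b] += 1
                        if (chrom, rpos + k + 1) in mask_sites:
                            skipped_known += 1
                        elif read_b == "N" or ref_b == "N":
                            skipped_n += 1
                        elif read_b == ref_b:
                            per_q[q][0] += 1
                            per_cycle[cycle][0] += 1
                        else:
                            per_q[q][1] += 1
                            per_cycle[cycle][1] += 1
                    qoff += n
                    rpos += n
                elif op in "IS":
                    qoff += n
                elif op in "DN":
                    rpos += n
    return {
        "depth": dict(depth),
        "per_q": {q: tuple(v) for q, v in per_q.items() if any(v)},
        "per_cycle": {c: tuple(v) for c, v in per_cycle.items() if any(v)},
        "cycle_n": dict(cycle_n),
        "cycle_comp": {c: dict(v) for c, v in cycle_comp.items()},
        "insert": {g: dict(v) for g, v in insert.items()},
        "counters": dict(counters),
        "skipped_known": skipped_known,
        "skipped_n": skipped_n,
        "total_aligned": total_aligned,
    }


def accumulator_as_oracle_dicts(acc):
    """Flatten a QcAccumulator into the oracle's dict shapes for equality."""
    depth = {}
    for chrom, arr in acc.depth.items():
        for pos0 in arr.nonzero()[0]:
            depth[(chrom, int(pos0))] = int(arr[pos0])
    per_q = {
        q: (int(acc.pq_matches[q]), int(acc.pq_mismatches[q]))
        for q in range(len(acc.pq_matches))
        if acc.pq_matches[q] or acc.pq_mismatches[q]
    }
    per_cycle = {
        c + 1: (int(acc.cy_matches[c]), int(acc.cy_mismatches[c]))
        for c in range(len(acc.cy_matches))
        if acc.cy_matches[c] or acc.cy_mismatches[c]
    }
    cycle_n = {
        c + 1: int(acc.cy_n_bases[c])
        for c in range(len(acc.cy_n_bases))
        if acc.cy_n_bases[c]
    }
    comp = {}
    for c in cycle_n:
        row = acc.cy_composition[c - 1]
        comp[c] = {
            b: int(row[i]) for i, b in enumerate("ACGTN") if row[i]
        }
    insert = {}
    for g, h in acc.insert_hist.items():
        d = {int(s): int(h[s]) for s in h.nonzero()[0]}
        if d:
            insert[g] = d
    return {
        "depth": depth,
        "per_q": per_q,
        "per_cycle": per_cycle,
        "cycle_n": cycle_n,
        "cycle_comp": comp,
        "insert": insert,
        "counters": {
            "records_seen": acc.records_seen,
            "mapped": acc.mapped,
            "paired": acc.paired,
            "duplicates": acc.duplicates,
            "qc_fail": acc.qc_fail,
        },
        "skipped_known": acc.skipped_known_site,
        "skipped_n": acc.skipped_n,
        "total_aligned": acc.total_aligned_bases,
    }
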