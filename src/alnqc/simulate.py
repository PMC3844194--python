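"""Synthetic alignment datasets with known ground truth.

Builds a random reference (optionally GC-graded along each contig so many
GC bins are populated), plants known variant sites, and emits coordinate-
sorted paired-end SAM with controlled per-cycle reported qualities,
controlled true error rates (calibrated to the reported quality or offset
from it by a fixed number of Phred units), controlled GC-dependent
fragment-sampling bias, a controlled insert-size distribution, and flagged
PCR duplicates.  A truth record retains the exact realised counts so every
downstream estimate has an oracle.

Sequencing errors are substitutions only (uniform over the three
alternative bases), matching the match/mismatch event model of the engine.
:func:`random_alignment_fixture` additionally emits structurally varied
alignments (soft clips, insertions, deletions, reverse strand, duplicates)
with no quality truth, for stress-testing the CIGAR walk against a
brute-force pileup.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .gcbias import build_window_schema
from .io import ReferenceGenome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_IDX = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
# row = base index, columns = the three alternative base codes
_OTHERS = np.array(
    [[c for c in _BASES if c != b] for b in _BASES], dtype=np.uint8
)


def default_quality_profile(read_length: int, levels: Sequence[int] = (30, 20, 10)) -> np.ndarray:
    """Step profile: reported quality drops along the read, one level per
    equal-length block of cycles (high quality early, low late)."""
    edges = np.linspace(0, read_length, len(levels) + 1).astype(int)
    prof = np.empty(read_length, dtype=np.int16)
    for lev, a, b in zip(levels, edges[:-1], edges[1:]):
        prof[a:b] = lev
    return prof


@dataclass
class SimulationParams:
    """Knobs of the generator; deterministic given ``seed``."""

    genome_bp: int = 100_000
    n_contigs: int = 2
    gc_gradient: tuple[float, float] = (0.25, 0.75)  # GC prob along each contig
    contig_gc: tuple[float, ...] | None = None  # constant GC per contig, overrides gradient
    read_length: int = 100
    n_pairs: int = 2_500  # ~5x depth at the defaults
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    insert_cap: int = 2_000
    reported_q_per_cycle: tuple[int, ...] | None = None  # default: 30/20/10 thirds
    quality_offset_phred: float = 0.0  # 0 = calibrated; -10 = 10x worse than reported
    gc_bias_multipliers: dict[int, float] = field(default_factory=dict)
    gc_window_bp: int = 100
    known_site_density: float = 0.001
    known_alt_fraction: float = 0.3
    duplicate_fraction: float = 0.02
    n_read_groups: int = 2
    seed: int = 0

    def quality_profile(self) -> np.ndarray:
        if self.reported_q_per_cycle is not None:
            prof = np.asarray(self.reported_q_per_cycle, dtype=np.int16)
            if len(prof) != self.read_length:
                raise ValueError("quality profile length != read_length")
            return prof
        return default_quality_profile(self.read_length)


@dataclass
class SimulationTruth:
    """Exact realised ground truth for one simulated dataset.

    Per-quality and per-cycle counts follow the default engine semantics:
    duplicates excluded; ``*_masked`` counts exclude bases at known variant
    sites (what the engine sees with the mask), ``*_all`` include them.
    """

    per_q_matches_masked: dict[int, int]
    per_q_mismatches_masked: dict[int, int]
    per_q_matches_all: dict[int, int]
    per_q_mismatches_all: dict[int, int]
    per_cycle_matches: dict[int, int]  # masked semantics
    per_cycle_mismatches: dict[int, int]
    depth: dict[str, np.ndarray]  # per-position, duplicates excluded
    insert_sizes: dict[str, np.ndarray]  # per read group, once per template
    gc_bias_multipliers: dict[int, float]
    known_sites: list[tuple[str, int]]  # 1-based
    n_unique_pairs: int
    n_duplicate_pairs: int
    params: SimulationParams


@dataclass
class SimulatedDataset:
    ref_path: str
    sam_path: str
    bam_path: str | None
    known_sites_path: str
    reference: ReferenceGenome
    truth: SimulationTruth


def _make_genome(params: SimulationParams, rng: np.random.Generator) -> dict[str, str]:
    sizes = [params.genome_bp // params.n_contigs] * params.n_contigs
    sizes[-1] += params.genome_bp - sum(sizes)
    g0, g1 = params.gc_gradient
    if params.contig_gc is not None and len(params.contig_gc) != params.n_contigs:
        raise ValueError("contig_gc length must equal n_contigs")
    contigs: dict[str, str] = {}
    for i, n in enumerate(sizes):
        if params.contig_gc is not None:
            p_gc = np.full(n, params.contig_gc[i])
        else:
            p_gc = np.linspace(g0, g1, n)
        is_gc = rng.random(n) < p_gc
        second = rng.random(n) < 0.5
        codes = np.where(
            is_gc,
            np.where(second, ord("G"), ord("C")),
            np.where(second, ord("A"), ord("T")),
        ).astype(np.uint8)
        contigs[f"c{i + 1}"] = codes.tobytes().decode("ascii")
    return contigs


def _write_fasta(contigs: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_vcf(sites, ref: ReferenceGenome, alt_codes, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, n in ref.lengths.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos1 in sites:
            r = ref.contigs[chrom][pos1 - 1]
            a = chr(alt_codes[chrom][pos1 - 1])
            fh.write(f"{chrom}\t{pos1}\t.\t{r}\t{a}\t.\t.\t.\n")


def simulate_dataset(
    params: SimulationParams, out_dir: str | os.PathLike, make_bam: bool = False
) -> SimulatedDataset:
    """Generate reference, known sites and a coordinate-sorted SAM (plus
    indexed BAM on request) under ``params``; byte-identical given the
    same seed."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    L = params.read_length
    if params.insert_mean < L and params.insert_sd == 0:
        raise ValueError("insert mean below read length with zero sd is infeasible")
    rng = np.random.default_rng(params.seed)
    contigs = _make_genome(params, rng)
    ref = ReferenceGenome(contigs)
    names = list(ref.contigs)
    lengths = np.array([ref.lengths[c] for c in names], dtype=np.int64)

    # --- known variant sites, with a fixed alternate allele each ---------
    known_pos0: dict[str, np.ndarray] = {}
    alt_codes: dict[str, np.ndarray] = {}
    known_sites: list[tuple[str, int]] = []
    for c in names:
        arr = ref.array(c)
        hit = np.nonzero(rng.random(len(arr)) < params.known_site_density)[0]
        known_pos0[c] = hit
        alts = np.zeros(len(arr), dtype=np.uint8)
        if len(hit):
            alts[hit] = _OTHERS[_BASE_TO_IDX[arr[hit]], rng.integers(0, 3, len(hit))]
        alt_codes[c] = alts
        known_sites.extend((c, int(p) + 1) for p in hit)

    # --- per-position GC-bias acceptance multiplier ----------------------
    mult_by_bin = np.ones(101)
    for b, m in params.gc_bias_multipliers.items():
        mult_by_bin[b] = m
    schema = build_window_schema(ref, params.gc_window_bp)
    mult_pos: dict[str, np.ndarray] = {c: np.ones(ref.lengths[c]) for c in names}
    for w in schema.windows:
        mult_pos[w.chrom][w.start_0based : w.end_exclusive] = mult_by_bin[w.gc_bin]
    max_mult = float(mult_by_bin.max())

    # --- draw fragments (contig ∝ length, start uniform, GC rejection) ---
    n = params.n_pairs
    cidx = np.zeros(0, dtype=np.int64)
    starts = np.zeros(0, dtype=np.int64)
    inserts = np.zeros(0, dtype=np.int64)
    p_contig = lengths / lengths.sum()
    while len(cidx) < n:
        batch = max(1024, 2 * (n - len(cidx)))
        ci = rng.choice(len(names), size=batch, p=p_contig)
        ins = np.rint(rng.normal(params.insert_mean, params.insert_sd, batch)).astype(np.int64)
        ins = np.clip(ins, L, np.minimum(params.insert_cap, lengths[ci]))
        st = (rng.random(batch) * (lengths[ci] - ins + 1)).astype(np.int64)
        accept = rng.random(batch) * max_mult
        thr = np.array([mult_pos[names[c]][s] for c, s in zip(ci, st)])
        keep = accept < thr
        cidx = np.concatenate([cidx, ci[keep]])
        starts = np.concatenate([starts, st[keep]])
        inserts = np.concatenate([inserts, ins[keep]])
    cidx, starts, inserts = cidx[:n], starts[:n], inserts[:n]
    rgroups = np.arange(n) % params.n_read_groups

    profile = params.quality_profile().astype(np.int64)
    delta = params.quality_offset_phred
    p_err_by_cycle = np.minimum(0.75, 10.0 ** (-(profile + delta) / 10.0))
    template_alt = rng.random(n) < params.known_alt_fraction

    # truth tallies
    tq_m_mask = np.zeros(100, dtype=np.int64)
    tq_mm_mask = np.zeros(100, dtype=np.int64)
    tq_m_all = np.zeros(100, dtype=np.int64)
    tq_mm_all = np.zeros(100, dtype=np.int64)
    tc_m = np.zeros(L, dtype=np.int64)
    tc_mm = np.zeros(L, dtype=np.int64)
    depth = {c: np.zeros(ref.lengths[c], dtype=np.int64) for c in names}

    seqs = np.zeros((2 * n, L), dtype=np.uint8)
    read_pos0 = np.zeros(2 * n, dtype=np.int64)
    read_pos0[0::2] = starts  # read1, forward
    read_pos0[1::2] = starts + inserts - L  # read2, reverse, stored ref-forward

    # stored-offset quality/error arrays: read1 stores machine order,
    # read2 stores machine order reversed (reference-forward layout)
    q_r1, q_r2 = profile, profile[::-1]
    p_r1, p_r2 = p_err_by_cycle, p_err_by_cycle[::-1]
    cyc0_r1 = np.arange(L)
    cyc0_r2 = L - 1 - np.arange(L)

    for ci, cname in enumerate(names):
        sel = np.nonzero(cidx == ci)[0]
        if not len(sel):
            continue
        arr = ref.array(cname)
        kpos = known_pos0[cname]
        for mate, (qv, pv, cyc0) in enumerate(
            ((q_r1, p_r1, cyc0_r1), (q_r2, p_r2, cyc0_r2))
        ):
            rows = 2 * sel + mate
            P = read_pos0[rows][:, None] + np.arange(L)[None, :]
            refc = arr[P]
            known = np.zeros(P.shape, dtype=bool)
            if len(kpos):
                j = np.searchsorted(kpos, P)
                j = np.minimum(j, len(kpos) - 1)
                known = kpos[j] == P
            base = refc.copy()
            alt_rows = template_alt[sel]
            put_alt = known & alt_rows[:, None]
            base[put_alt] = alt_codes[cname][P[put_alt]]
            err = rng.random(P.shape) < pv[None, :]
            sub = _OTHERS[_BASE_TO_IDX[base], rng.integers(0, 3, P.shape)]
            final = np.where(err, sub, base)
            seqs[rows] = final
            mism = final != refc
            qmat = np.broadcast_to(qv[None, :], P.shape)
            cmat = np.broadcast_to(cyc0[None, :], P.shape)
            for (tm, tmm), scored in (
                ((tq_m_mask, tq_mm_mask), ~known),
                ((tq_m_all, tq_mm_all), np.ones(P.shape, dtype=bool)),
            ):
                np.add.at(tm, qmat[scored & ~mism], 1)
                np.add.at(tmm, qmat[scored & mism], 1)
            np.add.at(tc_m, cmat[~known & ~mism], 1)
            np.add.at(tc_mm, cmat[~known & mism], 1)
            np.add.at(depth[cname], P.ravel(), 1)

    # --- duplicates -------------------------------------------------------
    n_dup = int(round(params.duplicate_fraction * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)

    insert_sizes = {
        f"rg{g + 1}": np.sort(inserts[rgroups == g])
        for g in range(params.n_read_groups)
        if (rgroups == g).any()
    }

    # --- emit SAM ---------------------------------------------------------
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ref.lengths[c]} for c in names],
        "RG": [{"ID": f"rg{g + 1}", "SM": "sim"} for g in range(params.n_read_groups)],
    }
    qual_r1 = np.asarray(q_r1, dtype=np.uint8)
    qual_r2 = np.asarray(q_r2, dtype=np.uint8)
    records = []
    for i in range(n):
        dup = False
        records.append((int(cidx[i]), i, 0, dup))
        records.append((int(cidx[i]), i, 1, dup))
    for i in dup_idx:
        records.append((int(cidx[i]), int(i), 0, True))
        records.append((int(cidx[i]), int(i), 1, True))
    # coordinate sort: (tid, pos)
    records.sort(key=lambda r: (r[0], int(read_pos0[2 * r[1] + r[2]])))

    ref_path = os.path.join(out_dir, "ref.fa")
    sam_path = os.path.join(out_dir, "reads.sam")
    vcf_path = os.path.join(out_dir, "known_sites.vcf")
    _write_fasta(contigs, ref_path)
    _write_vcf(known_sites, ref, alt_codes, vcf_path)

    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for tid, i, mate, dup in records:
            a = pysam.AlignedSegment(out.header)
            suffix = ".dup" if dup else ""
            a.query_name = f"frag{i:07d}{suffix}"
            a.reference_id = tid
            pos = int(read_pos0[2 * i + mate])
            mpos = int(read_pos0[2 * i + (1 - mate)])
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [(0, L)]
            a.query_sequence = seqs[2 * i + mate].tobytes().decode("ascii")
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in (qual_r1 if mate == 0 else qual_r2))
            )
            flag = 0x1 | 0x2  # paired, proper
            flag |= (0x20 | 0x40) if mate == 0 else (0x10 | 0x80)
            if dup:
                flag |= 0x400
            a.flag = flag
            a.next_reference_id = tid
            a.next_reference_start = mpos
            a.template_length = int(inserts[i]) if mate == 0 else -int(inserts[i])
            a.set_tag("RG", f"rg{int(rgroups[i]) + 1}")
            out.write(a)

    bam_path = None
    if make_bam:
        bam_path = os.path.join(out_dir, "reads.bam")
        pysam.samtools.view("-b", "-o", bam_path, sam_path, catch_stdout=False)
        pysam.index(bam_path)

    truth = SimulationTruth(
        per_q_matches_masked=_counts(tq_m_mask),
        per_q_mismatches_masked=_counts(tq_mm_mask),
        per_q_matches_all=_counts(tq_m_all),
        per_q_mismatches_all=_counts(tq_mm_all),
        per_cycle_matches={c + 1: int(v) for c, v in enumerate(tc_m) if v},
        per_cycle_mismatches={c + 1: int(v) for c, v in enumerate(tc_mm) if v},
        depth=depth,
        insert_sizes=insert_sizes,
        gc_bias_multipliers=dict(params.gc_bias_multipliers),
        known_sites=known_sites,
        n_unique_pairs=n,
        n_duplicate_pairs=n_dup,
        params=params,
    )
    return SimulatedDataset(
        ref_path=ref_path,
        sam_path=sam_path,
        bam_path=bam_path,
        known_sites_path=vcf_path,
        reference=ref,
        truth=truth,
    )


def _counts(arr: np.ndarray) -> dict[int, int]:
    return {q: int(v) for q, v in enumerate(arr) if v}


def random_alignment_fixture(
    out_dir: str | os.PathLike,
    genome_bp: int = 5_000,
    n_contigs: int = 2,
    n_reads: int = 300,
    read_length: tuple[int, int] = (30, 80),
    seed: int = 0,
    make_bam: bool = False,
) -> tuple[str, str, ReferenceGenome]:
    """Structurally varied fixture: random CIGARs with soft clips,
    insertions and deletions, reverse-strand reads, duplicates, a spread of
    MAPQs and reported qualities, and paired records with template lengths.
    Returns (sam_path, ref_path, reference).  No quality truth — meant for
    exact comparison against a brute-force pileup."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    sizes = [genome_bp // n_contigs] * n_contigs
    sizes[-1] += genome_bp - sum(sizes)
    contigs = {}
    for i, nbp in enumerate(sizes):
        codes = _BASES[rng.integers(0, 4, nbp)].copy()
        n_sites = max(1, nbp // 200)  # sprinkle reference Ns
        codes[rng.choice(nbp, n_sites, replace=False)] = ord("N")
        contigs[f"c{i + 1}"] = codes.tobytes().decode("ascii")
    ref = ReferenceGenome(contigs)
    ref_path = os.path.join(out_dir, "ref.fa")
    _write_fasta(contigs, ref_path)
    names = list(ref.contigs)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ref.lengths[c]} for c in names],
        "RG": [{"ID": "rgA", "SM": "fix"}, {"ID": "rgB", "SM": "fix"}],
    }
    reads = []
    for i in range(n_reads):
        L = int(rng.integers(read_length[0], read_length[1] + 1))
        tid = int(rng.integers(0, len(names)))
        arr = ref.array(names[tid])
        # CIGAR: [S] M (I|D M)* [S], query-consuming total == L
        lead_s = int(rng.integers(0, 6)) if rng.random() < 0.4 else 0
        tail_s = int(rng.integers(0, 6)) if rng.random() < 0.4 else 0
        core = L - lead_s - tail_s
        if core < 4:
            lead_s = tail_s = 0
            core = L
        cig: list[tuple[int, int]] = []
        if lead_s:
            cig.append((4, lead_s))
        remaining = core
        first = True
        while remaining > 0:
            if not first and remaining > 3 and rng.random() < 0.5:
                if rng.random() < 0.5:
                    k = int(rng.integers(1, 4))
                    cig.append((1, min(k, remaining - 1)))  # I consumes query
                    remaining -= min(k, remaining - 1)
                else:
                    cig.append((2, int(rng.integers(1, 5))))  # D consumes ref
            m = int(rng.integers(1, remaining + 1)) if remaining > 1 else 1
            cig.append((0, m))
            remaining -= m
            first = False
        if tail_s:
            cig.append((4, tail_s))
        ref_span = sum(n for op, n in cig if op in (0, 2))
        pos = int(rng.integers(0, ref.lengths[names[tid]] - ref_span))
        # build seq: M stretches copy reference with 10% substitution noise
        seq = np.zeros(L, dtype=np.uint8)
        qoff, rpos = 0, pos
        for op, k in cig:
            if op == 0:
                chunk = arr[rpos : rpos + k].copy()
                errs = rng.random(k) < 0.1
                chunk[errs] = _BASES[rng.integers(0, 4, int(errs.sum()))]
                seq[qoff : qoff + k] = chunk
                qoff += k
                rpos += k
            elif op in (1, 4):
                seq[qoff : qoff + k] = _BASES[rng.integers(0, 4, k)]
                qoff += k
            elif op == 2:
                rpos += k
        seq[rng.random(L) < 0.01] = ord("N")  # occasional read Ns
        quals = rng.integers(2, 41, L).astype(np.uint8)
        flag = 0
        if rng.random() < 0.5:
            flag |= 0x10
        if rng.random() < 0.05:
            flag |= 0x400
        if rng.random() < 0.03:
            flag |= 0x200
        tlen = 0
        if rng.random() < 0.5:
            flag |= 0x1 | 0x2 | (0x40 if rng.random() < 0.5 else 0x80)
            tlen = int(rng.integers(-500, 501))
        reads.append((tid, pos, cig, seq, quals, flag, tlen, i))
    reads.sort(key=lambda r: (r[0], r[1]))
    sam_path = os.path.join(out_dir, "reads.sam")
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for tid, pos, cig, seq, quals, flag, tlen, i in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i:05d}"
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = int(rng.integers(0, 61))
            a.cigartuples = cig
            a.query_sequence = seq.tobytes().decode("ascii")
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            a.flag = flag
            a.template_length = tlen
            a.set_tag("RG", "rgA" if i % 2 == 0 else "rgB")
            out.write(a)
    if make_bam:
        bam_path = os.path.join(out_dir, "reads.bam")
        pysam.samtools.view("-b", "-o", bam_path, sam_path, catch_stdout=False)
        pysam.index(bam_path)
        sam_path = bam_path
    return sam_path, ref_path, ref
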