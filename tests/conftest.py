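import numpy as np
import pysam
import pytest

from alnqc import AlignedRead, ReferenceGenome


def make_read(
    seq,
    cigar,
    pos_1based=1,
    chrom="c1",
    quals=None,
    reverse=False,
    mapq=60,
    tlen=0,
    paired=False,
    proper=False,
    duplicate=False,
    qc_fail=False,
    secondary=False,
    supplementary=False,
    unmapped=False,
    read_group="rg1",
    name="r1",
):
    if quals is None:
        quals = [30] * len(seq)
    elif isinstance(quals, int):
        quals = [quals] * len(seq)
    return AlignedRead(
        query_name=name,
        chrom=chrom,
        pos_1based=pos_1based,
        mapq=mapq,
        cigar=tuple(cigar),
        seq=seq,
        quals=np.array(quals, dtype=np.int16),
        paired=paired,
        proper_pair=proper,
        unmapped=unmapped,
        mate_unmapped=False,
        reverse_strand=reverse,
        read1=paired,
        read2=False,
        secondary=secondary,
        qc_fail=qc_fail,
        duplicate=duplicate,
        supplementary=supplementary,
        tlen=tlen,
        read_group=read_group,
    )


def write_sam(path, contigs, rows, read_groups=("rg1",)):
    """Write a SAM file from simple row dicts (pysam-backed)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in contigs.items()],
        "RG": [{"ID": g, "SM": "t"} for g in read_groups],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in rows:
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.get("name", "r")
            a.reference_id = list(contigs).index(row["chrom"]) if row.get("chrom") else -1
            a.reference_start = row.get("pos0", 0)
            a.mapping_quality = row.get("mapq", 60)
            a.cigarstring = row.get("cigar")
            a.query_sequence = row.get("seq")
            if row.get("seq"):
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in row.get("quals", [30] * len(row["seq"])))
                )
            a.flag = row.get("flag", 0)
            a.template_length = row.get("tlen", 0)
            a.set_tag("RG", row.get("rg", read_groups[0]))
            out.write(a)
    return str(path)


@pytest.fixture
def tiny_ref():
    return ReferenceGenome({"c1": "ACGTACGTACGTACGTACGT", "c2": "GGGGCCCCAAAATTTTGGCC"})
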