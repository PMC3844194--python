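"""High-level orchestration: scan one alignment file (fully or under a
sampling plan) into an accumulator and compile its report."""

from __future__ import annotations

import os

from .engine import QcAccumulator, ReadFilterPolicy
from .gcbias import GcWindowSchema, build_window_schema
from .io import (
    KnownSiteMask,
    ReferenceGenome,
    TargetRegions,
    read_alignments,
)
from .report import MetricsReport, compile_report
from .sampling import SamplingPlan, extrapolate, run_sampled


def scan_file(
    path: str | os.PathLike,
    ref: ReferenceGenome,
    mask: KnownSiteMask | None = None,
    policy: ReadFilterPolicy | None = None,
    plan: SamplingPlan | None = None,
    insert_cap: int = 2000,
) -> QcAccumulator:
    """Accumulate QC counts over one SAM/BAM file (whole file, or only the
    segments of ``plan``)."""
    mask = mask if mask is not None else KnownSiteMask()
    policy = policy if policy is not None else ReadFilterPolicy()
    if plan is not None:
        return run_sampled(path, ref, mask, plan, policy, insert_cap)
    acc = QcAccumulator(ref.lengths, insert_cap)
    for read in read_alignments(path):
        acc.add_record(read, ref, mask, policy)
    return acc


def analyze_file(
    path: str | os.PathLike,
    ref: ReferenceGenome,
    mask: KnownSiteMask | None = None,
    targets: TargetRegions | None = None,
    policy: ReadFilterPolicy | None = None,
    plan: SamplingPlan | None = None,
    window_bp: int = 100,
    insert_cap: int = 2000,
    label: str | None = None,
) -> MetricsReport:
    """Scan + derive: the one-call path from an alignment file to its
    :class:`MetricsReport`.

    The GC window schema and the coverage denominator follow the analysis
    space: target regions when a BED is given, the sampled segments when a
    plan is given, otherwise the whole genome.  For sampled runs the
    extrapolated genome-wide totals are recorded in the provenance.
    """
    if label is None:
        label = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    acc = scan_file(path, ref, mask, policy, plan, insert_cap)
    if plan is not None:
        space = plan.as_targets()
        provenance = {
            "mode": "sampled",
            "sampling_seed": str(plan.seed),
            "segment_bp": str(plan.segment_bp),
            "sampled_span": str(plan.sampled_span),
            "scale_factor": "%.6g" % plan.scale_factor,
        }
        ext = extrapolate(acc, plan)
        provenance["extrapolated_total_aligned_bases"] = "%.1f" % ext.total_aligned_bases
        provenance["extrapolated_records"] = "%.1f" % ext.records_seen
        span = plan.sampled_span
    elif targets is not None:
        space = targets
        provenance = {"mode": "targeted", "target_span": str(targets.total_span)}
        span = targets.total_span
    else:
        space = None
        provenance = {"mode": "full"}
        span = ref.genome_span
    schema = build_window_schema(ref, window_bp, space)
    provenance["window_bp"] = str(window_bp)
    provenance["insert_cap"] = str(insert_cap)
    provenance["alignment_file"] = os.path.basename(os.fspath(path))
    return compile_report(acc, schema, label, span, provenance)
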