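# Methods

## The statistic at the core

`alnqc` treats the reference genome as truth for well-behaved loci: after
excluding catalogued variant positions and N bases, a mismatch between an
aligned base and the reference is evidence of sequencing error.  The
empirical quality of any set of bases with `m` matches and `mm` mismatches
is the Phred scaling of the observed mismatch rate,

    Q_emp = −10 · log10( mm / (m + mm) ).

(The quantity inside the log is the mismatch *rate*; writing matches in the
numerator instead would assign low scores to good data and invert every
diagnostic, so the rate form is the only self-consistent definition.)
Empirical quality is tabulated two ways: per reported-quality bin — the
calibration diagnostic — and per machine cycle — the along-read error
profile.  A set with zero mismatches has an unbounded estimate and is
reported **censored** at a ceiling of (largest reported quality seen + 1),
keeping tables serialisable and plots bounded; censored bins are excluded
from the concordance summary.

The scalar concordance summary is the base-count-weighted mean squared
difference between empirical and reported quality over uncensored bins,
`Σ_q w_q (Q_emp(q) − q)²` with `w_q ∝ n_bases(q)`.  Weighting by base count
(rather than treating bins equally) makes the summary reflect the data the
caller will actually consume; an unweighted variant is a one-line change on
the table.

## Counting rules

Which bases are counted is the part of any QC tool that silently controls
every number, so the rules are explicit:

- **Read filter** (all configurable): unmapped, secondary, supplementary,
  duplicate and QC-fail records are excluded; MAPQ threshold defaults to 0.
  The rejection reason is the first failing criterion in the fixed order
  unmapped → secondary → supplementary → duplicate → qc_fail → mapq.
- **CIGAR walk**: exactly one event per query base consumed by M/=/X.
  Insertions and soft clips advance the machine cycle but contribute no
  match/mismatch/depth; hard clips and padding contribute nothing;
  deletions and reference skips advance the reference only.
- **Machine cycles**: SAM stores reverse-strand reads reference-forward, so
  for them cycle = read_length − query_offset; otherwise cycle =
  query_offset + 1.  Without this reversal, forward and reverse reads smear
  the per-cycle error signal.  Per-cycle base composition is tallied on the
  as-sequenced base (complemented for reverse-strand reads).  Soft-clipped
  bases occupy cycle numbering but are not tallied in composition — they
  were never aligned.
- **Known variant sites** (1-based, from a VCF — each REF base of a spanning
  allele masks one position — or a chrom/pos list) are excluded from
  match/mismatch and empirical-quality tallies **only**; they still count
  toward depth, GC windows and per-cycle base totals, because the exclusion
  exists to keep true polymorphism out of the *error-rate* estimate, not to
  hide coverage.
- **N bases** (read or reference) are neither match nor mismatch.  A
  position that is both masked and N is recorded as masked.
- **Insert size** is |TLEN|, counted once per template on the mate with
  TLEN > 0, requiring the paired and proper-pair flags; values above a
  configurable cap (default 2000 bp) are pooled into an overflow bin that
  is reported as a fraction.  Mean/median/sd/mode are histogram-exact over
  in-range sizes; mode and median ties break toward the smaller insert.
- The mean reported quality per cycle averages over all aligned bases at
  that cycle, including masked/N bases (they carry reported qualities).

The accumulator stores per-contig **base-resolution depth** rather than
per-window counts.  Window aggregation happens when the GC curve is built,
so one accumulator serves any window size, merging needs no window-schema
handshake (only an identical reference and insert cap), and depth can be
compared position-by-position against a brute-force pileup.  Merge is
field-wise addition: commutative, associative, with the empty accumulator
as identity — this is what makes per-region and per-file parallel or
sampled accumulation exact rather than approximate.

## GC bias

Windows of `window_bp` (default 100 — the natural size for integer 0–100 %
bins) tile each contig, or each BED target interval in capture mode, left
to right; a terminal fragment shorter than half a window is dropped.  The
GC bin is round-half-up of 100 × GC/(length − N); windows with > 50 % N (or
no non-N bases) are kept but flagged unusable and excluded from all
statistics.  For bin b, `mean_depth(b)` = total aligned bases in its usable
windows / their total length; `expected_depth` = total aligned bases in all
usable windows / usable span; `normalized_depth(b)` is their ratio.  Bin
weights are usable-**length** fractions (not window-count fractions — with
partial windows only length weighting preserves the identity below).  Two
algebraic identities hold by construction and are asserted in tests:
Σ_b weight(b) · normalized_depth(b) = 1, and the bias score
Σ_b weight(b) · (normalized_depth(b) − 1)² is invariant to scaling the
total read count.  Depth is attributed per aligned base, not per read
midpoint, making the curve exactly oracle-checkable.

Bins with no usable windows are absent from outputs, not zero.  A dataset
with no aligned bases in usable windows has no curve (expected depth zero
is an error, reported as NaN summaries at the report layer).

## Random sampling and extrapolation

A sampling plan draws ⌈total/segment⌉ non-overlapping segments: contig
chosen with probability proportional to its length, start uniform over
positions where the segment fits, overlaps rejection-resampled.  When
rejection cannot place a segment (near-saturating requests fragment the
free space), the plan falls back to drawing grid-aligned tiles without
replacement — still seeded, and exactly covering the genome when the full
span is requested, which gives the useful identity that a full-genome plan
reproduces the full scan bit for bit.  Plans serialise to a small text file
for audit and are deterministic given the seed.

A read belongs to the sampled accumulator iff its leftmost aligned base
lies inside a segment, and then **all** its bases are processed, including
those past the segment end.  This samples whole reads unbiasedly and avoids
truncation artifacts, at the cost of a ~read-length halo of depth outside
each segment; the GC schema for a sampled run tiles the sampled segments
themselves.  Sampled region queries see mapped records only, so flag
totals of a sampled run cover mapped records.

Extrapolation multiplies pure totals (aligned bases, record counts) by
genome span / sampled span.  Every rate or ratio statistic — empirical
quality, normalised GC depth, insert distribution, mean depth, flag
fractions — is scale-free and is deliberately **not** rescaled; sampled
reports carry the plan descriptor in their provenance.

Sampling noise floor: a 10 % sample of a 1 Mb genome at 5× holds ~5×10⁵
bases arriving in clusters of ~200 dependent bases (one fragment of a 100
bp pair).  Whole-sample statistics (mean depth, insert moments, empirical
quality of bins holding ≥ 10³ bases) are then reproducible to a few
percent, but a per-GC-bin normalised depth for a bin holding ~1 % of the
windows rests on only ~25 independent fragments and carries 10–20 %
relative sampling error.  At production scale (gigabase genomes, many-Mb
samples) the same per-bin comparison tightens by two orders of magnitude;
at desk scale it is the one headline metric a 10 % sample cannot pin down
to 5 %, and the corresponding check is expected to fail at that tolerance.

## The simulator, and what passing tests do and do not show

`simulate_dataset` emulates: a genome with controllable GC structure
(linear GC gradient along contigs by default, from 25 % to 75 %, to
populate many GC bins; or constant per-contig GC), uniformly placed
fragments with normal insert sizes (default mean 300 bp, sd 30, truncated
to [read length, cap]) sequenced as 100 bp proper pairs at ~5×, reported
qualities stepping 30/20/10 along the read (errors rising with cycle, as on
real instruments), substitution errors drawn per base at
10^(−(q+δ)/10) — δ = 0 is a calibrated run, δ = −10 a 10×-worse-than-
reported run (capped at 0.75, the ceiling of uniform-over-3 substitution) —
known variant sites at density 10⁻³ with 30 % of overlapping templates
carrying the alternate allele, 2 % duplicate pairs, and two read groups.
The truth record keeps the realised (not just nominal) per-bin counts,
per-position depth, and insert sizes, so downstream estimates are checked
against exact oracles rather than asymptotics.

Not emulated: indels and structural errors (the error model is
substitutions-only, matching the M/=/X event model), platform-specific
error motifs, mappability and alignment ambiguity, overlapping-mate
double-counting, splice-aware RNA alignment artifacts, and base-composition
biases of real library chemistry.  Passing tests therefore demonstrate that
the *counting and statistics* are exact and that planted signals of
realistic size are recovered; they do not certify behaviour on pathological
alignments (supplementary chains, CRAM, BAQ-adjusted qualities) beyond the
structural variety the random-CIGAR fixture covers (soft clips, insertions,
deletions, reverse strand, duplicates, N bases).

A second generator, `random_alignment_fixture`, produces structurally
varied alignments with no quality truth; its only purpose is exact
agreement between the vectorised engine and an independent nested-loop
pileup.

## Numerical and design choices

- Integer GC bins use round-half-up (platform-stable, unlike banker's
  rounding).
- All interval arithmetic is 0-based half-open internally; SAM/VCF 1-based
  coordinates are converted exactly once at the parser boundary.
- Quality and cycle count arrays auto-grow; nothing caps reported quality
  or read length.
- Reads with `*` sequence or qualities are kept in flag statistics and
  excluded from base-level metrics.
- Records lacking a read group fall into a synthetic `ungrouped` lane so
  per-lane insert curves always have a key.
- Text and XML serialise floats at fixed 4-decimal precision and are
  byte-identical across reruns on identical input; the XML validates
  against the XSD shipped in the package.  Plotted arrays are exported as
  TSV next to each image so figures are testable by value, not by pixel.
- Figures are rendered natively with matplotlib; the HTML report is static
  with client-side table sorting only, viewable without network access.
- The multi-sample page never pools accumulators across samples: batch
  effects are visible only as separate per-sample curves.

## Known limitations

CRAM input, alignment writing and genotype-aware VCF parsing are out of
scope.  The tool diagnoses miscalibration but does not recalibrate.  Depth
is raw (no mappability or overlapping-mate correction).  The GC model is
base-level, not fragment-level.  Analyses at desk scale in the test suite
use kilobase-to-megabase genomes with the sample sizes stated above; the
methods are size-independent, but the sampling-noise caveat above applies
to any small analysed span.
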