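# alnqc

Quality assessment for next-generation sequencing **alignments**.  Given
coordinate-sorted SAM/BAM files and a reference FASTA, `alnqc` computes the
diagnostics a sequencing core or analysis group inspects before variant
calling or expression analysis:

- **Empirical vs reported base quality.**  Every aligned base is compared
  with the reference; the empirical quality of a bin with `m` matches and
  `mm` mismatches is the Phred-scaled mismatch rate
  `Q_emp = −10·log10(mm / (m + mm))`, computed per reported-quality bin and
  per machine cycle, excluding known variant sites (so true polymorphism is
  not scored as error) and N bases.  A base-count-weighted mean squared
  difference `Σ w_q (Q_emp(q) − q)²` summarises concordance in one number;
  large values mean base-quality recalibration is warranted.
- **GC-bias curve.**  The genome (or the BED target regions of a capture
  experiment) is tiled into fixed windows (default 100 bp), each assigned an
  integer GC bin 0–100.  Mean depth per bin, normalised by the expected
  depth from total aligned bases, sits at 1 for unbiased coverage; the
  genome-weighted mean squared deviation from 1 is the scalar GC-bias score.
- **Insert sizes.**  Per read group (lane), the distribution of template
  lengths (|TLEN|, counted once per proper pair) with histogram-exact mode,
  mean, median and sd.
- **Coverage and flags.**  Mean depth, mapped/duplicate/paired fractions,
  MAPQ histogram.
- **Random-region sampling.**  Very large alignments can be evaluated from
  randomly drawn genomic segments; scale-free statistics pass through
  unchanged and totals are extrapolated by genome span / sampled span.
- **Reports.**  Per-sample tab-separated text and XML (validated against a
  shipped XSD, database-ready), four diagnostic plots with their plotted
  arrays exported as TSV, and a static multi-sample HTML page with a
  sortable summary table — overlaying many samples exposes batch effects.

A seeded simulator (`alnqc.simulate`) generates reference + reads with
planted error rates, GC bias, insert distribution and known variant sites,
so every statistic above can be checked against ground truth.

## Worked example

Simulate a 50 kb genome with 1,500 read pairs whose true error rate is 10×
worse than the reported qualities claim (reported q 30/20/10 along the
read), then run the tool:

```sh
python -c "
from alnqc import SimulationParams, simulate_dataset
simulate_dataset(SimulationParams(genome_bp=50_000, n_pairs=1_500, seed=7,
                                  quality_offset_phred=-10.0), 'sim')"
alnqc sim/reads.sam -r sim/ref.fa --known-sites sim/known_sites.vcf -o qc
```

`qc/reads.qc.txt` then contains (excerpt):

```
[summary]
quality_mse	91.4419
gc_bias_score	0.0178
mean_depth	6.0000
duplicate_fraction	0.0196
[quality_concordance]
reported_q	n_matches	n_mismatches	n_bases	empirical_q	censored
10	25232	76689	101921	1.2353	0
20	89025	9880	98905	10.0046	0
30	97947	967	98914	20.0983	0
```

Reading it: bases reported as q20 are empirically q10.0 and q30 bases are
q20.1 — the planted 10-Phred miscalibration, recovered exactly (the q10 bin
saturates because a 100% error rate is impossible for substitutions).  The
concordance MSE of ≈91 ≈ 10² flags the run for recalibration; the GC-bias
score near zero says coverage is even across GC content; mean depth is
1,500 pairs × 200 bases / 50 kb = 6×.  `qc/index.html` links per-sample
pages embedding the four panels; `qc/reads.qc.xml` carries the same numbers
for a tracking database.

For a large BAM, add `--sample-bp 100000000 --segment-bp 5000000 --seed 1`
to evaluate ~100 Mb of randomly drawn 5 Mb segments instead of the whole
file (requires a BAM index); the sampling plan is written next to the
reports for audit.

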