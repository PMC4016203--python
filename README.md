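# maxcounts

Peak-coverage expression summarization for RNA-seq exons, with the
surrounding pipeline and a bias/robustness diagnostic battery.

## The problem

The standard way to quantify an exon (or single-isoform transcript) from
RNA-seq is the total number of reads aligned to it (*totcounts*,
N<sub>ij</sub> for exon *i* in library *j*). Totcounts inherit two
systematic distortions: they scale with exon length, and they integrate
the non-uniform read coverage that library preparation leaves along a
transcript (priming-site preference, under-representation of the 3'
end). Two transcripts present at the same concentration can therefore
receive very different totcounts.

This package implements an alternative summary: compute the per-base
coverage N<sub>ijp</sub> — the number of reads covering each position
*p* of the exon — and take its maximum,

```
maxcounts_ij = max_p N_ijp
```

The peak of the coverage profile sits at the best-represented positions
of the transcript, so it is nearly independent of exon length and robust
to coverage non-uniformity, while remaining a plain count that scales
with abundance.

The package is aimed at people building or evaluating RNA-seq
quantification pipelines. It provides:

- `readprep` — FASTQ quality trimming (Phred < 20 end runs), length
  filtering (< 33 bp discarded) and re-mating of pairs / separation of
  singletons;
- `sieve` — alignment filtering: multireads (NH > 1 or duplicate
  records) and records with reference similarity
  `(aligned_len − NM)/aligned_len` below 97% are removed;
- `counting` — per-exon coverage profiles (CIGAR-aware, spliced reads
  honored), maxcounts and totcounts, count matrices, the 0.5-mean
  low-expression filter;
- `normalization` — TMM scaling factors, RPKM, between-lane and
  within-lane (covariate-stratified) full-quantile normalization;
- `diagnostics` — binned cubic-spline bias curves, count-concentration
  summaries, variance/CV curves, spike-in accuracy regression, the Δ
  statistic for equal-concentration pairs, and the relative-variation
  robustness statistic;
- `simulate` — a seeded generator of synthetic references, annotations
  and alignments with controlled positional bias, spike-in panels,
  multireads and mismatches;
- a `maxcounts` CLI chaining the stages with a run manifest.

## Worked example

Two synthetic spike-in transcripts at identical concentration, one with
uniform sequencing preference and one highly skewed (gamma shape 0.5),
sequenced to ~100k reads:

```python
import math
import numpy as np
from maxcounts import (SimConfig, make_spikein_panel, simulate_library,
                       count_library, delta_stat)
from maxcounts.simulate import to_aligned_reads

config = SimConfig(seed=1, depth=100_000, three_prime_decay=math.inf)
truth, conc = make_spikein_panel(2, 1e-6, 1e-6, config, length=1000,
                                 preference_k=np.array([1e6, 0.5]))
reads = simulate_library(truth, config, replicate_seed=1001)
mx, tot = count_library(to_aligned_reads(reads), truth.exons)
print("totcounts:", tot.to_dict())
print("maxcounts:", mx.to_dict())
print(f"delta(totcounts) = {delta_stat(tot.iloc[0], tot.iloc[1]):+.1f}%")
print(f"delta(maxcounts) = {delta_stat(mx.iloc[0], mx.iloc[1]):+.1f}%")
```

Output:

```
totcounts: {'SPIKE-000': 74820, 'SPIKE-001': 25397}
maxcounts: {'SPIKE-000': 2911, 'SPIKE-001': 2863}
delta(totcounts) = +49.3%
delta(maxcounts) = +0.8%
```

The skewed transcript yields a third as many reads (its inefficient
regions go unsequenced), so totcounts disagree by ~49% despite equal
concentrations. The coverage peaks, however, sit in fully efficient
hotspot regions on both transcripts, so maxcounts agree to within 1%.

The same contrast holds for exon length: on a 2000-exon simulated
library with uniform coverage, Spearman correlation with exon length is
about 0.72 for totcounts and 0.13 for maxcounts
(`maxcounts.experiments.length_bias_experiment`).

## Command line

```
maxcounts simulate --config sim.yaml --out-dir fixtures/
maxcounts sieve    --bam lib.sam --min-similarity 0.97 --out lib.sieved.sam
maxcounts count    --bam lib.sieved.sam --bed exons.bed --method max --out counts.tsv
maxcounts normalize --counts counts.tsv --method tmm --out counts.tmm.tsv
maxcounts run      --config run.yaml --out-dir results/   # whole pipeline + manifest
```

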