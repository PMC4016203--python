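# Methods

## Summarization model

For exon *i* in library *j*, let N<sub>ijp</sub> be the number of
alignment records whose aligned blocks cover base *p* of the exon
(CIGAR M/=/X operations; N and D operations open gaps that contribute
no coverage; read bases outside the exon contribute nothing). The two
summaries are

- **totcounts**: the number of distinct records with at least one
  aligned base inside the exon (a one-base overlap counts fully, a
  record whose two blocks both fall in the exon counts once);
- **maxcounts**: max<sub>p</sub> N<sub>ijp</sub>.

Invariants that follow directly and are enforced by tests: maxcounts ≤
totcounts; both are zero together; they coincide for 1-bp exons and
when every counted read fully contains the exon.

Counting decisions: exons are summarized independently (a read
overlapping several exons is counted for each; no fractional
assignment), paired-end mates are two independent records, and
duplicates are kept. Coverage is unstranded; strand is carried through
the annotation but never consulted. Profiles are accumulated with
block-interval difference arrays, O(blocks) per read, and checked
against a naive per-base oracle in the test suite.

## Pre-processing and alignment filtering

Quality trimming removes the maximal runs of bases with Phred quality
below 20 from both read ends (interior low-quality bases survive);
reads shorter than 33 bp after trimming are discarded; surviving pairs
are re-mated positionally and lone survivors become singletons. Both
thresholds are strict: a read of exactly 33 bp is kept. End-run
clipping is the simplest trimming rule consistent with a per-end
quality threshold; sliding-window schemes are deliberately not
implemented so results are exactly reproducible.

The alignment sieve removes (a) multireads — any read reported at more
than one location, detected from the NH tag, from secondary or
supplementary flags, or from read-id multiplicity within a mate when no
tag is present — and (b) records whose similarity to the reference,
(aligned_len − NM)/aligned_len, is strictly below 0.97. The denominator
counts aligned read bases only, since soft-clipped bases were never
compared to the reference; similarity is per record. A record at
exactly 0.97 is kept.

## Normalization

- **TMM** follows the original trimmed-mean-of-M-values formulation:
  reference library by upper-quartile proximity to the mean upper
  quartile; M and A computed on exons positive in both libraries;
  double trim (30% on M, 5% on A, rank-based); inverse
  binomial-variance weights; factors rescaled to geometric mean 1. The
  implementation is cross-checked in the tests against an independent
  literal evaluation of the formula and against edgeR's
  `calcNormFactors`. Note that TMM sees only proportions y/N, so it is
  exactly invariant to joint rescaling and — because the variance
  weights see absolute counts — only approximately invariant to
  rescaling a single library. For the same reason, applying the factors
  and re-estimating reproduces the same factors; the meaningful fixed
  point, which tests assert, is that effective library sizes
  (factor × total) equalize.
- **RPKM**: N<sub>ij</sub> / (L<sub>i</sub>/10³ · N<sub>·j</sub>/10⁶),
  with library totals from the raw (not TMM-scaled) matrix.
- **Full-quantile** normalization maps each group of values onto the
  mean empirical quantile profile of all groups, where a group's
  quantile function interpolates its order statistics at
  mid-probabilities (i + 0.5)/n. For equal-size groups this reduces
  exactly to averaging order statistics. Ties receive the common
  mid-rank value. Between-lane treats libraries as groups; within-lane
  stratifies exons into 10 near-equal strata by covariate rank (exon
  length by default, the stratification shared across libraries) and
  normalizes across strata within each library. Zero counts
  participate; rows are only removed earlier by the 0.5-mean filter.
  When both are requested the within-lane step runs first; the order is
  exposed in the CLI.

The low-expression filter drops exons whose mean raw count across the
replicates at hand is strictly below 0.5 (a mean of exactly 0.5 is
kept). Whether the mean is taken across all libraries or within each
replicate group is exposed as a flag (`per_group`), defaulting to
across-all.

## Diagnostics

Curves use the binned-spline convention: points sorted by the x
covariate, averaged in consecutive bins of 5000 exons (the last bin may
be smaller), and a natural interpolating cubic spline through the bin
means — the bins already smooth, so no additional smoothing parameter
is introduced. Log transforms are log2(x + 1) so zeros stay
representable. The Spearman correlation of the raw (x, y) pairs is
attached to each bias curve as a scalar score.

- **Count concentration**: nonzero-count exons sorted by decreasing
  count; the summary reports the percentage of exons holding 50% and
  90% of the library's counts.
- **Variance/CV**: across the replicates of one group, the variance
  curve uses unbiased variance of log-counts vs their mean; the CV
  curve uses sd/mean of raw counts vs the log of the raw mean; both
  x-axes are affinely rescaled to [0, 1] so differently scaled measures
  are comparable.
- **Spike-in accuracy**: least-squares regression of log10 counts on
  log10 true concentrations; Pearson r with the standard t-transform
  p-value; per-spike-in residuals. Zero-count spike-ins are excluded
  and at least three points are required.
- **Δ statistic**: (X_A − X_B)/(X_A + X_B)·100 for two transcripts of
  (near-)equal true concentration; antisymmetric, bounded by ±100.
- **Relative variation**: (X_orig − X_filt)/(X_orig + 1)·100 per entry,
  on raw counts; the +1 avoids division by zero; the fraction of
  entries at exactly 0% summarizes robustness to filtering.

## Synthetic-data generator

The generator emulates the features the diagnostics need, on a
generated pseudo-chromosome so alignments are self-consistent without
downloads:

- exon lengths log-normal (median 500 bp, σ(ln) = 1.0, clipped to
  [50, 5000] bp); GC Beta(20, 22) (mean ≈ 0.48, sd ≈ 0.08, typical of
  exonic sequence); expression log-normal with σ(ln) = 1.0 — a moderate
  spread chosen so that length and expression contribute comparably to
  count variation in the bias experiments;
- **positional preference**: per start position an efficiency
  e_p = min(Gamma(k, 1/k), 1), one draw per read-length-wide block so
  hotspots are wider than a read, times an exponential 3'-end decay
  exp(−d/decay) over a window of 4·decay bp (default decay 150 bp).
  k → ∞ gives uniform coverage; k ≈ 0.5 gives strongly skewed coverage.
  Efficiency vectors are drawn once per experiment and shared across
  replicates, reproducing the empirically reproducible coverage
  patterns of a transcript across libraries;
- **read yield**: reads per exon are Poisson with mean proportional to
  expression × Σ<sub>p</sub> e<sub>p</sub>, and start positions are
  drawn with probabilities e/Σe. Capping efficiency at 1 makes skewed
  preference *lower* the total yield while fully efficient hotspots are
  sequenced at the concentration-determined rate — the mechanism that
  lets peak coverage track abundance when the integral does not. (A
  model in which weights are merely renormalized to sum 1 leaves the
  yield independent of skew and cannot produce the totcounts
  discrepancy between equal-concentration transcripts.)
- spike-in panels: single-isoform transcripts, each on its own
  reference sequence, with log-uniformly spaced known concentrations;
- artifacts: a configurable fraction of reads receives a second mapping
  record (NH = 2 on both), every read carries
  Binomial(read_length, mismatch_rate) background mismatches, and a
  separate fraction is forced below 97% similarity; NM tags and read
  sequences are mutated consistently;
- read length 36 bp single-end by default; counting treats mates
  independently, so single-end exercises all counting logic.

All randomness flows through explicitly seeded numpy generators;
identical configuration and seeds give byte-identical FASTQ/SAM/BED/
FASTA outputs.

What the generator does **not** model: sequence-dependent error
profiles, fragment-size distributions, splice-junction reads (the
counting layer supports spliced alignments and is oracle-tested on
them, but simulated reads are contiguous), GC-dependent amplification
(GC is annotated but does not drive yield), and stranded protocols.
Passing the evaluation battery on this generator therefore shows that
the summarization and its diagnostics behave as designed under
controlled positional bias — not that any particular real library is
free of other artifacts.

## Evaluation scenarios and problem sizes

The experiments module fixes the study conditions: length bias on 2000
exons at ~1.4M reads (mean per-base coverage ≈ 20×), uniform
preference; the Δ contrast on two 1-kb transcripts of equal
concentration (uniform vs k = 0.5) at 100k reads × 6 replicates;
spike-in recovery on 30 transcripts spanning three decades of
concentration at 100k reads × 3 replicates; robustness on 500 exons ×
2 replicates with 10% multireads and 5% low-similarity reads; count
concentration on 1000 exons × 2 replicates. These sizes keep every
scenario around a minute on one core while the measured contrasts
exceed their seed-to-seed variability by an order of magnitude.

## Known limitations

- Exons are summarized as given; overlapping exons are counted
  independently and no gene- or transcript-level aggregation is
  offered.
- Similarity filtering requires NM tags; files without them fail
  loudly rather than silently skipping the filter.
- The within-lane full-quantile step removes the covariate's effect on
  the whole count distribution per stratum; residual within-stratum
  trends survive (they are bounded by the stratum width).
- maxcounts of very short exons at high depth saturate more slowly than
  totcounts grow; extreme-value growth of the coverage peak with exon
  length is small but not exactly zero.
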