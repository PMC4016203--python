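"""Synthetic RNA-seq alignment generator with controlled coverage bias.

Emulates the statistical structure the diagnostics battery probes:

* exons of log-normal length and beta-distributed GC content on a
  generated pseudo-chromosome, so SAM coordinates are self-consistent;
* non-uniform positional "sequencing preference": each exon carries a
  per-start-position efficiency e_p = min(Gamma(k, 1/k), 1), drawn once
  per read-length-wide block so hotspots are wider than a read, shared
  across replicates (real coverage patterns are reproducible between
  libraries of the same transcript);
* 3'-end under-representation: an exponential decay of efficiency over a
  window at the 3' end, as reverse transcription with random hexamers
  produces;
* read yield proportional to expression × total efficiency, so a
  transcript with skewed preference yields fewer reads at equal
  concentration while its best-covered positions still reflect the true
  abundance — the mechanism behind the coverage-bias contrast between
  total and peak summarization;
* spike-in panels with known, log-uniformly spaced concentrations;
* multireads (a second mapping record, NH=2) and mismatch-bearing
  alignments with consistent NM tags.

All randomness flows through numpy Generators seeded from explicit
integers; identical configuration and seeds give byte-identical output
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import ExonRecord, ExonTable, save_exons
from .sieve import AlignedRead

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimRead",
    "simulate_preference",
    "simulate_truth",
    "make_spikein_panel",
    "simulate_library",
    "simulate_experiment",
    "to_aligned_reads",
    "write_sam",
    "write_sim_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions of a simulated experiment.

    Lengths are log-normal in bp (clipped to [length_min, length_max]),
    GC fractions Beta(gc_alpha, gc_beta), expression log-normal in
    arbitrary units. ``depth`` is the expected number of reads per
    library. ``preference_k`` is the gamma shape of positional
    efficiency (k → ∞ gives uniform coverage); ``three_prime_decay`` is
    the half-distance in bp of the exponential efficiency decay at the
    3' end (infinite disables it).
    """

    seed: int = 1
    n_exons: int = 2000
    length_meanlog: float = math.log(500.0)
    length_sdlog: float = 1.0
    length_min: int = 50
    length_max: int = 5000
    gc_alpha: float = 20.0
    gc_beta: float = 22.0
    expr_meanlog: float = 0.0
    expr_sdlog: float = 1.0
    read_length: int = 36
    depth: int = 500_000
    preference_k: float = 1.0
    preference_block: int | None = None  # default: read_length
    three_prime_decay: float = 150.0
    multiread_fraction: float = 0.0
    mismatch_rate: float = 0.002
    low_similarity_fraction: float = 0.0
    n_replicates: int = 3
    spacer: int = 100

    def __post_init__(self) -> None:
        for name in ("multiread_fraction", "mismatch_rate", "low_similarity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.read_length > self.length_min:
            raise ValueError("read_length must not exceed length_min")
        for name in ("n_exons", "read_length", "depth", "preference_k",
                     "three_prime_decay", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def block(self) -> int:
        return self.preference_block or self.read_length


@dataclass
class GroundTruth:
    """Known quantities of a simulated experiment.

    ``weights`` are per-exon start-position preference vectors normalized
    to sum 1 and shared across replicates; ``efficiency`` holds the raw
    per-position efficiencies in (0, 1] whose mean sets the read yield of
    the exon relative to its expression.
    """

    exons: ExonTable
    sequences: dict[str, str]
    expression: pd.Series
    weights: dict[str, np.ndarray]
    efficiency: dict[str, np.ndarray]

    def yield_factor(self) -> pd.Series:
        return pd.Series({eid: float(e.mean()) for eid, e in self.efficiency.items()})


def _efficiency(n_pos: int, k: float, decay: float, block: int,
                rng: np.random.Generator) -> np.ndarray:
    n_blocks = (n_pos + block - 1) // block
    g = np.minimum(rng.gamma(k, 1.0 / k, n_blocks), 1.0)
    e = np.repeat(g, block)[:n_pos]
    if math.isfinite(decay):
        window = min(n_pos, int(round(4 * decay)))
        if window > 0:
            d = np.arange(window)
            e[n_pos - window:] *= np.exp(-d / decay)
    return np.maximum(e, 1e-12)


def simulate_preference(length: int, k: float, decay: float, seed: int,
                        read_length: int = 36,
                        block: int | None = None) -> np.ndarray:
    """Per-start-position preference weights for one exon, summing to 1.

    Efficiency is one clipped Gamma(k, 1/k) draw per ``block`` positions
    (default: one read length) times an exponential 3'-end decay;
    deterministic under a fixed seed.
    """
    if length < read_length:
        raise ValueError(
            f"exon length {length} shorter than read length {read_length}"
        )
    rng = np.random.default_rng(seed)
    e = _efficiency(length - read_length + 1, k, decay, block or read_length, rng)
    return e / e.sum()


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def simulate_truth(config: SimConfig) -> GroundTruth:
    """Draw the fixed, replicate-shared layer of an experiment.

    Builds one pseudo-chromosome with exons separated by spacers, and per
    exon a length, GC content, expression level and positional
    efficiency vector.
    """
    rng = np.random.default_rng(config.seed)
    lengths = np.exp(rng.normal(config.length_meanlog, config.length_sdlog,
                                config.n_exons))
    lengths = np.clip(lengths, config.length_min, config.length_max).astype(int)
    gcs = rng.beta(config.gc_alpha, config.gc_beta, config.n_exons)
    expr = np.exp(rng.normal(config.expr_meanlog, config.expr_sdlog, config.n_exons))

    chrom = "sim1"
    parts: list[str] = []
    pos = 0
    table = ExonTable()
    weights: dict[str, np.ndarray] = {}
    efficiency: dict[str, np.ndarray] = {}
    expression: dict[str, float] = {}
    for i in range(config.n_exons):
        parts.append(_random_sequence(config.spacer, 0.5, rng))
        pos += config.spacer
        eid = f"ex{i:05d}"
        length = int(lengths[i])
        parts.append(_random_sequence(length, float(gcs[i]), rng))
        table.add(ExonRecord(chrom=chrom, start=pos, end=pos + length,
                             exon_id=eid, strand="+", gc=float(gcs[i])))
        e = _efficiency(length - config.read_length + 1, config.preference_k,
                        config.three_prime_decay, config.block, rng)
        efficiency[eid] = e
        weights[eid] = e / e.sum()
        expression[eid] = float(expr[i])
        pos += length
    parts.append(_random_sequence(config.spacer, 0.5, rng))
    return GroundTruth(
        exons=table,
        sequences={chrom: "".join(parts)},
        expression=pd.Series(expression),
        weights=weights,
        efficiency=efficiency,
    )


def make_spikein_panel(
    n: int,
    conc_min: float,
    conc_max: float,
    config: SimConfig,
    length: int = 1000,
    preference_k: np.ndarray | None = None,
) -> tuple[GroundTruth, pd.Series]:
    """A panel of single-isoform transcripts with known concentrations.

    Concentrations are log-uniformly spaced over [conc_min, conc_max]
    (consecutive log-ratios equal). Each transcript sits on its own
    reference sequence, like real spike-in controls. ``preference_k`` may
    give a per-transcript gamma shape to mix uniform and skewed coverage.

    Returns the panel's ground truth and its concentration table.
    """
    if n < 2:
        raise ValueError("a spike-in panel needs at least 2 transcripts")
    rng = np.random.default_rng(config.seed)
    concs = (np.geomspace(conc_min, conc_max, n) if conc_min != conc_max
             else np.full(n, conc_min))
    ks = (np.full(n, config.preference_k) if preference_k is None
          else np.asarray(preference_k, dtype=float))
    table = ExonTable()
    sequences: dict[str, str] = {}
    weights: dict[str, np.ndarray] = {}
    efficiency: dict[str, np.ndarray] = {}
    expression: dict[str, float] = {}
    for i in range(n):
        sid = f"SPIKE-{i:03d}"
        gc = float(rng.beta(config.gc_alpha, config.gc_beta))
        sequences[sid] = _random_sequence(length, gc, rng)
        table.add(ExonRecord(chrom=sid, start=0, end=length, exon_id=sid,
                             strand="+", gc=gc))
        e = _efficiency(length - config.read_length + 1, float(ks[i]),
                        config.three_prime_decay, config.block, rng)
        efficiency[sid] = e
        weights[sid] = e / e.sum()
        expression[sid] = float(concs[i])
    truth = GroundTruth(exons=table, sequences=sequences,
                        expression=pd.Series(expression),
                        weights=weights, efficiency=efficiency)
    return truth, pd.Series(expression, name="concentration")


@dataclass
class SimRead:
    """One simulated alignment (plus its read) before serialization."""

    read_id: str
    chrom: str
    pos: int
    length: int
    nm: int
    nh: int
    mismatch_offsets: tuple[int, ...] = ()
    secondary: bool = False


def simulate_library(truth: GroundTruth, config: SimConfig,
                     replicate_seed: int) -> list[SimRead]:
    """Sample one library's alignments from the shared ground truth.

    Per exon, the read count is Poisson with mean proportional to
    expression × Σ efficiency (so preference skew lowers yield); start
    positions follow the exon's preference weights. A configured fraction
    of reads receives a second mapping record (NH=2) at a random other
    location; a configured fraction is emitted with enough mismatches to
    fall below 97% similarity; all reads carry Binomial(L, mismatch_rate)
    background mismatches.
    """
    rng = np.random.default_rng(replicate_seed)
    rl = config.read_length
    total_intensity = sum(
        truth.expression[e.exon_id] * truth.efficiency[e.exon_id].sum()
        for e in truth.exons
    )
    scale = config.depth / total_intensity if total_intensity > 0 else 0.0
    low_sim_nm = max(2, math.ceil(0.05 * rl))
    reads: list[SimRead] = []
    serial = 0
    for exon in truth.exons:
        eff = truth.efficiency[exon.exon_id]
        lam = scale * truth.expression[exon.exon_id] * eff.sum()
        n_reads = rng.poisson(lam)
        if n_reads == 0:
            continue
        w = truth.weights[exon.exon_id]
        starts = rng.choice(w.size, size=n_reads, p=w) + exon.start
        n_mm = rng.binomial(rl, config.mismatch_rate, size=n_reads)
        is_low = rng.random(n_reads) < config.low_similarity_fraction
        is_multi = rng.random(n_reads) < config.multiread_fraction
        chrom_len = len(truth.sequences[exon.chrom])
        for s, k_mm, low, multi in zip(starts, n_mm, is_low, is_multi):
            nm = max(int(k_mm), low_sim_nm) if low else int(k_mm)
            nm = min(nm, rl)
            offsets = tuple(sorted(rng.choice(rl, size=nm, replace=False))) if nm else ()
            nh = 2 if multi else 1
            rid = f"sim.{replicate_seed}.{serial}"
            serial += 1
            reads.append(SimRead(rid, exon.chrom, int(s), rl, nm, nh, offsets))
            if multi:
                alt = int(rng.integers(0, chrom_len - rl + 1))
                reads.append(SimRead(rid, exon.chrom, alt, rl, nm, nh,
                                     offsets, secondary=True))
    return reads


def to_aligned_reads(reads: list[SimRead]) -> list[AlignedRead]:
    return [
        AlignedRead(read_id=r.read_id, ref=r.chrom, pos=r.pos,
                    blocks=((r.pos, r.pos + r.length),), nm=r.nm, nh=r.nh,
                    mate=1, secondary=r.secondary)
        for r in reads
    ]


def _mutate(seq: str, offsets: tuple[int, ...], rng: np.random.Generator) -> str:
    if not offsets:
        return seq
    out = list(seq)
    for off in offsets:
        choices = [b for b in "ACGT" if b != out[off]]
        out[off] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def write_sam(reads: list[SimRead], truth: GroundTruth, path: str | Path,
              mutation_seed: int = 0) -> int:
    """Serialize simulated alignments as a SAM file with NM/NH tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": len(seq)}
               for chrom, seq in truth.sequences.items()],
    }
    rng = np.random.default_rng(mutation_seed)
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for r in reads:
            rec = pysam.AlignedSegment()
            rec.query_name = r.read_id
            rec.flag = 256 if r.secondary else 0
            rec.reference_id = tid[r.chrom]
            rec.reference_start = r.pos
            rec.mapping_quality = 255 if r.nh == 1 else 1
            rec.cigarstring = f"{r.length}M"
            seq = truth.sequences[r.chrom][r.pos:r.pos + r.length]
            rec.query_sequence = _mutate(seq, r.mismatch_offsets, rng)
            rec.query_qualities = pysam.qualitystring_to_array("I" * r.length)
            rec.set_tags([("NM", r.nm, "i"), ("NH", r.nh, "i")])
            out.write(rec)
            n += 1
    return n


def write_sim_fastq(reads: list[SimRead], truth: GroundTruth, path: str | Path,
                    mutation_seed: int = 0) -> int:
    """Write each read (primary records only) as FASTQ."""
    rng = np.random.default_rng(mutation_seed)
    n = 0
    with open(path, "w") as out:
        for r in reads:
            if r.secondary:
                continue
            seq = truth.sequences[r.chrom][r.pos:r.pos + r.length]
            seq = _mutate(seq, r.mismatch_offsets, rng)
            out.write(f"@{r.read_id}\n{seq}\n+\n{'I' * r.length}\n")
            n += 1
    return n


def write_reference(truth: GroundTruth, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for chrom, seq in truth.sequences.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def simulate_experiment(config: SimConfig, out_dir: str | Path,
                        group: str = "sim") -> dict:
    """Full fixture: reference FASTA, exon BED, truth TSV, per-replicate
    SAM and FASTQ. Returns the file manifest and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    ref = out_dir / "reference.fa"
    bed = out_dir / "exons.bed"
    write_reference(truth, ref)
    save_exons(truth.exons, bed)
    truth_tsv = out_dir / "ground_truth.tsv"
    pd.DataFrame({
        "expression": truth.expression,
        "yield_factor": truth.yield_factor(),
    }).rename_axis("exon_id").to_csv(truth_tsv, sep="\t")
    libraries = {}
    for rep in range(config.n_replicates):
        rep_seed = config.seed * 1000 + rep + 1
        reads = simulate_library(truth, config, rep_seed)
        lib_id = f"{group}_rep{rep + 1}"
        sam = out_dir / f"{lib_id}.sam"
        fastq = out_dir / f"{lib_id}.fastq"
        write_sam(reads, truth, sam, mutation_seed=rep_seed)
        write_sim_fastq(reads, truth, fastq, mutation_seed=rep_seed)
        libraries[lib_id] = {"sam": str(sam), "fastq": str(fastq), "group": group}
    return {
        "reference": str(ref),
        "bed": str(bed),
        "ground_truth": str(truth_tsv),
        "libraries": libraries,
        "truth": truth,
    }
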