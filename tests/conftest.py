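"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from maxcounts.annotation import ExonRecord
from maxcounts.sieve import AlignedRead


# ---------------------------------------------------------------------------
# Brute-force per-base pileup oracle: counts every base of every block with
# an explicit double loop. Deliberately naive; never shares code with the
# difference-array implementation it checks.
# ---------------------------------------------------------------------------

def oracle_profile(exon: ExonRecord, alignments) -> np.ndarray:
    depth = np.zeros(exon.length, dtype=int)
    for aln in alignments:
        for bstart, bend in aln.blocks:
            for refpos in range(bstart, bend):
                if exon.start <= refpos < exon.end:
                    depth[refpos - exon.start] += 1
    return depth


def oracle_totcounts(exon: ExonRecord, alignments) -> int:
    n = 0
    for aln in alignments:
        touched = False
        for bstart, bend in aln.blocks:
            for refpos in range(bstart, bend):
                if exon.start <= refpos < exon.end:
                    touched = True
        if touched:
            n += 1
    return n


def random_alignments(rng: np.random.Generator, exon: ExonRecord, n_reads: int,
                      spliced_fraction: float = 0.3) -> list[AlignedRead]:
    """Random single- and spliced-block reads around an exon (some miss it)."""
    out = []
    lo = max(0, exon.start - 80)
    hi = exon.end + 80
    for i in range(n_reads):
        start = int(rng.integers(lo, hi))
        if rng.random() < spliced_fraction:
            len1 = int(rng.integers(5, 40))
            gap = int(rng.integers(1, 200))
            len2 = int(rng.integers(5, 40))
            blocks = ((start, start + len1),
                      (start + len1 + gap, start + len1 + gap + len2))
        else:
            blocks = ((start, start + int(rng.integers(20, 80))),)
        out.append(AlignedRead(read_id=f"r{i}", ref=exon.chrom, pos=start,
                               blocks=blocks))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exon():
    return ExonRecord(chrom="chr1", start=100, end=200, exon_id="e1")
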