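"""FASTQ pre-processing: quality trimming, length filtering, re-mating.

Trimming clips the maximal runs of sub-threshold bases from both read
ends; interior low-quality bases survive. Reads shorter than the length
floor after trimming are discarded. For paired-end input, pairs where
both mates survive are re-mated in order; a lone survivor becomes a
singleton.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ReadRecord",
    "trim_read",
    "passes_length",
    "remate",
    "read_fastq",
    "write_fastq",
    "PrepStats",
]

DEFAULT_QMIN = 20
DEFAULT_MINLEN = 33


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def trim_read(read: ReadRecord, qmin: int = DEFAULT_QMIN) -> ReadRecord:
    """Clip end runs of bases with quality below ``qmin``.

    Removes the maximal run of consecutive sub-threshold bases from the
    5' end and from the 3' end. May return an empty read.
    """
    quals = read.qualities
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < qmin:
        lo += 1
    while hi > lo and quals[hi - 1] < qmin:
        hi -= 1
    if lo == 0 and hi == len(quals):
        return read
    return ReadRecord(read.read_id, read.sequence[lo:hi], quals[lo:hi])


def passes_length(read: ReadRecord, minlen: int = DEFAULT_MINLEN) -> bool:
    """Keep reads of at least ``minlen`` bases (a read of exactly
    ``minlen`` is kept; shorter ones are discarded)."""
    return len(read) >= minlen


@dataclass
class PrepStats:
    reads_in: int = 0
    pairs_out: int = 0
    singletons_out: int = 0
    discarded: int = 0

    def conserved(self) -> bool:
        return self.pairs_out * 2 + self.singletons_out + self.discarded == self.reads_in


def _strip_mate_suffix(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def remate(
    fastq1: str | Path,
    fastq2: str | Path,
    qmin: int = DEFAULT_QMIN,
    minlen: int = DEFAULT_MINLEN,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord], PrepStats]:
    """Trim and length-filter two mate files; restore pair correspondence.

    Returns (pairs, singletons, stats). Mates are matched positionally and
    their ids (after stripping any ``/1``/``/2`` suffix) must agree;
    a mismatch raises, naming the offending id.
    """
    reads1 = list(read_fastq(fastq1))
    reads2 = list(read_fastq(fastq2))
    if len(reads1) != len(reads2):
        raise ValueError(
            f"mate files hold {len(reads1)} vs {len(reads2)} records; "
            "pairing cannot be established"
        )
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    singletons: list[ReadRecord] = []
    stats = PrepStats(reads_in=2 * len(reads1))
    for r1, r2 in zip(reads1, reads2):
        id1, id2 = _strip_mate_suffix(r1.read_id), _strip_mate_suffix(r2.read_id)
        if id1 != id2:
            raise ValueError(f"mate pairing cannot be established for read {r1.read_id!r}")
        t1, t2 = trim_read(r1, qmin), trim_read(r2, qmin)
        ok1, ok2 = passes_length(t1, minlen), passes_length(t2, minlen)
        if ok1 and ok2:
            pairs.append((t1, t2))
            stats.pairs_out += 1
        elif ok1 or ok2:
            singletons.append(t1 if ok1 else t2)
            stats.singletons_out += 1
            stats.discarded += 1
        else:
            stats.discarded += 2
    return pairs, singletons, stats


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Parse 4-line FASTQ records (Sanger Phred+33 by default)."""
    with open(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                break
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header {header.strip()!r}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not plus.startswith("+") or len(qual) != len(seq):
                raise ValueError(f"{path}: truncated FASTQ record {header.strip()!r}")
            yield ReadRecord(
                read_id=header[1:].split()[0],
                sequence=seq,
                qualities=[ord(c) - phred_offset for c in qual],
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path,
                phred_offset: int = 33) -> int:
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + phred_offset) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n
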