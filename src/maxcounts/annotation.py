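"""Exon annotation handling: BED models, reference sequences, GC content.

Exons are the unit of summarization throughout the package. Coordinates
follow the BED convention (0-based, half-open) everywhere internally.
Strand is carried but never used in counting, which is unstranded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from pyfaidx import Fasta

__all__ = [
    "ExonRecord",
    "ExonTable",
    "load_exons",
    "save_exons",
    "compute_gc",
    "annotate_gc",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass
class ExonRecord:
    """A genomic interval with identifier and optional GC fraction.

    ``start``/``end`` are 0-based half-open; ``gc`` is the G+C fraction of
    the exon sequence in [0, 1], or NaN when no sequence is available.
    """

    chrom: str
    start: int
    end: int
    exon_id: str
    strand: str = "."
    gc: float = math.nan

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"exon {self.exon_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"exon {self.exon_id!r}: invalid strand {self.strand!r}")
        if not math.isnan(self.gc) and not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"exon {self.exon_id!r}: gc {self.gc} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


class ExonTable:
    """Ordered collection of :class:`ExonRecord` with id lookup."""

    def __init__(self, exons: Iterable[ExonRecord] = ()) -> None:
        self._exons: list[ExonRecord] = []
        self._by_id: dict[str, ExonRecord] = {}
        for exon in exons:
            self.add(exon)

    def add(self, exon: ExonRecord) -> None:
        if exon.exon_id in self._by_id:
            raise ValueError(f"duplicate exon id {exon.exon_id!r}")
        self._exons.append(exon)
        self._by_id[exon.exon_id] = exon

    def __len__(self) -> int:
        return len(self._exons)

    def __iter__(self) -> Iterator[ExonRecord]:
        return iter(self._exons)

    def __getitem__(self, exon_id: str) -> ExonRecord:
        return self._by_id[exon_id]

    def __contains__(self, exon_id: str) -> bool:
        return exon_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [e.exon_id for e in self._exons]

    def lengths(self) -> dict[str, int]:
        return {e.exon_id: e.length for e in self._exons}

    def gc(self) -> dict[str, float]:
        return {e.exon_id: e.gc for e in self._exons}


def load_exons(bed_path: str | Path) -> ExonTable:
    """Read a BED3+ file into an :class:`ExonTable`.

    The optional 4th column supplies the exon id; without it the id is
    synthesized as ``chrom:start-end``. The 6th column, when present,
    supplies the strand. Coordinates are kept verbatim.
    """
    table = ExonTable()
    with open(bed_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}, line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{bed_path}, line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ValueError(
                    f"{bed_path}, line {lineno}: zero- or negative-length interval "
                    f"[{start}, {end})"
                )
            exon_id = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else (
                f"{chrom}:{start}-{end}"
            )
            strand = fields[5] if len(fields) >= 6 and fields[5] in _VALID_STRANDS else "."
            table.add(ExonRecord(chrom=chrom, start=start, end=end,
                                 exon_id=exon_id, strand=strand))
    return table


def save_exons(table: ExonTable, bed_path: str | Path) -> None:
    """Write a BED6 file; round-trips coordinates bit-exactly."""
    with open(bed_path, "w") as handle:
        for exon in table:
            handle.write(
                f"{exon.chrom}\t{exon.start}\t{exon.end}\t{exon.exon_id}\t0\t{exon.strand}\n"
            )


def compute_gc(sequence: str) -> float:
    """G+C fraction of a nucleotide sequence, case-insensitive.

    N bases are excluded from both numerator and denominator, so a masked
    run does not dilute the covariate. All-N input yields NaN.
    """
    if not sequence:
        raise ValueError("cannot compute GC content of an empty sequence")
    seq = sequence.upper()
    gc = at = 0
    for base in seq:
        if base in "GC":
            gc += 1
        elif base in "AT":
            at += 1
        elif base != "N":
            raise ValueError(f"invalid base {base!r} in sequence")
    denom = gc + at
    if denom == 0:
        return math.nan
    return gc / denom


def annotate_gc(table: ExonTable, fasta_path: str | Path) -> ExonTable:
    """Fill in each exon's ``gc`` field from an indexed FASTA reference."""
    with Fasta(str(fasta_path)) as fasta:
        for exon in table:
            seq = str(fasta[exon.chrom][exon.start:exon.end])
            exon.gc = compute_gc(seq)
    return table
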