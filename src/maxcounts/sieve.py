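"""Alignment post-processing: drop multireads and low-similarity records.

Two filters are applied to a SAM/BAM stream before counting:

* multireads — reads reported at more than one mapping location — are
  removed entirely (every record of the read);
* records whose similarity to the reference, ``(aligned_len - NM) /
  aligned_len``, is below a threshold (default 0.97, strict: a record at
  exactly the threshold is kept).

Multimapping is detected primarily from the ``NH`` tag; files without it
fall back to read-id multiplicity within a mate. Secondary and
supplementary records count as evidence of multimapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

__all__ = [
    "AlignedRead",
    "similarity",
    "filter_alignments",
    "filter_sam",
    "read_sam",
    "SieveStats",
]

DEFAULT_MIN_SIMILARITY = 0.97


@dataclass
class AlignedRead:
    """One alignment record, reduced to what counting and filtering need.

    ``blocks`` are half-open reference intervals covered by aligned bases
    (CIGAR M/=/X); N and D operations open gaps between blocks.
    ``nm`` is the edit distance (None when the file carries no NM tag),
    ``nh`` the number of reported mapping locations, ``mate`` 1 or 2,
    ``secondary`` marks secondary/supplementary records.
    """

    read_id: str
    ref: str
    pos: int
    blocks: tuple[tuple[int, int], ...]
    nm: int | None = 0
    nh: int = 1
    mate: int = 1
    secondary: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id!r}: no aligned blocks")
        prev_end = None
        for start, end in self.blocks:
            if end <= start or (prev_end is not None and start < prev_end):
                raise ValueError(
                    f"read {self.read_id!r}: blocks must be sorted, non-empty, "
                    "non-overlapping"
                )
            prev_end = end
        if self.nh < 1:
            raise ValueError(f"read {self.read_id!r}: nh must be >= 1")

    @property
    def aligned_len(self) -> int:
        return sum(end - start for start, end in self.blocks)

    @classmethod
    def from_pysam(cls, rec: "pysam.AlignedSegment") -> "AlignedRead":
        blocks = tuple((int(s), int(e)) for s, e in rec.get_blocks())
        return cls(
            read_id=rec.query_name,
            ref=rec.reference_name,
            pos=rec.reference_start,
            blocks=blocks,
            nm=rec.get_tag("NM") if rec.has_tag("NM") else None,
            nh=rec.get_tag("NH") if rec.has_tag("NH") else 1,
            mate=2 if rec.is_read2 else 1,
            secondary=rec.is_secondary or rec.is_supplementary,
        )


def similarity(aln: AlignedRead) -> float:
    """Fraction of aligned bases matching the reference.

    Computed as ``(aligned_len - nm) / aligned_len`` clamped to [0, 1];
    the denominator counts aligned read bases only, since soft-clipped
    bases were never compared to the reference.
    """
    if aln.nm is None:
        raise ValueError(
            f"read {aln.read_id!r}: no edit-distance (NM) information; "
            "the similarity filter cannot be applied"
        )
    return min(1.0, max(0.0, (aln.aligned_len - aln.nm) / aln.aligned_len))


@dataclass
class SieveStats:
    records_in: int = 0
    removed_multiread: int = 0
    removed_low_similarity: int = 0
    records_out: int = 0


def _multimapped_ids(alignments: Iterable[AlignedRead]) -> set[str]:
    seen: dict[tuple[str, int], int] = {}
    flagged: set[str] = set()
    for aln in alignments:
        if aln.nh > 1 or aln.secondary:
            flagged.add(aln.read_id)
        key = (aln.read_id, aln.mate)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] > 1:
            flagged.add(aln.read_id)
    return flagged


def filter_alignments(
    alignments: Iterable[AlignedRead],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    drop_multireads: bool = True,
    stats: SieveStats | None = None,
) -> list[AlignedRead]:
    """Apply the multiread and similarity filters to a complete stream.

    The stream must contain every record of each read so multimapping can
    be established. Records with similarity exactly at the threshold are
    kept; only strictly lower ones are removed.
    """
    alignments = list(alignments)
    stats = stats if stats is not None else SieveStats()
    stats.records_in += len(alignments)
    flagged = _multimapped_ids(alignments) if drop_multireads else set()
    kept: list[AlignedRead] = []
    for aln in alignments:
        if aln.read_id in flagged:
            stats.removed_multiread += 1
            continue
        if similarity(aln) < min_similarity:
            stats.removed_low_similarity += 1
            continue
        kept.append(aln)
    stats.records_out += len(kept)
    return kept


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Yield mapped records of a SAM/BAM file as :class:`AlignedRead`."""
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped:
                continue
            yield AlignedRead.from_pysam(rec)


def filter_sam(
    in_path: str | Path,
    out_path: str | Path,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    drop_multireads: bool = True,
) -> SieveStats:
    """File-to-file sieve: two passes so multimapping is established
    without holding the file in memory."""
    stats = SieveStats()
    flagged: set[str] = set()
    if drop_multireads:
        flagged = _multimapped_ids(read_sam(in_path))
    mode = "wb" if str(out_path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(in_path), check_sq=False) as src:
        with pysam.AlignmentFile(str(out_path), mode, template=src) as dst:
            for rec in src:
                if rec.is_unmapped:
                    continue
                stats.records_in += 1
                if rec.query_name in flagged:
                    stats.removed_multiread += 1
                    continue
                if similarity(AlignedRead.from_pysam(rec)) < min_similarity:
                    stats.removed_low_similarity += 1
                    continue
                dst.write(rec)
                stats.records_out += 1
    return stats
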