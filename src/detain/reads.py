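"""Lightweight alignment records and SAM I/O.

Every analysis module consumes :class:`ReadAlignment`: a read reduced to
its reference-aligned blocks (CIGAR M/=/X runs; N gaps separate blocks).
This keeps the statistics independent of the on-disk format; pysam
adapters convert SAM/BAM at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .intervals import Interval


@dataclass
class ReadAlignment:
    read_id: str
    chrom: str
    blocks: list[Interval]
    strand: str = "+"
    quality: Optional[float] = None  # mean basecall quality (long reads)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)

    @property
    def gaps(self) -> list[Interval]:
        """Splice gaps between consecutive aligned blocks."""
        return [
            (a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:]) if b[0] > a[1]
        ]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def span(self) -> Interval:
        return self.blocks[0][0], self.blocks[-1][1]


QUALITY_TAG = "qs"  # SAM float tag carrying mean read quality


def _cigar_from_blocks(blocks: Sequence[Interval]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_sam(
    reads: Iterable[ReadAlignment],
    path: str,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write reads as a coordinate-sortable SAM text file (sequence '*')."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_lengths.items()],
    }
    reads = sorted(reads, key=lambda r: (r.chrom, r.blocks[0][0]))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.blocks[0][0]
            a.cigarstring = _cigar_from_blocks(r.blocks)
            a.mapping_quality = 60
            a.flag = 0 if r.strand == "+" else 16
            if r.quality is not None:
                a.set_tag(QUALITY_TAG, float(r.quality))
            out.write(a)


def read_sam(path: str) -> list[ReadAlignment]:
    """Read primary alignments from SAM/BAM into :class:`ReadAlignment`.

    Secondary and supplementary alignments are skipped; malformed
    (unmapped / block-free) records are counted and dropped.
    """
    import pysam

    out: list[ReadAlignment] = []
    skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            blocks = _merge_abutting(rec.get_blocks())
            if not blocks:
                skipped += 1
                continue
            quality = rec.get_tag(QUALITY_TAG) if rec.has_tag(QUALITY_TAG) else None
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    blocks=blocks,
                    strand="-" if rec.is_reverse else "+",
                    quality=quality,
                )
            )
    if skipped:
        import logging

        logging.getLogger(__name__).warning("%s: skipped %d alignment records", path, skipped)
    return out


def _merge_abutting(blocks: Sequence[Interval]) -> list[Interval]:
    """pysam get_blocks() splits on insertions/deletions too; only true
    reference gaps (N) should separate blocks, so re-join abutting ones."""
    merged: list[Interval] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def group_by_chrom(reads: Iterable[ReadAlignment]) -> dict[str, list[ReadAlignment]]:
    groups: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        groups.setdefault(r.chrom, []).append(r)
    return groups
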