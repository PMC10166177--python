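"""Junction-read counting, the intron retention index (IRI), and DI calls.

Only reads informative about a splice decision are used: exon–intron
junction reads (a contiguous aligned block crossing an exon/intron
boundary with a minimum overhang on each side) count as intronic
evidence, and exon–exon junction reads (a splice gap matching the
intron's boundaries exactly) count as spliced evidence.  Per splice
site,

    IRI_ss = intronic junction reads / (intronic + exon–exon junction reads)

and the intron's IRI is the mean of the 5'SS and 3'SS values.  Restricting
to junction reads sidesteps mappability and intronic-ncRNA artefacts, so
no further coverage correction is applied.

A detained intron (DI) is called when IRI and intron coverage (breadth of
intronic bases hit by >=1 aligned block) clear strict thresholds and both
flanking exons are covered.  Presets: ``rnaseq`` (IRI > 0.1, coverage >
0.9) and ``ripseq`` (coverage > 0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotation import Intron
from .intervals import covered_length, intervals_overlap
from .reads import ReadAlignment

DEFAULT_MIN_OVERHANG = 6  # nt of aligned sequence required on each side of a boundary


@dataclass
class JunctionCounts:
    intron_id: str
    ei5: int = 0
    ei3: int = 0
    ee: int = 0
    flanking_exons_covered: bool = False
    flanking_exon_reads: int = 0

    def __post_init__(self) -> None:
        if min(self.ei5, self.ei3, self.ee, self.flanking_exon_reads) < 0:
            raise ValueError("junction counts must be non-negative")


@dataclass
class IRIRecord:
    intron_id: str
    iri5: float
    iri3: float
    iri: float
    coverage: float
    counts: JunctionCounts
    undefined_side: bool = False

    @property
    def informative(self) -> bool:
        return not self.undefined_side and not math.isnan(self.iri)


def count_junction_reads(
    alignments: Iterable[ReadAlignment],
    intron: Intron,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> JunctionCounts:
    """Classify reads against one intron's two boundaries.

    A read with a splice gap exactly matching ``(intron.start,
    intron.end)`` is an exon–exon read and contributes nothing else.
    Otherwise a contiguous block spanning a boundary with
    ``min_overhang`` aligned nt on each side contributes to that side's
    exon–intron count; a read spanning the whole intron plus both
    boundaries therefore increments both sides.  Reads on other
    chromosomes contribute zero.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    left_b, right_b = intron.start, intron.end
    ei_left = ei_right = ee = 0
    up_cov = down_cov = False
    flank_reads = 0
    for read in alignments:
        if read.chrom != intron.chrom:
            continue
        touches_flank = any(
            intervals_overlap(b, intron.upstream_exon)
            or intervals_overlap(b, intron.downstream_exon)
            for b in read.blocks
        )
        if touches_flank:
            flank_reads += 1
            up_cov = up_cov or any(
                intervals_overlap(b, intron.upstream_exon) for b in read.blocks
            )
            down_cov = down_cov or any(
                intervals_overlap(b, intron.downstream_exon) for b in read.blocks
            )
        if (left_b, right_b) in read.gaps:
            ee += 1
            continue
        for s, e in read.blocks:
            if s <= left_b - min_overhang and e >= left_b + min_overhang:
                ei_left += 1
            if s <= right_b - min_overhang and e >= right_b + min_overhang:
                ei_right += 1
    ei5, ei3 = (ei_left, ei_right) if intron.strand == "+" else (ei_right, ei_left)
    return JunctionCounts(
        intron_id=intron.intron_id,
        ei5=ei5,
        ei3=ei3,
        ee=ee,
        flanking_exons_covered=up_cov and down_cov,
        flanking_exon_reads=flank_reads,
    )


def compute_intron_coverage(
    alignments: Iterable[ReadAlignment], intron: Intron
) -> float:
    """Breadth of intronic bases covered by >=1 aligned block, as a fraction."""
    blocks = [
        b
        for read in alignments
        if read.chrom == intron.chrom
        for b in read.blocks
        if intervals_overlap(b, (intron.start, intron.end))
    ]
    return covered_length(blocks, intron.start, intron.end) / intron.length


def compute_iri(counts: JunctionCounts, coverage: float = 0.0) -> IRIRecord:
    """IRI from junction counts; a side with zero total reads is undefined.

    When only one side is defined the record carries that side's value
    but is flagged ``undefined_side`` and excluded from DI calling.
    """
    d5 = counts.ei5 + counts.ee
    d3 = counts.ei3 + counts.ee
    iri5 = counts.ei5 / d5 if d5 else math.nan
    iri3 = counts.ei3 / d3 if d3 else math.nan
    if d5 and d3:
        iri = (iri5 + iri3) / 2
        undefined = False
    elif d5 or d3:
        iri = iri5 if d5 else iri3
        undefined = True
    else:
        iri = math.nan
        undefined = True
    return IRIRecord(
        intron_id=counts.intron_id,
        iri5=iri5,
        iri3=iri3,
        iri=iri,
        coverage=coverage,
        counts=counts,
        undefined_side=undefined,
    )


#: Named threshold presets; the RIP variant relaxes only the coverage cut.
PRESETS = {
    "rnaseq": dict(iri_min=0.1, cov_min=0.9),
    "ripseq": dict(iri_min=0.1, cov_min=0.8),
}


def call_detained_introns(
    records: Iterable[IRIRecord],
    iri_min: float = 0.1,
    cov_min: float = 0.9,
    exon_reads_min: int = 20,
) -> list[IRIRecord]:
    """DI calls: strict inequalities on IRI, coverage and flanking-exon reads.

    Records with an undefined splice-site side or uncovered flanking
    exons are never called.
    """
    if not (0 <= iri_min <= 1 and 0 <= cov_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if exon_reads_min < 0:
        raise ValueError("exon_reads_min must be >= 0")
    return [
        r
        for r in records
        if r.informative
        and r.counts.flanking_exons_covered
        and r.iri > iri_min
        and r.coverage > cov_min
        and r.counts.flanking_exon_reads > exon_reads_min
    ]


def quantify(
    alignments: Sequence[ReadAlignment],
    introns: Sequence[Intron],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[IRIRecord]:
    """Count junction reads and coverage for many introns at once.

    Reads are selected per intron by binary search on sorted read starts,
    so the scan stays near-linear for non-overlapping genes.
    """
    from bisect import bisect_left

    from .reads import group_by_chrom

    by_chrom = {
        chrom: sorted(reads, key=lambda r: r.span[0])
        for chrom, reads in group_by_chrom(alignments).items()
    }
    starts = {c: [r.span[0] for r in rs] for c, rs in by_chrom.items()}
    max_span = {
        c: max(r.span[1] - r.span[0] for r in rs) for c, rs in by_chrom.items()
    }
    records = []
    for intron in introns:
        reads = by_chrom.get(intron.chrom, [])
        lo = min(intron.upstream_exon[0], intron.downstream_exon[0])
        hi = max(intron.upstream_exon[1], intron.downstream_exon[1])
        if reads:
            i0 = bisect_left(starts[intron.chrom], lo - max_span[intron.chrom])
            i1 = bisect_left(starts[intron.chrom], hi)
            candidates = reads[i0:i1]
        else:
            candidates = []
        local = [r for r in candidates if r.span[1] > lo and r.span[0] < hi]
        counts = count_junction_reads(local, intron, min_overhang)
        coverage = compute_intron_coverage(local, intron)
        records.append(compute_iri(counts, coverage))
    return records


def records_to_frame(records: Sequence[IRIRecord], introns: Optional[Sequence[Intron]] = None):
    """Tabulate IRI records (optionally joined with intron coordinates)."""
    import pandas as pd

    by_id = {i.intron_id: i for i in introns} if introns else {}
    rows = []
    for r in records:
        row = dict(
            intron_id=r.intron_id,
            ei5=r.counts.ei5,
            ei3=r.counts.ei3,
            ee=r.counts.ee,
            iri5=r.iri5,
            iri3=r.iri3,
            iri=r.iri,
            coverage=r.coverage,
            flanking_exons_covered=r.counts.flanking_exons_covered,
            flanking_exon_reads=r.counts.flanking_exon_reads,
            undefined_side=r.undefined_side,
        )
        intron = by_id.get(r.intron_id)
        if intron is not None:
            row.update(
                chrom=intron.chrom, start=intron.start, end=intron.end,
                strand=intron.strand, length=intron.length, is_small=intron.is_small,
            )
        rows.append(row)
    return pd.DataFrame(rows)
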