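"""Full-length transcript calling and intron detention from long reads.

Nanopore-style reads are filtered on mean basecall quality (> 7) and
aligned length (> 500 nt), then a read is *full length* for its gene iff
its aligned blocks overlap both the annotated 5'UTR and 3'UTR.  Each
intron of the gene is then scored per read:

* ``spliced``  — the read has a splice gap matching the intron's
  boundaries (within a configurable tolerance, exact by default);
* ``retained`` — no such gap and >= 90% of intronic bases are covered by
  the read's aligned blocks;
* ``ambiguous`` — anything else (truncated or partially covering reads).

The long-read IRI of an intron is the retained fraction among informative
(retained or spliced) full-length reads — a direct per-molecule
observation rather than the short-read junction formula.  DI thresholds
are IRI > 0.05 with intron coverage > 0.9.  An intron-detaining
transcript (IDT) is a full-length read retaining >= 1 intron.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .annotation import GeneModel, Intron, derive_introns
from .intervals import covered_length, intervals_overlap
from .reads import ReadAlignment

IntronStatus = Literal["retained", "spliced", "ambiguous"]

DEFAULT_Q_MIN = 7.0
DEFAULT_LEN_MIN = 500
RETAINED_COVERAGE_MIN = 0.9  # fraction of intronic bases a retained read must cover


@dataclass
class FullLengthCall:
    read_id: str
    gene_id: str
    is_full_length: bool
    intron_status: dict[str, IntronStatus]
    excluded: Optional[str] = None

    @property
    def n_retained(self) -> int:
        return sum(1 for s in self.intron_status.values() if s == "retained")


@dataclass
class LongReadIRI:
    intron_id: str
    n_retained: int
    n_spliced: int
    n_ambiguous: int
    iri: float
    coverage: float
    is_di: bool
    uninformative: bool


def filter_long_reads(
    reads: Iterable[ReadAlignment],
    q_min: float = DEFAULT_Q_MIN,
    len_min: int = DEFAULT_LEN_MIN,
) -> list[ReadAlignment]:
    """Strict quality/length filter: keep quality > q_min AND length > len_min."""
    return [
        r
        for r in reads
        if r.quality is not None
        and r.quality > q_min
        and r.aligned_length > len_min
    ]


def call_full_length(
    read: ReadAlignment, gene: GeneModel, min_utr_overlap: int = 1
) -> bool:
    """True iff the read overlaps >= min_utr_overlap nt of both UTRs."""
    if not gene.has_utrs:
        raise ValueError(f"{gene.gene_id}: no UTR annotation; cannot call full length")

    def overlap(utrs) -> int:
        return sum(
            max(0, min(b[1], u[1]) - max(b[0], u[0]))
            for b in read.blocks
            for u in utrs
        )

    return overlap(gene.utr5) >= min_utr_overlap and overlap(gene.utr3) >= min_utr_overlap


def per_read_intron_status(
    read: ReadAlignment, intron: Intron, gap_tolerance: int = 0
) -> IntronStatus:
    """Score one intron on one read (see module docstring for the rules)."""
    for gs, ge in read.gaps:
        if abs(gs - intron.start) <= gap_tolerance and abs(ge - intron.end) <= gap_tolerance:
            return "spliced"
    covered = covered_length(
        [b for b in read.blocks if intervals_overlap(b, (intron.start, intron.end))],
        intron.start,
        intron.end,
    )
    if covered / intron.length >= RETAINED_COVERAGE_MIN:
        return "retained"
    return "ambiguous"


def classify_reads(
    reads: Iterable[ReadAlignment],
    gene: GeneModel,
    min_utr_overlap: int = 1,
    gap_tolerance: int = 0,
) -> list[FullLengthCall]:
    """Full-length status and per-intron retention vector for each read."""
    introns = derive_introns(gene)
    calls = []
    for read in reads:
        if read.chrom != gene.chrom:
            continue
        if not gene.has_utrs:
            calls.append(FullLengthCall(read.read_id, gene.gene_id, False, {},
                                        excluded="no_utr_annotation"))
            continue
        full = call_full_length(read, gene, min_utr_overlap)
        status = {
            i.intron_id: per_read_intron_status(read, i, gap_tolerance) for i in introns
        }
        calls.append(FullLengthCall(read.read_id, gene.gene_id, full, status))
    return calls


def long_read_iri(
    full_length_reads: Sequence[ReadAlignment],
    intron: Intron,
    iri_min: float = 0.05,
    cov_min: float = 0.9,
    gap_tolerance: int = 0,
) -> LongReadIRI:
    """Retained-read fraction IRI and DI flag for one intron.

    Ambiguous reads are excluded from the denominator; coverage is the
    breadth of intronic bases covered by retained reads' blocks.
    """
    statuses = [per_read_intron_status(r, intron, gap_tolerance) for r in full_length_reads]
    n = Counter(statuses)
    n_ret, n_spl, n_amb = n["retained"], n["spliced"], n["ambiguous"]
    informative = n_ret + n_spl
    if informative == 0:
        return LongReadIRI(intron.intron_id, 0, 0, n_amb, math.nan, 0.0,
                           is_di=False, uninformative=True)
    iri = n_ret / informative
    retained_blocks = [
        b
        for r, s in zip(full_length_reads, statuses)
        if s == "retained"
        for b in r.blocks
        if intervals_overlap(b, (intron.start, intron.end))
    ]
    coverage = covered_length(retained_blocks, intron.start, intron.end) / intron.length
    return LongReadIRI(
        intron.intron_id, n_ret, n_spl, n_amb, iri, coverage,
        is_di=iri > iri_min and coverage > cov_min, uninformative=False,
    )


def intron_number_distribution(
    calls: Iterable[FullLengthCall],
) -> dict:
    """Distribution of retained-intron counts among IDTs (n_retained >= 1).

    Returns ``{"counts": {k: reads}, "proportions": {k: frac},
    "frac_1_2": cumulative 1-2 intron fraction, "n": total IDTs}``.
    """
    ks = [c.n_retained for c in calls if c.n_retained >= 1]
    counts = Counter(ks)
    total = sum(counts.values())
    proportions = {k: v / total for k, v in sorted(counts.items())} if total else {}
    frac_1_2 = (counts.get(1, 0) + counts.get(2, 0)) / total if total else math.nan
    return {
        "counts": dict(sorted(counts.items())),
        "proportions": proportions,
        "frac_1_2": frac_1_2,
        "n": total,
    }
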