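"""Gene models, intron derivation, and annotation I/O.

Internally every coordinate is 0-based half-open, sorted by genomic
position regardless of strand.  GTF/GFF input (1-based inclusive) is
converted at the boundary.  Introns carry strand-aware splice-site
positions: the 5' splice site (donor) of a '-'-strand intron is its
*higher* genomic coordinate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import Interval, intervals_overlap, merge_intervals

logger = logging.getLogger(__name__)

SMALL_INTRON_MAX_LENGTH = 150  # introns shorter than this form the "small" class


@dataclass
class GeneModel:
    """A gene's exon/intron/UTR structure.

    ``exons`` is the merged exonic union across transcripts (sorted,
    non-overlapping).  ``transcripts`` maps transcript id to that
    transcript's own exon chain and is what intron derivation walks;
    single-transcript constructions may omit it, in which case ``exons``
    is treated as the sole transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: Optional[list[Interval]] = None
    utr5: Optional[list[Interval]] = None
    utr3: Optional[list[Interval]] = None
    transcripts: Optional[dict[str, list[Interval]]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} and {(s2, e2)}")
        for name, ivs in (("cds", self.cds), ("utr5", self.utr5), ("utr3", self.utr3)):
            if not ivs:
                continue
            for iv in ivs:
                if not any(x[0] <= iv[0] and iv[1] <= x[1] for x in self.exons):
                    raise ValueError(f"{self.gene_id}: {name} interval {iv} not contained in an exon")

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    def transcript_exons(self) -> dict[str, list[Interval]]:
        if self.transcripts:
            return self.transcripts
        return {self.gene_id: self.exons}

    @property
    def has_utrs(self) -> bool:
        return bool(self.utr5) and bool(self.utr3)


@dataclass
class Intron:
    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    upstream_exon: Interval
    downstream_exon: Interval

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.intron_id}: empty intron ({self.start}, {self.end})")
        # flanking exons must abut the intron exactly
        left = self.upstream_exon if self.strand == "+" else self.downstream_exon
        right = self.downstream_exon if self.strand == "+" else self.upstream_exon
        if left[1] != self.start or right[0] != self.end:
            raise ValueError(f"{self.intron_id}: flanking exons do not abut intron boundaries")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_small(self) -> bool:
        return self.length < SMALL_INTRON_MAX_LENGTH

    @property
    def five_prime_ss(self) -> int:
        """Donor position: genomic ``start`` on '+', ``end`` on '-'."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime_ss(self) -> int:
        """Acceptor position: genomic ``end`` on '+', ``start`` on '-'."""
        return self.end if self.strand == "+" else self.start


def derive_introns(gene: GeneModel) -> list[Intron]:
    """All distinct introns of a gene, with exact flanking exons.

    Introns are derived per transcript and de-duplicated by coordinate;
    flanking exons come from the transcript that defined the intron.
    A single-exon gene yields an empty list.
    """
    seen: dict[tuple[int, int], Intron] = {}
    for tx_exons in gene.transcript_exons().values():
        exons = sorted(tx_exons)
        for left, right in zip(exons, exons[1:]):
            start, end = left[1], right[0]
            if (start, end) in seen:
                continue
            up, down = (left, right) if gene.strand == "+" else (right, left)
            intron = Intron(
                intron_id=f"{gene.gene_id}:{gene.chrom}:{start}-{end}",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                start=start,
                end=end,
                upstream_exon=up,
                downstream_exon=down,
            )
            seen[(start, end)] = intron
    return [seen[k] for k in sorted(seen)]


def _gff_intervals(features) -> list[Interval]:
    return sorted((f.start - 1, f.end) for f in features)


def read_annotation(path: str) -> list[GeneModel]:
    """Parse a GTF/GFF3 file into :class:`GeneModel` records.

    Uses an in-memory gffutils database.  Multi-transcript genes keep a
    per-transcript exon chain (for intron derivation) and a merged exon
    union.  UTRs come from ``five_prime_utr``/``three_prime_utr``
    features when present, else are computed from the CDS extent.
    """
    import gffutils

    with open(path) as fh:
        if not fh.read().strip():
            warnings.warn(f"{path}: empty annotation file")
            return []
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ValueError(f"{gene.id}: unknown strand {gene.strand!r}")
        transcripts: dict[str, list[Interval]] = {}
        for tx in db.children(gene, level=1):
            exons = _gff_intervals(db.children(tx, featuretype="exon"))
            if not exons:
                continue
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{tx.id}: overlapping exons {(s1, e1)} and {(s2, e2)}"
                    )
            transcripts[tx.id] = exons
        if not transcripts:
            logger.warning("gene %s has no exons; skipped", gene.id)
            continue
        cds = _gff_intervals(db.children(gene, featuretype="CDS"))
        utr5 = _gff_intervals(db.children(gene, featuretype="five_prime_utr"))
        utr3 = _gff_intervals(db.children(gene, featuretype="three_prime_utr"))
        merged_exons = merge_intervals(iv for ivs in transcripts.values() for iv in ivs)
        if cds and not (utr5 or utr3):
            utr5, utr3 = _utrs_from_cds(merged_exons, cds, gene.strand)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=merged_exons,
                cds=sorted(cds) or None,
                utr5=utr5 or None,
                utr3=utr3 or None,
                transcripts=transcripts,
            )
        )
    return genes


def _utrs_from_cds(
    exons: Sequence[Interval], cds: Sequence[Interval], strand: str
) -> tuple[list[Interval], list[Interval]]:
    """Exonic regions outside the CDS span, split into 5'/3' by strand."""
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    left: list[Interval] = []
    right: list[Interval] = []
    for s, e in exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    return (left, right) if strand == "+" else (right, left)


def write_introns_bed(introns: Iterable[Intron], path: str) -> None:
    """BED6: name=intron_id, score=length, strand respected."""
    with open(path, "w") as fh:
        for i in introns:
            fh.write(f"{i.chrom}\t{i.start}\t{i.end}\t{i.intron_id}\t{i.length}\t{i.strand}\n")


def read_introns_bed(path: str, genes: Mapping[str, GeneModel] | None = None) -> list[dict]:
    """Read a BED6 intron file back as plain records (coordinates round-trip)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                dict(chrom=chrom, start=int(start), end=int(end), intron_id=name,
                     length=int(score), strand=strand)
            )
    return out


def read_fasta(path: str) -> dict[str, str]:
    """Load a (small) FASTA into a chrom -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
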