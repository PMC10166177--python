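"""Synthetic annotations, reads and CLIP libraries with known truth.

The simulators emit the statistical structure the estimators assume, so
every stage of the pipeline is testable without external data:

* genes with exons, introns (including a <150 nt "small" stratum),
  in-frame CDS and both UTRs, plus a random genome sequence with GT..AG
  intron ends and a stop-free CDS;
* short-read junction evidence at each splice site: at depth *d* per
  site, exon-intron reads ~ Binomial(d, theta) independently per site
  and a shared exon-exon pool ~ Binomial(d, 1 - theta), matching the
  fact that one spliced junction read is the same molecule at both
  boundaries; retained introns additionally get tiling body reads so
  intron coverage saturates when theta > 0;
* full-length long reads with independent Bernoulli(theta) retention per
  intron and a configurable truncated-read fraction;
* CLIP libraries with uniform background plus point enrichment at
  configured splice-site offsets for configured intron groups.

All randomness flows from one master seed through per-stage child
streams, so adding a stage never perturbs earlier ones and identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import GeneModel, Intron, derive_introns
from .reads import ReadAlignment

_STAGE = {"annotation": 0, "short": 1, "long": 2, "clip": 3}

# codons that never terminate translation, for stop-free CDS interiors
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cerebellum-like dataset.

    Defaults give compact protein-coding genes whose exon/intron
    geometry supports every downstream filter: exons long enough for
    junction overhangs and metagene windows, a small-intron stratum
    below 150 nt, long-read lengths above the 500 nt filter, and
    junction depth matching a well-covered bulk library.
    """

    seed: int = 0
    n_genes: int = 10
    exons_per_gene: int = 4
    exon_len: int = 260
    utr_len: int = 120
    intron_len_range: tuple[int, int] = (300, 800)
    small_intron_frac: float = 0.3
    small_len_range: tuple[int, int] = (60, 149)
    intergenic_len: int = 400
    chrom: str = "chrS"
    theta: float = 0.1
    junction_depth: int = 200
    read_len: int = 50
    overhang: int = 10
    long_read_n: int = 1000
    full_length_frac: float = 0.8
    long_read_quality: float = 12.0

    def __post_init__(self) -> None:
        if not 0 <= self.theta <= 1:
            raise ValueError("theta must lie in [0, 1]")
        if self.junction_depth < 0 or self.long_read_n < 0:
            raise ValueError("depths must be >= 0")
        if self.exon_len < 2 * self.overhang:
            raise ValueError("exon shorter than twice the junction overhang")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STAGE))[_STAGE[stage]]
        )


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Generate gene models and a matching genome sequence.

    Genes alternate strand along one chromosome.  The CDS spans all
    exons minus the UTR ends, its length is a multiple of three, starts
    ATG, ends with a single stop, and is stop-free inside; introns get
    canonical GT..AG ends (transcript orientation).
    """
    rng = config.rng("annotation")
    genes: list[GeneModel] = []
    seq_parts: list[str] = []
    cursor = 0

    def random_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    for gi in range(config.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"gene{gi:03d}"
        seq_parts.append(random_seq(config.intergenic_len))
        cursor += config.intergenic_len
        exons: list[tuple[int, int]] = []
        gene_seq_parts: list[str] = []
        pos = cursor
        for ei in range(config.exons_per_gene):
            exons.append((pos, pos + config.exon_len))
            gene_seq_parts.append(random_seq(config.exon_len))
            pos += config.exon_len
            if ei < config.exons_per_gene - 1:
                if rng.random() < config.small_intron_frac:
                    ilen = int(rng.integers(*config.small_len_range))
                else:
                    ilen = int(rng.integers(*config.intron_len_range))
                iseq = random_seq(ilen)
                # canonical splice ends in transcript orientation
                if strand == "+":
                    iseq = "GT" + iseq[2:-2] + "AG"
                else:
                    iseq = "CT" + iseq[2:-2] + "AC"
                gene_seq_parts.append(iseq)
                pos += ilen
        gene_seq = "".join(gene_seq_parts)
        gene_start = cursor
        cursor = pos
        seq_parts.append(gene_seq)

        # UTRs sit at the transcript ends: genomic left end of the first
        # exon is the 5'UTR on '+', the 3'UTR on '-'
        first, last = exons[0], exons[-1]
        left_utr = [(first[0], first[0] + config.utr_len)]
        right_utr = [(last[1] - config.utr_len, last[1])]
        utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
        cds = _cds_intervals(exons, config.utr_len)
        gene_seq = _write_cds(gene_seq, gene_start, cds, strand, rng)
        seq_parts[-1] = gene_seq

        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=config.chrom,
                strand=strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                transcripts={f"{gene_id}.t1": exons},
            )
        )
    seq_parts.append(random_seq(config.intergenic_len))
    genome = {config.chrom: "".join(seq_parts)}
    return genes, genome


def _cds_intervals(
    exons: Sequence[tuple[int, int]], utr_len: int
) -> list[tuple[int, int]]:
    cds = [list(iv) for iv in exons]
    cds[0][0] += utr_len
    cds[-1][1] -= utr_len
    total = sum(e - s for s, e in cds)
    cds[-1][1] -= total % 3  # keep CDS length a multiple of three
    return [tuple(iv) for iv in cds]


def _write_cds(
    gene_seq: str,
    gene_start: int,
    cds: Sequence[tuple[int, int]],
    strand: str,
    rng: np.random.Generator,
) -> str:
    """Overwrite exonic CDS positions with an ATG..stop, stop-free frame."""
    from Bio.Seq import Seq

    n_codons = sum(e - s for s, e in cds) // 3
    codons = ["ATG"] + list(rng.choice(_NONSTOP_CODONS, size=n_codons - 2)) + ["TAA"]
    cds_seq = "".join(codons)
    if strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
    out = list(gene_seq)
    i = 0
    for s, e in sorted(cds):
        out[s - gene_start : e - gene_start] = cds_seq[i : i + (e - s)]
        i += e - s
    return "".join(out)


def write_gtf(genes: Sequence[GeneModel], path: str, source: str = "detain-sim") -> None:
    """GTF (1-based inclusive) with gene/transcript/exon/CDS/UTR features."""

    def line(chrom, feature, start, end, strand, attrs):
        attr = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr}\n"

    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            fh.write(line(g.chrom, "gene", span[0], span[1], g.strand, [("gene_id", g.gene_id)]))
            for tx_id, exons in g.transcript_exons().items():
                base = [("gene_id", g.gene_id), ("transcript_id", tx_id)]
                fh.write(line(g.chrom, "transcript", exons[0][0], exons[-1][1], g.strand, base))
                for s, e in exons:
                    fh.write(line(g.chrom, "exon", s, e, g.strand, base))
                for s, e in g.cds or []:
                    fh.write(line(g.chrom, "CDS", s, e, g.strand, base))
                for s, e in g.utr5 or []:
                    fh.write(line(g.chrom, "five_prime_utr", s, e, g.strand, base))
                for s, e in g.utr3 or []:
                    fh.write(line(g.chrom, "three_prime_utr", s, e, g.strand, base))


def simulate_junction_counts(
    theta, depth: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized junction-count draws (ei5, ei3, ee) per intron.

    At per-site depth *d*, each exon-intron count is Binomial(d, theta)
    and the shared exon-exon pool is Binomial(d, 1 - theta).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    ei5 = rng.binomial(depth, theta)
    ei3 = rng.binomial(depth, theta)
    ee = rng.binomial(depth, 1 - theta)
    return ei5, ei3, ee


def simulate_intron_site_reads(
    intron: Intron,
    theta: float,
    depth: int,
    rng: np.random.Generator,
    read_len: int = 50,
) -> list[ReadAlignment]:
    """Alignment records realizing the junction-count model for one intron.

    Emits exon-intron reads centred on each boundary, shared exact
    exon-exon junction reads, and (when theta > 0) body reads tiling the
    intron so breadth coverage saturates.
    """
    half = read_len // 2
    ei_l, ei_r, ee = (
        int(v[0]) for v in simulate_junction_counts(theta, depth, rng)
    )
    reads: list[ReadAlignment] = []
    rid = 0

    def new_id() -> str:
        nonlocal rid
        rid += 1
        return f"{intron.intron_id}:r{rid}"

    left, right = intron.start, intron.end
    for _ in range(ei_l):
        reads.append(ReadAlignment(new_id(), intron.chrom, [(left - half, left + half)]))
    for _ in range(ei_r):
        reads.append(ReadAlignment(new_id(), intron.chrom, [(right - half, right + half)]))
    for _ in range(ee):
        reads.append(
            ReadAlignment(new_id(), intron.chrom, [(left - half, left), (right, right + half)])
        )
    if theta > 0:
        for s in range(left, right, read_len):
            reads.append(ReadAlignment(new_id(), intron.chrom, [(s, min(s + read_len, right))]))
    return reads


def simulate_short_reads(
    genes: Sequence[GeneModel],
    theta: float | Mapping[str, float],
    junction_depth: int,
    rng: np.random.Generator,
    read_len: int = 50,
) -> list[ReadAlignment]:
    """Short-read junction evidence for every intron of every gene."""
    reads: list[ReadAlignment] = []
    for gene in genes:
        for intron in derive_introns(gene):
            th = theta[intron.intron_id] if isinstance(theta, Mapping) else theta
            reads.extend(
                simulate_intron_site_reads(intron, th, junction_depth, rng, read_len)
            )
    return reads


def simulate_long_reads(
    genes: Sequence[GeneModel],
    theta: float | Mapping[str, float],
    long_read_n: int,
    full_length_frac: float,
    rng: np.random.Generator,
    quality: float = 12.0,
) -> list[ReadAlignment]:
    """Full-length-or-truncated long reads with Bernoulli intron retention.

    A full-length read spans the whole transcript including both UTRs;
    truncated reads lose one transcript end (alternating which) and so
    fail the UTR-containment filter.  Retained introns appear as
    contiguous alignment through the intron, spliced ones as exact
    splice gaps.  Genes without UTRs are skipped.
    """
    eligible = [g for g in genes if g.has_utrs]
    if not eligible:
        return []
    reads: list[ReadAlignment] = []
    for ri in range(long_read_n):
        gene = eligible[int(rng.integers(len(eligible)))]
        introns = derive_introns(gene)
        keep = {
            i.intron_id: bool(
                rng.random()
                < (theta[i.intron_id] if isinstance(theta, Mapping) else theta)
            )
            for i in introns
        }
        blocks = _transcript_blocks(gene, keep)
        full = rng.random() < full_length_frac
        if not full:
            # drop the terminal exon block at one transcript end
            drop_left = (ri % 2 == 0) if gene.strand == "+" else (ri % 2 == 1)
            blocks = blocks[1:] if drop_left else blocks[:-1]
            if not blocks:
                continue
        reads.append(
            ReadAlignment(
                read_id=f"lr{ri:06d}",
                chrom=gene.chrom,
                blocks=blocks,
                strand=gene.strand,
                quality=quality,
            )
        )
    return reads


def _transcript_blocks(
    gene: GeneModel, retained: Mapping[str, bool]
) -> list[tuple[int, int]]:
    """Aligned blocks of a molecule: exons plus retained introns merged."""
    introns = {(i.start, i.end): retained[i.intron_id] for i in derive_introns(gene)}
    blocks: list[tuple[int, int]] = []
    exons = sorted(gene.exons)
    for i, exon in enumerate(exons):
        if blocks and blocks[-1][1] == exon[0]:
            blocks[-1] = (blocks[-1][0], exon[1])
        else:
            blocks.append(exon)
        if i < len(exons) - 1:
            key = (exon[1], exons[i + 1][0])
            if introns.get(key, False):
                blocks[-1] = (blocks[-1][0], exons[i + 1][0])
    return blocks


def simulate_clip_reads(
    genes: Sequence[GeneModel],
    enriched: Mapping[str, Sequence[tuple[str, int]]],
    rng: np.random.Generator,
    n_background: int = 20000,
    reads_per_site: int = 50,
    background_len: int = 30,
    footprint: int = 1,
) -> list[ReadAlignment]:
    """CLIP library: uniform background plus point enrichment.

    ``enriched`` maps intron_id -> list of (anchor, offset) pairs in the
    metagene offset convention; each gets ``reads_per_site`` stacked
    reads of ``footprint`` nt centred on the target base.  Background
    reads of ``background_len`` nt are placed uniformly over gene spans.
    """
    from .clip import _offset_positions

    introns = {i.intron_id: i for g in genes for i in derive_introns(g)}
    reads: list[ReadAlignment] = []
    rid = 0
    spans = [(g.chrom, *g.span) for g in genes]
    total = sum(e - s for _, s, e in spans)
    for chrom, s, e in spans:
        n = int(round(n_background * (e - s) / total))
        starts = rng.integers(s, max(s + 1, e - background_len), size=n)
        for st in np.sort(starts):
            reads.append(
                ReadAlignment(f"bg{rid:07d}", chrom, [(int(st), int(st) + background_len)])
            )
            rid += 1
    for intron_id, sites in enriched.items():
        intron = introns[intron_id]
        for anchor, offset in sites:
            pos = int(_offset_positions(intron, anchor, np.array([offset]))[0])
            half = footprint // 2
            for _ in range(reads_per_site):
                reads.append(
                    ReadAlignment(
                        f"en{rid:07d}", intron.chrom,
                        [(pos - half, pos - half + footprint)],
                        strand=intron.strand,
                    )
                )
                rid += 1
    return reads


def truth_table(genes: Sequence[GeneModel], theta: float | Mapping[str, float]):
    """Per-intron ground-truth retention fractions as a DataFrame."""
    import pandas as pd

    rows = []
    for g in genes:
        for i in derive_introns(g):
            th = theta[i.intron_id] if isinstance(theta, Mapping) else theta
            rows.append(
                dict(intron_id=i.intron_id, gene_id=g.gene_id, chrom=i.chrom,
                     start=i.start, end=i.end, strand=i.strand, length=i.length,
                     is_small=i.is_small, theta=th)
            )
    return pd.DataFrame(rows)
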