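"""Customized DI peptide database construction.

For every detained intron in a protein-coding gene the spliced mRNA is
translated *in silico* from 60 nt upstream of the intron (in CDS
coordinates, crossing exon-exon junctions as needed) through the
retained intron until the first in-frame stop codon (the premature
termination codon, PTC).  If the intron itself is stop-free, translation
continues into the downstream exonic CDS until a stop or the transcript
end.  The reading frame is derived from the annotated CDS phase at the
upstream position.  Tryptic peptides (cleavage C-terminal to K/R, not
before P, up to a configurable number of missed cleavages) are then
enumerated for a search-engine-ready FASTA.

DIs in UTRs or non-coding genes are skipped with a reason code rather
than six-frame translated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .annotation import GeneModel, Intron

Source = Literal["upstream_exon", "intron"]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PeptideEntry:
    entry_id: str
    gene_id: str
    intron_id: str
    source: Source
    aa_sequence: str
    frame_offset: int  # bases trimmed from the upstream window to reach a codon boundary
    stop_found: bool
    truncated_upstream: bool = False

    def __post_init__(self) -> None:
        if "*" in self.aa_sequence:
            raise ValueError("aa_sequence must not contain a stop symbol")


@dataclass
class SkippedDI:
    intron_id: str
    reason: str


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else str(Seq(seq).reverse_complement())


def translate_di_region(
    gene: GeneModel,
    intron: Intron,
    genome: Mapping[str, str],
    upstream_nt: int = 60,
) -> PeptideEntry | SkippedDI:
    """Translate one DI with its upstream exonic context until the PTC.

    Returns a :class:`SkippedDI` for non-coding genes or introns outside
    the CDS.  The upstream window is truncated (and flagged) when fewer
    than ``upstream_nt`` CDS bases precede the intron.
    """
    if not gene.cds:
        return SkippedDI(intron.intron_id, "noncoding_gene")
    chrom_seq = genome[gene.chrom]
    cds = sorted(gene.cds)
    # transcript order: genomic order on '+', reversed on '-'
    ordered = cds if gene.strand == "+" else list(reversed(cds))

    if gene.strand == "+":
        upstream_ivs = [iv for iv in ordered if iv[1] <= intron.start]
        downstream_ivs = [iv for iv in ordered if iv[0] >= intron.end]
    else:
        upstream_ivs = [iv for iv in ordered if iv[0] >= intron.end]
        downstream_ivs = [iv for iv in ordered if iv[1] <= intron.start]
    if not upstream_ivs:
        return SkippedDI(intron.intron_id, "intron_outside_cds")
    # the intron must abut the CDS region it interrupts
    boundary_iv = upstream_ivs[-1]
    boundary = boundary_iv[1] if gene.strand == "+" else boundary_iv[0]
    if boundary != (intron.start if gene.strand == "+" else intron.end):
        return SkippedDI(intron.intron_id, "intron_not_flanked_by_cds")

    upstream_seq = "".join(
        _oriented(chrom_seq[s:e], gene.strand) for s, e in upstream_ivs
    )
    n_up = len(upstream_seq)
    window = min(upstream_nt, n_up)
    truncated = window < upstream_nt
    start_in_cds = n_up - window
    frame_offset = (3 - start_in_cds % 3) % 3  # trim to the next codon boundary
    upstream_window = upstream_seq[start_in_cds + frame_offset :]

    intron_seq = _oriented(chrom_seq[intron.start : intron.end], gene.strand)
    downstream_seq = "".join(
        _oriented(chrom_seq[s:e], gene.strand) for s, e in downstream_ivs
    )
    mrna = upstream_window + intron_seq + downstream_seq
    mrna = mrna[: len(mrna) - len(mrna) % 3]
    aa = str(Seq(mrna).translate())
    stop_idx = aa.find("*")
    stop_found = stop_idx != -1
    peptide = aa[:stop_idx] if stop_found else aa
    # a peptide reaches the intron iff its nt extent passes the window end
    source: Source = (
        "intron" if 3 * len(peptide) > len(upstream_window) else "upstream_exon"
    )
    return PeptideEntry(
        entry_id=f"{gene.gene_id}|{intron.intron_id}|{source}|{frame_offset}",
        gene_id=gene.gene_id,
        intron_id=intron.intron_id,
        source=source,
        aa_sequence=peptide,
        frame_offset=frame_offset,
        stop_found=stop_found,
        truncated_upstream=truncated,
    )


def tryptic_digest(
    aa_sequence: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> list[str]:
    """In-silico tryptic peptides, ordered by position then length.

    Cleaves C-terminal to K/R except before P; emits every fragment with
    0..``max_missed`` internal missed cleavages whose length lies in
    ``[min_len, max_len]``.
    """
    seq = aa_sequence.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    sites = [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    boundaries = [0] + sites + [len(seq)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            frag = seq[boundaries[i] : boundaries[j]]
            if min_len <= len(frag) <= max_len:
                peptides.append(frag)
    return peptides


def build_entries(
    genes: Sequence[GeneModel],
    di_introns: Sequence[Intron],
    genome: Mapping[str, str],
    upstream_nt: int = 60,
) -> tuple[list[PeptideEntry], list[SkippedDI]]:
    """Translate every DI of every gene; split results into kept/skipped."""
    by_gene = {g.gene_id: g for g in genes}
    entries: list[PeptideEntry] = []
    skipped: list[SkippedDI] = []
    for intron in di_introns:
        gene = by_gene.get(intron.gene_id)
        if gene is None:
            skipped.append(SkippedDI(intron.intron_id, "unknown_gene"))
            continue
        result = translate_di_region(gene, intron, genome, upstream_nt)
        if isinstance(result, SkippedDI):
            skipped.append(result)
        else:
            entries.append(result)
    return entries, skipped


def write_peptide_fasta(entries: Iterable[PeptideEntry], path: str) -> None:
    """Deterministic FASTA (`>gene|intron|source|frame`), byte-stable
    across runs given identical inputs; duplicate entry ids are rejected."""
    entries = list(entries)
    seen: set[str] = set()
    for e in entries:
        if e.entry_id in seen:
            raise ValueError(f"duplicate entry_id: {e.entry_id}")
        seen.add(e.entry_id)
    if not entries:
        import warnings

        warnings.warn(f"{path}: writing empty peptide database")
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.entry_id}\n{e.aa_sequence}\n")
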