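import numpy as np
import pytest

from detain.annotation import GeneModel, Intron, derive_introns
from detain.reads import ReadAlignment
from detain.simulate import SimulationConfig, simulate_annotation


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic annotation + genome shared across tests."""
    cfg = SimulationConfig(seed=11, n_genes=6)
    genes, genome = simulate_annotation(cfg)
    return cfg, genes, genome


@pytest.fixture
def toy_intron():
    """One '+'-strand intron (1000, 1500) with 300 nt flanking exons."""
    return Intron(
        intron_id="toy:chr1:1000-1500",
        gene_id="toy",
        chrom="chr1",
        strand="+",
        start=1000,
        end=1500,
        upstream_exon=(700, 1000),
        downstream_exon=(1500, 1800),
    )


@pytest.fixture
def toy_coding_gene():
    """Hand-built coding gene whose intron carries an in-frame PTC.

    chrom 't': exon1 = CDS 'ATGGAA' at [0,6), intron 'TGGTAAGG' at
    [6,14), exon2 = CDS 'GGCTAA' at [14,20).  Translating from 6 nt
    upstream of the intron gives peptide 'MEW' (stop inside the intron).
    """
    seq = "ATGGAA" + "TGGTAAGG" + "GGCTAA"
    gene = GeneModel(
        gene_id="toy",
        chrom="t",
        strand="+",
        exons=[(0, 6), (14, 20)],
        cds=[(0, 6), (14, 20)],
    )
    return gene, {"t": seq}


def ei_read(intron, boundary, rid="r", overhang=10):
    """A contiguous read spanning one intron boundary."""
    pos = intron.start if boundary == "left" else intron.end
    return ReadAlignment(rid, intron.chrom, [(pos - overhang, pos + overhang)])


def ee_read(intron, rid="r", overhang=10):
    """An exact exon-exon junction read for the intron."""
    return ReadAlignment(
        rid,
        intron.chrom,
        [(intron.start - overhang, intron.start), (intron.end, intron.end + overhang)],
    )
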