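"""Junction counting, IRI arithmetic, intron coverage and DI calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detain.annotation import Intron
from detain.junctions import (
    IRIRecord,
    JunctionCounts,
    PRESETS,
    call_detained_introns,
    compute_intron_coverage,
    compute_iri,
    count_junction_reads,
    quantify,
)
from detain.reads import ReadAlignment

from conftest import ee_read, ei_read


def brute_force_counts(reads, intron, min_overhang):
    """Independent per-read, per-base boundary scan (test oracle)."""
    ei_left = ei_right = ee = 0
    for read in reads:
        if read.chrom != intron.chrom:
            continue
        gaps = [
            (a[1], b[0]) for a, b in zip(read.blocks, read.blocks[1:]) if b[0] > a[1]
        ]
        if any(g == (intron.start, intron.end) for g in gaps):
            ee += 1
            continue
        for boundary, bump in ((intron.start, "left"), (intron.end, "right")):
            wanted = set(range(boundary - min_overhang, boundary + min_overhang))
            for s, e in read.blocks:
                if wanted <= set(range(s, e)):
                    if bump == "left":
                        ei_left += 1
                    else:
                        ei_right += 1
                    break
    if intron.strand == "+":
        return ei_left, ei_right, ee
    return ei_right, ei_left, ee


class TestCountJunctionReads:
    def test_hand_constructed_fixture(self, toy_intron):
        reads = [ei_read(toy_intron, "left", f"a{i}") for i in range(3)]
        reads += [ee_read(toy_intron, f"b{i}") for i in range(2)]
        c = count_junction_reads(reads, toy_intron, min_overhang=6)
        assert (c.ei5, c.ei3, c.ee) == (3, 0, 2)

    def test_offset_gap_is_not_exon_exon(self, toy_intron):
        shifted = ReadAlignment(
            "r", toy_intron.chrom,
            [(toy_intron.start - 9, toy_intron.start + 1),
             (toy_intron.end + 1, toy_intron.end + 11)],
        )
        c = count_junction_reads([shifted], toy_intron)
        assert c.ee == 0

    def test_no_reads(self, toy_intron):
        c = count_junction_reads([], toy_intron)
        assert (c.ei5, c.ei3, c.ee) == (0, 0, 0)
        assert not c.flanking_exons_covered

    def test_other_chromosome_contributes_zero(self, toy_intron):
        read = ReadAlignment("r", "chrX", [(toy_intron.start - 10, toy_intron.start + 10)])
        c = count_junction_reads([read], toy_intron)
        assert (c.ei5, c.ei3, c.ee, c.flanking_exon_reads) == (0, 0, 0, 0)

    def test_insufficient_overhang_not_counted(self, toy_intron):
        read = ReadAlignment(
            "r", toy_intron.chrom, [(toy_intron.start - 3, toy_intron.start + 30)]
        )
        assert count_junction_reads([read], toy_intron, min_overhang=6).ei5 == 0
        assert count_junction_reads([read], toy_intron, min_overhang=3).ei5 == 1

    def test_intron_spanning_read_counts_both_sides(self, toy_intron):
        read = ReadAlignment(
            "r", toy_intron.chrom, [(toy_intron.start - 20, toy_intron.end + 20)]
        )
        c = count_junction_reads([read], toy_intron)
        assert (c.ei5, c.ei3, c.ee) == (1, 1, 0)

    def test_minus_strand_swaps_site_labels(self, toy_intron):
        minus = Intron(
            intron_id="m", gene_id="g", chrom=toy_intron.chrom, strand="-",
            start=toy_intron.start, end=toy_intron.end,
            upstream_exon=toy_intron.downstream_exon,
            downstream_exon=toy_intron.upstream_exon,
        )
        reads = [ei_read(toy_intron, "left", f"r{i}") for i in range(3)]
        plus_c = count_junction_reads(reads, toy_intron)
        minus_c = count_junction_reads(reads, minus)
        assert (plus_c.ei5, plus_c.ei3) == (3, 0)
        assert (minus_c.ei5, minus_c.ei3) == (0, 3)

    def test_flanking_exon_coverage_requires_both_exons(self, toy_intron):
        left_only = ei_read(toy_intron, "left")
        c = count_junction_reads([left_only], toy_intron)
        assert not c.flanking_exons_covered
        c = count_junction_reads([left_only, ei_read(toy_intron, "right")], toy_intron)
        assert c.flanking_exons_covered

    def test_rejects_nonpositive_overhang(self, toy_intron):
        with pytest.raises(ValueError):
            count_junction_reads([], toy_intron, min_overhang=0)

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_matches_brute_force_on_random_micro_fixtures(self, data):
        """Optimized counting equals the per-base brute-force scan."""
        strand = data.draw(st.sampled_from(["+", "-"]))
        n_introns = data.draw(st.integers(1, 3))
        introns = []
        pos = 100
        for k in range(n_introns):
            ilen = data.draw(st.integers(20, 120))
            up, down = (pos - 50, pos), (pos + ilen, pos + ilen + 50)
            introns.append(
                Intron(
                    intron_id=f"i{k}", gene_id="g", chrom="c", strand=strand,
                    start=pos, end=pos + ilen,
                    upstream_exon=up if strand == "+" else down,
                    downstream_exon=down if strand == "+" else up,
                )
            )
            pos += ilen + 100
        reads = []
        for r in range(data.draw(st.integers(0, 50))):
            start = data.draw(st.integers(0, pos))
            if data.draw(st.booleans()):
                blocks = [(start, start + data.draw(st.integers(1, 80)))]
            else:
                l1 = data.draw(st.integers(1, 40))
                gap = data.draw(st.integers(1, 150))
                l2 = data.draw(st.integers(1, 40))
                blocks = [(start, start + l1), (start + l1 + gap, start + l1 + gap + l2)]
            reads.append(ReadAlignment(f"r{r}", "c", blocks))
        for intron in introns:
            got = count_junction_reads(reads, intron, min_overhang=6)
            assert (got.ei5, got.ei3, got.ee) == brute_force_counts(reads, intron, 6)


class TestIntronCoverage:
    def test_partial_coverage(self, toy_intron):
        # intron length 500; one read covering intronic bases 0..474
        read = ReadAlignment("r", toy_intron.chrom,
                             [(toy_intron.start, toy_intron.start + 475)])
        assert compute_intron_coverage([read], toy_intron) == pytest.approx(0.95)

    def test_tiling_reads_saturate(self, toy_intron):
        reads = [
            ReadAlignment(f"r{s}", toy_intron.chrom, [(s, s + 50)])
            for s in range(toy_intron.start, toy_intron.end, 50)
        ]
        assert compute_intron_coverage(reads, toy_intron) == 1.0

    def test_overlapping_reads_union_not_sum(self, toy_intron):
        s = toy_intron.start
        reads = [
            ReadAlignment("a", toy_intron.chrom, [(s, s + 250)]),
            ReadAlignment("b", toy_intron.chrom, [(s + 125, s + 375)]),
        ]
        assert compute_intron_coverage(reads, toy_intron) == pytest.approx(0.75)

    def test_empty_input_is_zero(self, toy_intron):
        assert compute_intron_coverage([], toy_intron) == 0.0


class TestComputeIRI:
    def test_direct_formula(self):
        r = compute_iri(JunctionCounts("i", ei5=3, ei3=1, ee=7))
        assert r.iri5 == pytest.approx(0.3)
        assert r.iri3 == pytest.approx(0.125)
        assert r.iri == pytest.approx(0.2125)
        assert not r.undefined_side

    def test_fully_spliced_and_fully_retained_limits(self):
        assert compute_iri(JunctionCounts("i", 0, 0, 10)).iri == 0.0
        assert compute_iri(JunctionCounts("i", 5, 3, 0)).iri == 1.0

    def test_one_undefined_side_is_flagged(self):
        r = compute_iri(JunctionCounts("i", ei5=5, ei3=0, ee=0))
        assert r.undefined_side
        assert math.isnan(r.iri3)

    def test_no_reads_at_all(self):
        r = compute_iri(JunctionCounts("i", 0, 0, 0))
        assert r.undefined_side and math.isnan(r.iri)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
    )
    def test_bounded_and_symmetric(self, ei5, ei3, ee):
        r = compute_iri(JunctionCounts("i", ei5, ei3, ee))
        if not math.isnan(r.iri):
            assert 0.0 <= r.iri <= 1.0
        swapped = compute_iri(JunctionCounts("i", ei3, ei5, ee))
        if not (math.isnan(r.iri) or math.isnan(swapped.iri)):
            assert swapped.iri == pytest.approx(r.iri)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(1, 200))
    def test_monotone_in_intronic_reads(self, ei5, ei3, ee):
        lo = compute_iri(JunctionCounts("i", ei5, ei3, ee)).iri
        hi = compute_iri(JunctionCounts("i", ei5 + 1, ei3, ee)).iri
        assert hi >= lo


def record(iri, coverage=1.0, exon_reads=100, covered=True, undefined=False):
    ei = max(0, round(100 * iri))
    counts = JunctionCounts("i", ei, ei, 100 - ei, covered, exon_reads)
    return IRIRecord("i", iri, iri, iri, coverage, counts, undefined)


class TestCallDetainedIntrons:
    def test_passing_record_is_called(self):
        assert call_detained_introns([record(0.2, 0.95, 50)])

    def test_boundary_iri_is_strictly_excluded(self):
        assert not call_detained_introns([record(0.1)])
        assert not call_detained_introns([record(0.2, coverage=0.9)])
        assert not call_detained_introns([record(0.2, exon_reads=20)])

    def test_ripseq_preset_relaxes_coverage_only(self):
        r = record(0.3, coverage=0.85)
        assert not call_detained_introns([r], **PRESETS["rnaseq"])
        assert call_detained_introns([r], **PRESETS["ripseq"])

    def test_undefined_or_uncovered_records_never_called(self):
        assert not call_detained_introns([record(0.5, undefined=True)])
        assert not call_detained_introns([record(0.5, covered=False)])

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_detained_introns([], iri_min=1.5)
        with pytest.raises(ValueError):
            call_detained_introns([], exon_reads_min=-1)


class TestQuantify:
    def test_matches_per_intron_counting(self, small_dataset):
        from detain.annotation import derive_introns
        from detain.simulate import simulate_short_reads

        cfg, genes, _ = small_dataset
        introns = [i for g in genes for i in derive_introns(g)]
        reads = simulate_short_reads(genes, 0.3, 50, cfg.rng("short"))
        records = quantify(reads, introns)
        assert len(records) == len(introns)
        for rec, intron in zip(records, introns):
            direct = count_junction_reads(
                [r for r in reads if r.chrom == intron.chrom], intron
            )
            assert (rec.counts.ei5, rec.counts.ei3, rec.counts.ee) == (
                direct.ei5, direct.ei3, direct.ee,
            )
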