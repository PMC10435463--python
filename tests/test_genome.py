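import numpy as np
import pytest
from hypothesis import given, strategies as st

import occudiff as od
from occudiff.genome import GenomeFormatError, GenomeValidationError, FeatureIndex


class TestChromSizes:
    def test_reads_two_chromosomes_in_file_order(self, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chrA\t25000\nchrB\t10000\n")
        layout = od.read_chrom_sizes(p)
        assert layout.names == ("chrA", "chrB")
        assert layout.total_length == 35_000

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty"
        p.write_text("")
        with pytest.raises(GenomeFormatError, match="no chromosomes"):
            od.read_chrom_sizes(p)

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "dup"
        p.write_text("chrA\t25000\nchrA\t100\n")
        with pytest.raises(GenomeValidationError, match="duplicate"):
            od.read_chrom_sizes(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad"
        p.write_text("chrA\t25000\nchrB\n")
        with pytest.raises(GenomeFormatError, match=":2"):
            od.read_chrom_sizes(p)

    def test_non_positive_length_rejected(self, tmp_path):
        p = tmp_path / "bad"
        p.write_text("chrA\t0\n")
        with pytest.raises(GenomeValidationError):
            od.read_chrom_sizes(p)


BED12_PLUS = (
    "chrA\t100\t1100\tg1\t0\t+\t100\t1100\t0\t2\t200,300,\t0,700,\n"
)


class TestGeneAnnotation:
    def test_bed12_plus_strand_tss_is_start(self, tmp_path, layout):
        p = tmp_path / "genes.bed"
        p.write_text(BED12_PLUS)
        gs = od.read_gene_annotation(p, layout)
        g = gs.genes["g1"]
        assert g.tss == 100
        assert len(g.exons) == 2
        assert (g.exons[1].start, g.exons[1].end) == (800, 1100)

    def test_minus_strand_tss_is_end(self, tmp_path, layout):
        p = tmp_path / "genes.bed"
        p.write_text("chrA\t100\t1100\tg1\t0\t-\t100\t1100\t0\t1\t1000,\t0,\n")
        gs = od.read_gene_annotation(p, layout)
        assert gs.genes["g1"].tss == 1100

    def test_gene_past_chromosome_end_rejected(self, tmp_path, layout):
        p = tmp_path / "genes.bed"
        p.write_text("chrB\t9000\t11000\tgX\t0\t+\t9000\t11000\t0\t1\t2000,\t0,\n")
        with pytest.raises(GenomeValidationError):
            od.read_gene_annotation(p, layout)

    def test_missing_strand_rejected(self, tmp_path, layout):
        p = tmp_path / "genes.bed"
        p.write_text("chrA\t100\t1100\tg1\t0\t.\t100\t1100\t0\t1\t1000,\t0,\n")
        with pytest.raises(GenomeValidationError, match="strand"):
            od.read_gene_annotation(p, layout)

    def test_gtf_matches_bed12(self, tmp_path, layout):
        bed = tmp_path / "genes.bed"
        bed.write_text(BED12_PLUS)
        gtf = tmp_path / "genes.gtf"
        # GTF is 1-based closed: [101, 1100] == BED [100, 1100)
        gtf.write_text(
            'chrA\tsrc\tgene\t101\t1100\t.\t+\t.\tgene_id "g1";\n'
            'chrA\tsrc\texon\t101\t300\t.\t+\t.\tgene_id "g1";\n'
            'chrA\tsrc\texon\t801\t1100\t.\t+\t.\tgene_id "g1";\n'
        )
        from_bed = od.read_gene_annotation(bed, layout).genes["g1"]
        from_gtf = od.read_gene_annotation(gtf, layout).genes["g1"]
        assert from_bed == from_gtf

    def test_bed12_roundtrip(self, tmp_path, geneset):
        p = tmp_path / "out.bed"
        od.write_gene_annotation_bed12(geneset, p)
        back = od.read_gene_annotation(p, geneset.layout)
        assert back.genes == geneset.genes


class TestPromoters:
    def test_plus_strand_symmetric_window(self, layout):
        g = od.GeneModel("g", od.Interval("chrA", 5000, 9000, "+"),
                         (od.Interval("chrA", 5000, 9000, "+"),))
        gs = od.GeneSet({"g": g}, layout)
        [(gid, iv)] = od.promoters(gs, od.AnnotationConfig(2000, 2000))
        assert (iv.start, iv.end) == (3000, 7000)

    def test_minus_strand_window_clipped_at_zero(self, layout):
        g = od.GeneModel("g", od.Interval("chrA", 100, 900, "-"),
                         (od.Interval("chrA", 100, 900, "-"),))
        gs = od.GeneSet({"g": g}, layout)
        [(gid, iv)] = od.promoters(gs, od.AnnotationConfig(2000, 2000))
        # tss = 900; [900 - down, 900 + up) clipped to chromosome start
        assert (iv.start, iv.end) == (0, 2900)

    def test_asymmetric_window_upstream_only(self, layout):
        g = od.GeneModel("g", od.Interval("chrA", 5000, 9000, "+"),
                         (od.Interval("chrA", 5000, 9000, "+"),))
        gs = od.GeneSet({"g": g}, layout)
        [(gid, iv)] = od.promoters(gs, od.AnnotationConfig(1000, 0))
        assert (iv.start, iv.end) == (4000, 5000)

    @given(
        tss_offset=st.integers(min_value=0, max_value=25_000 - 10),
        strand=st.sampled_from("+-"),
        up=st.integers(min_value=0, max_value=5000),
        down=st.integers(min_value=1, max_value=5000),
    )
    def test_promoter_always_within_chromosome(self, tss_offset, strand, up, down):
        layout = od.GenomeLayout((("chrA", 25_000),))
        start = min(tss_offset, 25_000 - 10)
        g = od.GeneModel("g", od.Interval("chrA", start, start + 10, strand),
                         (od.Interval("chrA", start, start + 10, strand),))
        gs = od.GeneSet({"g": g}, layout)
        [(_, iv)] = od.promoters(gs, od.AnnotationConfig(up, down))
        assert 0 <= iv.start < iv.end <= 25_000


class TestClassification:
    def test_priority_promoter_beats_exon(self, geneset):
        # 5100 is inside g1's first exon AND inside its promoter window
        assert od.classify_point("chrA", 5100, geneset) == od.FeatureCategory.PROMOTER

    def test_intron_inside_gene_outside_exons_and_promoter(self, geneset):
        assert od.classify_point("chrA", 7500, geneset) == od.FeatureCategory.INTRON

    def test_gene_free_chromosome_is_intergenic(self, geneset):
        assert od.classify_point("chrB", 5000, geneset) == od.FeatureCategory.INTERGENIC

    def test_unknown_chromosome_is_error(self, geneset):
        with pytest.raises(GenomeValidationError):
            od.classify_point("chrZ", 100, geneset)

    def test_interval_classified_by_midpoint(self, geneset):
        # [0, 10000) has midpoint 5000 = g1's TSS, inside the promoter window
        assert (
            od.classify_interval(od.Interval("chrA", 0, 10_000), geneset)
            == od.FeatureCategory.PROMOTER
        )

    def test_straddling_interval_with_midpoint_outside_promoter(self, geneset):
        # promoter window of g1 = [3000, 7000); [6500, 9500) has midpoint 8000,
        # inside g1's second exon, so the promoter overlap does not count
        assert (
            od.classify_interval(od.Interval("chrA", 6_500, 9_500), geneset)
            == od.FeatureCategory.EXON
        )

    def test_fully_intergenic_interval(self, geneset):
        assert (
            od.classify_interval(od.Interval("chrA", 22_000, 24_000), geneset)
            == od.FeatureCategory.INTERGENIC
        )

    def test_category_fractions_sum_to_one_over_any_tiling(self, geneset):
        index = FeatureIndex(geneset)
        bins = od.tile_genome(geneset.layout, 1000).bins
        counts = {c: 0 for c in od.FeatureCategory}
        for b in bins:
            counts[od.classify_interval(b, geneset, index=index)] += 1
        assert sum(counts.values()) == len(bins)

    def test_classification_is_deterministic(self, geneset):
        cats = [od.classify_point("chrA", p, geneset) for p in range(0, 25_000, 997)]
        again = [od.classify_point("chrA", p, geneset) for p in range(0, 25_000, 997)]
        assert cats == again
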