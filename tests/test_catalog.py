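import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txstress import (
    GeneRecord,
    build_catalog,
    filter_genes,
    load_annotation,
)
from txstress.catalog import AnnotationParseError, GeneCatalog


BED = """\
chr1\t100\t600\tgA\t0\t+
chr1\t1000\t1800\tgB\t0\t-
chr1\t1000\t1500\tgB\t0\t-
"""

GTF = """\
chr1\tsrc\ttranscript\t101\t600\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\tsrc\ttranscript\t1001\t1800\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
chr1\tsrc\ttranscript\t1001\t1500\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t2";
"""


class TestLoadAnnotation:
    def test_bed_half_open_lengths(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text(BED)
        records = {r.gene_id: r for r in load_annotation(path)}
        assert records["gA"].length_bp == 500
        assert records["gB"].length_bp == 800  # longest of 800/500

    def test_gtf_one_based_inclusive_lengths(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(GTF)
        records = {r.gene_id: r for r in load_annotation(path)}
        assert records["gA"].length_bp == 500
        assert records["gB"].length_bp == 800

    def test_dialect_equivalence(self, tmp_path):
        """GTF and BED encodings of the same intervals give identical lengths."""
        bed, gtf = tmp_path / "g.bed", tmp_path / "g.gtf"
        bed.write_text(BED)
        gtf.write_text(GTF)
        from_bed = {r.gene_id: r.length_bp for r in load_annotation(bed)}
        from_gtf = {r.gene_id: r.length_bp for r in load_annotation(gtf)}
        assert from_bed == from_gtf

    def test_longest_transcript_tie_breaks_on_smallest_id(self, tmp_path):
        gtf = tmp_path / "tie.gtf"
        gtf.write_text(
            'chr1\ts\ttranscript\t501\t1000\t.\t+\t.\tgene_id "g"; transcript_id "t2";\n'
            'chr1\ts\ttranscript\t101\t600\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
        )
        (rec,) = load_annotation(gtf)
        assert rec.length_bp == 500
        assert rec.start == 100  # t1 chosen, not t2

    def test_unparseable_line_names_line_number(self, tmp_path):
        bad = tmp_path / "bad.gtf"
        bad.write_text(
            'chr1\ts\ttranscript\t101\t600\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "chr1\tnot-enough-columns\n"
        )
        with pytest.raises(AnnotationParseError, match=":2"):
            load_annotation(bad)

    def test_gene_without_transcript_skipped(self, tmp_path, caplog):
        gtf = tmp_path / "orphan.gtf"
        gtf.write_text(
            'chr1\ts\tgene\t1\t900\t.\t+\t.\tgene_id "orphan";\n'
            'chr1\ts\ttranscript\t101\t600\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with caplog.at_level("WARNING"):
            records = load_annotation(gtf)
        assert [r.gene_id for r in records] == ["g"]
        assert "orphan" in caplog.text


class TestFilterGenes:
    @pytest.mark.parametrize(
        "length,expression,max_len,require_expr,kept",
        [
            (4_999, 1.0, None, False, False),  # below the 5 kb cut
            (5_000, 1.0, None, False, True),
            (750_001, 1.0, 750_000, False, False),  # above the 750 kb cut
            (750_000, 1.0, 750_000, False, True),
            (10_000, 0.0, None, True, False),  # unexpressed (0 RPM)
            (10_000, 0.0, None, False, True),
        ],
    )
    def test_boundary_rules(self, length, expression, max_len, require_expr, kept):
        records = [
            GeneRecord("probe", length, expression),
            GeneRecord("anchor", 10_000, 1.0),
        ]
        report = filter_genes(records, 5_000, max_len, require_expr)
        assert ("probe" in [r.gene_id for r in report.records]) is kept

    def test_removal_counts_per_rule(self):
        records = [
            GeneRecord("short", 1_000, 1.0),
            GeneRecord("long", 800_000, 1.0),
            GeneRecord("silent", 10_000, 0.0),
            GeneRecord("ok", 10_000, 1.0),
        ]
        report = filter_genes(records, 5_000, 750_000, require_expressed=True)
        assert (report.removed_short, report.removed_long,
                report.removed_unexpressed) == (1, 1, 1)

    def test_idempotence(self):
        records = [GeneRecord(f"g{i}", 2_000 * (i + 1), 1.0) for i in range(10)]
        once = filter_genes(records, 5_000, 12_000).records
        twice = filter_genes(once, 5_000, 12_000).records
        assert [r.gene_id for r in once] == [r.gene_id for r in twice]

    def test_empty_result_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            filter_genes([GeneRecord("g", 100, 1.0)], 5_000)


class TestBuildCatalog:
    def test_q_formula(self):
        cat = build_catalog([GeneRecord("g", 100_000, 1.0)], 3_200_000_000)
        assert cat.q[0] == pytest.approx(7.8125e-6, rel=1e-12)

    def test_alpha_normalization(self, two_gene_catalog):
        assert two_gene_catalog.alpha == pytest.approx([0.75, 0.25])

    def test_lengths_exceeding_genome_rejected(self):
        with pytest.raises(ValueError, match="simulator"):
            build_catalog([GeneRecord("g", 2_000, 1.0)], 1_000)

    def test_all_zero_expression_rejected(self):
        with pytest.raises(ValueError, match="zero expression"):
            build_catalog([GeneRecord("g", 2_000, 0.0)], 1_000_000)

    def test_duplicate_gene_ids_rejected(self):
        records = [GeneRecord("g", 2_000, 1.0), GeneRecord("g", 3_000, 1.0)]
        with pytest.raises(ValueError, match="unique"):
            build_catalog(records, 1_000_000)

    def test_tsv_round_trip(self, tmp_path, two_gene_catalog):
        path = tmp_path / "cat.tsv"
        two_gene_catalog.to_tsv(path)
        back = GeneCatalog.from_tsv(path)
        np.testing.assert_allclose(back.alpha, two_gene_catalog.alpha)
        np.testing.assert_array_equal(back.lengths, two_gene_catalog.lengths)

    @given(
        expr=st.lists(
            st.floats(min_value=0.01, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_alpha_sums_to_one_for_any_expression(self, expr):
        records = [
            GeneRecord(f"g{i}", 10_000, e) for i, e in enumerate(expr)
        ]
        cat = build_catalog(records, 10_000 * len(expr) * 10)
        assert cat.alpha.sum() == pytest.approx(1.0, abs=1e-9)

    def test_filter_then_rebuild_keeps_normalization(self, mouse_like_catalog):
        # rebuild after dropping the longest half of the genes
        keep = mouse_like_catalog.lengths < np.median(mouse_like_catalog.lengths)
        records = [
            GeneRecord(str(g), int(l), float(e))
            for g, l, e, k in zip(
                mouse_like_catalog.gene_ids,
                mouse_like_catalog.lengths,
                mouse_like_catalog.expression_raw,
                keep,
            )
            if k
        ]
        rebuilt = build_catalog(records, mouse_like_catalog.genome_length_L)
        assert rebuilt.alpha.sum() == pytest.approx(1.0, abs=1e-9)
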