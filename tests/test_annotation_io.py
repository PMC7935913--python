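"""Annotation parsing: coordinate conventions, filters, round-trips."""
import gzip

import pytest
from hypothesis import given, settings, strategies as st

from tecount.annotation_io import (
    parse_gtf,
    parse_rmsk,
    parse_te_bed,
    write_gtf,
    write_rmsk,
    write_te_bed,
)
from tecount.models import AnnotationParseError, GenomicInterval
from tecount.synthetic import FixtureSpec, make_annotation


def gtf_row(chrom, feature, start1, end1, gene_id, gene_name=None):
    attrs = f'gene_id "{gene_id}"; gene_name "{gene_name or gene_id}";'
    return f"{chrom}\thavana\t{feature}\t{start1}\t{end1}\t.\t+\t.\t{attrs}"


def rmsk_row(chrom, start, end, rep_name, rep_class):
    cols = ["585", "1000", "1", "1", "1", chrom, str(start), str(end), "0", "+",
            rep_name, rep_class, rep_class, "0", "0", "0", "1"]
    return "\t".join(cols)


class TestParseGtf:
    def test_one_based_inclusive_converted_to_half_open(self):
        genes = parse_gtf([gtf_row("chr1", "exon", 1001, 1100, "G1")])
        assert genes[0].exons == (GenomicInterval("chr1", 1000, 1100),)

    def test_body_is_union_span_without_gene_row(self):
        genes = parse_gtf(
            [
                gtf_row("chr1", "exon", 1001, 1100, "G1"),
                gtf_row("chr1", "exon", 1401, 1500, "G1"),
            ]
        )
        assert len(genes) == 1
        assert genes[0].body == GenomicInterval("chr1", 1000, 1500)

    def test_gene_row_defines_body(self):
        genes = parse_gtf(
            [
                gtf_row("chr1", "gene", 901, 1600, "G1"),
                gtf_row("chr1", "exon", 1001, 1100, "G1"),
            ]
        )
        assert genes[0].body == GenomicInterval("chr1", 900, 1600)

    def test_empty_stream(self):
        assert parse_gtf([]) == []

    def test_non_exon_rows_ignored_for_exon_set(self):
        genes = parse_gtf(
            [
                gtf_row("chr1", "exon", 1001, 1100, "G1"),
                gtf_row("chr1", "CDS", 1001, 1050, "G1"),
                gtf_row("chr1", "transcript", 1001, 1100, "G1"),
            ]
        )
        assert len(genes[0].exons) == 1

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\thavana\texon\t100",  # too few columns
            gtf_row("chr1", "exon", "x", 1100, "G1"),  # non-integer
            gtf_row("chr1", "exon", 1200, 1100, "G1"),  # end < start
        ],
    )
    def test_malformed_row_names_line(self, line):
        with pytest.raises(AnnotationParseError, match="line 2"):
            parse_gtf([gtf_row("chr1", "exon", 1, 50, "G0"), line])

    def test_gene_without_exons_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            genes = parse_gtf([gtf_row("chr1", "gene", 100, 200, "G1")])
        assert genes == []
        assert "G1" in caplog.text

    def test_gene_on_two_chromosomes_rejected(self):
        with pytest.raises(AnnotationParseError, match="chromosome"):
            parse_gtf(
                [
                    gtf_row("chr1", "exon", 100, 200, "G1"),
                    gtf_row("chr2", "exon", 100, 200, "G1"),
                ]
            )

    def test_gzip_input(self, tmp_path):
        path = tmp_path / "genes.gtf.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(gtf_row("chr1", "exon", 1001, 1100, "G1") + "\n")
        genes = parse_gtf(path)
        assert genes[0].gene_id == "G1"


class TestParseRmsk:
    def test_coordinates_taken_as_zero_based_half_open(self):
        tes = parse_rmsk([rmsk_row("chr1", 3000007, 3000156, "L1MdA_I", "LINE")])
        assert tes[0].interval == GenomicInterval("chr1", 3000007, 3000156)
        assert tes[0].subtype == "L1MdA_I"
        assert tes[0].interval.length == 3000156 - 3000007

    def test_class_filter_keeps_te_classes_only(self):
        rows = [
            rmsk_row("chr1", 100, 200, "L1MdA_I", "LINE"),
            rmsk_row("chr1", 400, 500, "(CA)n", "Simple_repeat"),
            rmsk_row("chr1", 700, 800, "MERVL-int", "LTR"),
        ]
        tes = parse_rmsk(rows, class_filter={"LINE", "SINE", "LTR", "Retroposon", "DNA"})
        assert [t.subtype for t in tes] == ["L1MdA_I", "MERVL-int"]

    def test_class_filter_substring_matches_uncertain_classes(self):
        tes = parse_rmsk(
            [rmsk_row("chr1", 100, 200, "MER53", "DNA?")], class_filter={"DNA"}
        )
        assert len(tes) == 1

    def test_no_filter_keeps_everything(self):
        rows = [
            rmsk_row("chr1", 100, 200, "L1MdA_I", "LINE"),
            rmsk_row("chr1", 400, 500, "(CA)n", "Simple_repeat"),
        ]
        assert len(parse_rmsk(rows)) == 2

    def test_bad_coordinates_raise(self):
        with pytest.raises(AnnotationParseError, match="line 1"):
            parse_rmsk([rmsk_row("chr1", 200, 200, "L1", "LINE")])


class TestParseTeBed:
    def test_basic_row(self):
        tes = parse_te_bed(["chr1\t100\t200\tMERVL-int"])
        assert tes[0].interval == GenomicInterval("chr1", 100, 200)
        assert tes[0].subtype == "MERVL-int"
        assert tes[0].te_class is None

    def test_empty_interval_rejected(self):
        with pytest.raises(AnnotationParseError):
            parse_te_bed(["chr1\t100\t100\tX"])

    def test_blank_and_track_lines_skipped(self):
        tes = parse_te_bed(
            ["track name=te", "", "# comment", "chr1\t10\t20\tA", "browser x"]
        )
        assert len(tes) == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_round_trip_all_formats(tmp_path, seed):
    """write(parse(x)) -> parse yields identical models, all formats."""
    ann = make_annotation(
        FixtureSpec(n_genes=8, n_te_subtypes=5, copies_per_subtype=4, seed=seed)
    )
    paths = ann.write(tmp_path)
    genes = parse_gtf(paths["gtf"])
    tes = parse_rmsk(paths["rmsk"])
    beds = parse_te_bed(paths["bed"])
    assert genes == ann.genes
    assert tes == ann.tes
    assert [(t.interval, t.subtype) for t in beds] == [
        (t.interval, t.subtype) for t in ann.tes
    ]
    # second generation round-trip
    write_gtf(genes, tmp_path / "again.gtf")
    assert parse_gtf(tmp_path / "again.gtf") == genes
    write_rmsk(tes, tmp_path / "again.rmsk")
    assert parse_rmsk(tmp_path / "again.rmsk") == tes
    write_te_bed(beds, tmp_path / "again.bed")
    assert parse_te_bed(tmp_path / "again.bed") == beds


@settings(derandomize=True, max_examples=50)
@given(
    start=st.integers(min_value=0, max_value=10**8),
    length=st.integers(min_value=1, max_value=10**6),
    name=st.text(
        alphabet=st.characters(whitelist_categories=("L", "N"), whitelist_characters="_-"),
        min_size=1,
        max_size=20,
    ),
)
def test_bed_round_trip_property(start, length, name):
    """Any interval survives a BED write/parse cycle unchanged."""
    line = f"chrX\t{start}\t{start + length}\t{name}"
    te = parse_te_bed([line])[0]
    assert te.interval.length == length
    assert parse_te_bed([f"{te.interval.chrom}\t{te.interval.start}\t{te.interval.end}\t{te.subtype}"]) == [te]
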