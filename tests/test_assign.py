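"""Alignment streaming and read-to-feature allocation rules."""
import pytest

from conftest import write_sam
from tecount.assign import (
    QCStats,
    assign_read,
    decide_assignment,
    read_alignments,
)
from tecount.index import build_index
from tecount.models import (
    Alignment,
    Assignment,
    AssignmentMode,
    BarcodeSource,
    Category,
    CountMode,
    GenomicInterval,
)

TAGS = [("CR", "AAAACCCCGGGG"), ("UR", "ACGTACGTACGT")]


class TestReadAlignments:
    def test_simple_cigar_blocks_zero_based(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [{"pos": 100, "cigar": "30M", "tags": TAGS}])
        alns = list(read_alignments(sam, CountMode()))
        assert alns[0].blocks == (GenomicInterval("chr1", 100, 130),)

    def test_splice_gap_splits_blocks(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam", [{"pos": 100, "cigar": "20M1000N20M", "tags": TAGS}]
        )
        alns = list(read_alignments(sam, CountMode()))
        assert alns[0].blocks == (
            GenomicInterval("chr1", 100, 120),
            GenomicInterval("chr1", 1120, 1140),
        )

    def test_secondary_supplementary_unmapped_skipped(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [
                {"pos": 100, "cigar": "30M", "tags": TAGS},
                {"pos": 100, "cigar": "30M", "tags": TAGS, "flag": 256},
                {"pos": 100, "cigar": "30M", "tags": TAGS, "flag": 2048},
                {"flag": 4, "tags": TAGS},
            ],
        )
        qc = QCStats()
        alns = list(read_alignments(sam, CountMode(), qc=qc))
        assert len(alns) == 1
        assert (qc.secondary, qc.supplementary, qc.unmapped, qc.kept) == (1, 1, 1, 1)

    def test_missing_barcode_and_umi_tallied(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [
                {"pos": 100, "cigar": "30M", "tags": []},
                {"pos": 100, "cigar": "30M", "tags": [("CR", "AC")]},
                {"pos": 100, "cigar": "30M", "tags": TAGS},
            ],
        )
        qc = QCStats()
        alns = list(read_alignments(sam, CountMode(umi_enabled=True), qc=qc))
        assert len(alns) == 1
        assert qc.missing_barcode == 1
        assert qc.missing_umi == 1

    def test_mapq_zero_multimappers_kept(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam", [{"pos": 100, "cigar": "30M", "tags": TAGS, "mapq": 0}]
        )
        assert len(list(read_alignments(sam, CountMode()))) == 1

    def test_filename_barcode_mode(self, tmp_path):
        sam = write_sam(tmp_path / "cellX.sam", [{"pos": 100, "cigar": "30M", "tags": []}])
        mode = CountMode(umi_enabled=False, barcode_source=BarcodeSource.FILENAME)
        alns = list(read_alignments(sam, mode))
        assert alns[0].barcode == "cellX"

    def test_read_name_barcode_extraction(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam",
            [{"pos": 100, "cigar": "30M", "tags": [], "name": "CCACGTTGTGGACTGA:A00519:1:1"}],
        )
        mode = CountMode(umi_enabled=False, barcode_source=BarcodeSource.READ_NAME)
        alns = list(read_alignments(sam, mode))
        assert alns[0].barcode == "CCACGTTGTGGACTGA"


def _aln(start, end, *more):
    blocks = tuple(GenomicInterval("chr1", s, e) for s, e in ((start, end),) + more)
    return Alignment("r", "BC", "U", "chr1", blocks)


class TestAssignmentRules:
    """The four geometries under each mode (toy annotation in conftest)."""

    def test_te_inside_exon_credits_gene_only_by_default(self, toy_index):
        out = assign_read(_aln(130, 160), toy_index, CountMode(AssignmentMode.GENE_PRIORITY))
        assert out == [Assignment.gene("GeneA")]

    def test_te_inside_exon_credits_both_in_dual_mode(self, toy_index):
        out = assign_read(_aln(130, 160), toy_index, CountMode(AssignmentMode.DUAL))
        assert out == [Assignment.gene("GeneA"), Assignment.te("TEexon")]

    def test_intronic_te_read_falls_through_to_te(self, toy_index):
        out = assign_read(_aln(215, 245), toy_index, CountMode(AssignmentMode.GENE_PRIORITY))
        assert out == [Assignment.te("TEintron")]

    def test_intronic_te_read_discarded_in_nointronic_mode(self, toy_index):
        out = assign_read(_aln(215, 245), toy_index, CountMode(AssignmentMode.NOINTRONIC))
        assert out == [Assignment.unassigned()]

    def test_intergenic_te_counted_in_every_mode(self, toy_index):
        for m in AssignmentMode:
            assert assign_read(_aln(5020, 5050), toy_index, CountMode(m)) == [
                Assignment.te("TEinter")
            ]

    def test_no_overlap_is_unassigned(self, toy_index):
        for m in AssignmentMode:
            assert assign_read(_aln(8100, 8130), toy_index, CountMode(m)) == [
                Assignment.unassigned()
            ]

    def test_spliced_blocks_pool_overlap(self, toy_index):
        # both blocks exonic -> gene; pooled bases drive the choice
        out = assign_read(_aln(180, 200, (450, 470)), toy_index, CountMode())
        assert out == [Assignment.gene("GeneA")]


class TestTieBreaking:
    def _two_gene_index(self):
        from tecount.models import GeneModel

        g1 = GeneModel("1", "Alpha", (GenomicInterval("chr1", 100, 200),), GenomicInterval("chr1", 100, 200))
        g2 = GeneModel("2", "Beta", (GenomicInterval("chr1", 150, 250),), GenomicInterval("chr1", 150, 250))
        return build_index([g1, g2], [])

    def test_greater_overlap_wins(self):
        idx = self._two_gene_index()
        out = assign_read(_aln(140, 200), idx, CountMode())  # Alpha 60, Beta 50
        assert out == [Assignment.gene("Alpha")]
        out = assign_read(_aln(160, 240), idx, CountMode())  # Alpha 40, Beta 80
        assert out == [Assignment.gene("Beta")]

    def test_exact_tie_breaks_lexicographically(self):
        idx = self._two_gene_index()
        out = assign_read(_aln(150, 200), idx, CountMode())  # both 50
        assert out == [Assignment.gene("Alpha")]


class TestModeInvariants:
    def test_gene_decisions_identical_in_dual(self, toy_index):
        for aln in (_aln(130, 160), _aln(215, 245), _aln(5020, 5050), _aln(8100, 8130)):
            gp = assign_read(aln, toy_index, CountMode(AssignmentMode.GENE_PRIORITY))
            dual = assign_read(aln, toy_index, CountMode(AssignmentMode.DUAL))
            assert [a for a in gp if a.category is Category.GENE] == [
                a for a in dual if a.category is Category.GENE
            ]

    def test_at_most_one_assignment_per_category(self, toy_index):
        for aln in (_aln(130, 160), _aln(180, 220), _aln(215, 245)):
            for m in AssignmentMode:
                out = assign_read(aln, toy_index, CountMode(m))
                cats = [a.category for a in out]
                assert cats.count(Category.GENE) <= 1
                assert cats.count(Category.TE) <= 1
                assert len(out) == 1 or m is AssignmentMode.DUAL

    def test_nointronic_te_assignments_subset_of_default(self, toy_index):
        for aln in (_aln(130, 160), _aln(215, 245), _aln(5020, 5050)):
            ni = assign_read(aln, toy_index, CountMode(AssignmentMode.NOINTRONIC))
            gp = assign_read(aln, toy_index, CountMode(AssignmentMode.GENE_PRIORITY))
            ni_te = {a.feature for a in ni if a.category is Category.TE}
            gp_te = {a.feature for a in gp if a.category is Category.TE}
            assert ni_te <= gp_te


def test_assignment_sequence_deterministic(tmp_path, toy_index):
    records = [
        {"pos": p, "cigar": "30M", "tags": TAGS} for p in (100, 130, 215, 5020, 8100)
    ]
    sam = write_sam(tmp_path / "det.sam", records)
    mode = CountMode()
    runs = []
    for _ in range(2):
        runs.append(
            [assign_read(a, toy_index, mode) for a in read_alignments(sam, mode)]
        )
    assert runs[0] == runs[1]
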