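"""Core domain types shared across the package.

Coordinates are uniformly 0-based half-open (``[start, end)``), the BED/UCSC
convention. GTF input is converted on parse; SAM positions are converted by
pysam. Strand is parsed where present but ignored for read assignment.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Tuple


class Category(enum.Enum):
    """What a read was credited to."""

    GENE = "GENE"
    TE = "TE"
    UNASSIGNED = "UNASSIGNED"


class AssignmentMode(enum.Enum):
    """Read-to-feature allocation policy.

    GENE_PRIORITY
        Exon overlap wins; TEs are credited only when no exon overlaps
        (the default). Intronic reads fall through to TEs.
    DUAL
        Gene decision as in GENE_PRIORITY, but a TE overlap is *also*
        credited, even for exonic reads (the ``--mode exclusive`` switch).
    NOINTRONIC
        Exonic reads go to genes; any other read touching a gene body is
        discarded; only reads fully outside gene bodies can count to TEs.
    """

    GENE_PRIORITY = "gene_priority"
    DUAL = "dual"
    NOINTRONIC = "nointronic"


class BarcodeSource(enum.Enum):
    TAG = "tag"            # CR:Z tag (10x-style)
    FILENAME = "filename"  # one input file per cell (C1/SMART-seq-style)
    READ_NAME = "read_name"  # barcode is the read-name prefix before ':'


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, start: int, end: int) -> int:
        """Number of bases shared with ``[start, end)`` (0 if disjoint)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class GeneModel:
    """A gene: identifier, display name, exon set and full genomic span."""

    gene_id: str
    gene_name: str
    exons: Tuple[GenomicInterval, ...]
    body: GenomicInterval

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exon set must be non-empty")
        for ex in self.exons:
            if ex.chrom != self.body.chrom:
                raise ValueError(
                    f"gene {self.gene_id}: exon on {ex.chrom} but body on "
                    f"{self.body.chrom}"
                )
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex} outside body {self.body}"
                )


@dataclass(frozen=True)
class TECopy:
    """One genomic copy of a transposable element.

    All copies sharing ``subtype`` (the RepeatMasker repName, e.g.
    ``MERVL-int``) are collapsed onto a single metagene feature when
    counting; per-copy identity is deliberately not part of the count
    matrix.
    """

    interval: GenomicInterval
    subtype: str
    te_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.subtype:
            raise ValueError("TE subtype must be non-empty")


@dataclass(frozen=True)
class Assignment:
    """Outcome of allocating one read: a catalog feature or UNASSIGNED."""

    feature: Optional[str]
    category: Category

    def __post_init__(self) -> None:
        if (self.category is Category.UNASSIGNED) != (self.feature is None):
            raise ValueError("feature must be None iff category is UNASSIGNED")

    @classmethod
    def gene(cls, name: str) -> "Assignment":
        return cls(name, Category.GENE)

    @classmethod
    def te(cls, subtype: str) -> "Assignment":
        return cls(subtype, Category.TE)

    @classmethod
    def unassigned(cls) -> "Assignment":
        return cls(None, Category.UNASSIGNED)


@dataclass(frozen=True)
class Alignment:
    """One kept read alignment.

    ``blocks`` are the reference-consuming segments from the CIGAR
    (splice gaps split blocks), sorted and disjoint.
    """

    read_name: str
    barcode: str
    umi: Optional[str]
    chrom: str
    blocks: Tuple[GenomicInterval, ...]
    primary: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment must have at least one block")


@dataclass
class CountMode:
    """Switchboard for a counting run."""

    assignment_mode: AssignmentMode = AssignmentMode.GENE_PRIORITY
    umi_enabled: bool = True
    barcode_source: BarcodeSource = BarcodeSource.TAG


@dataclass
class CellFilterParams:
    """Cell-quality filter settings.

    Defaults follow common droplet scRNA-seq practice: cells with fewer
    than 1000 total counts or fewer than 500 detected features are
    removed, then only the ``expect_cells`` cells with the most detected
    features are kept.
    """

    min_count: int = 1000
    min_genes: int = 500
    expect_cells: int = 10000
    combine: str = "or"  # "or": fail either threshold -> removed; "and": fail both

    def __post_init__(self) -> None:
        if min(self.min_count, self.min_genes, self.expect_cells) < 0:
            raise ValueError("cell filter parameters must be non-negative")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")


#: Repeat classes retained when building a chromatin-accessibility (ATAC)
#: TE index from a RepeatMasker table.
ATAC_TE_CLASSES = frozenset({"LINE", "SINE", "LTR", "Retroposon", "DNA"})


@dataclass
class AtacParams:
    """Settings for scATAC-seq TE quantification."""

    te_classes: frozenset = ATAC_TE_CLASSES
    min_te_reads: int = 1000
    # deduplication is always per cell: one read per (cell, position)

    def __post_init__(self) -> None:
        if not self.te_classes:
            raise ValueError("te_classes must be non-empty")
        if self.min_te_reads < 0:
            raise ValueError("min_te_reads must be non-negative")


class AnnotationParseError(ValueError):
    """Raised for malformed annotation rows; message names the line."""


class IndexLoadError(RuntimeError):
    """Raised when an index file cannot be read."""


class IndexVersionError(IndexLoadError):
    """Raised when an index file was written by an incompatible version."""
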