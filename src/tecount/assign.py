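"""Stream SAM/BAM alignments and allocate reads to features.

Reads are credited to gene exons first and to TE metagenes only when no
exon overlaps (GENE_PRIORITY); DUAL additionally credits a TE overlap
even inside exons; NOINTRONIC discards any non-exonic read that touches
a gene body, so only reads fully outside gene bodies can count to TEs.

Multimapping reads are expected to arrive as a single best alignment
(e.g. STAR ``--outSAMmultNmax 1``); MAPQ-0 records are kept — they carry
most of the TE signal. Secondary, supplementary and unmapped records are
skipped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Union

import pysam

from .index import FeatureIndex, QueryResult
from .models import (
    Alignment,
    Assignment,
    AssignmentMode,
    BarcodeSource,
    CountMode,
    GenomicInterval,
)

log = logging.getLogger(__name__)

BARCODE_TAG = "CR"
UMI_TAG = "UR"


@dataclass
class QCStats:
    """Tallies of records seen and why any were skipped."""

    seen: int = 0
    kept: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    missing_barcode: int = 0
    missing_umi: int = 0
    bad_cigar: int = 0
    positional_duplicates: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def read_alignments(
    path: Union[str, Path],
    mode: CountMode,
    filename_barcode: Optional[str] = None,
    qc: Optional[QCStats] = None,
) -> Iterator[Alignment]:
    """Yield one :class:`Alignment` per kept record of a SAM/BAM file.

    Barcode comes from the CR:Z tag (TAG source), from
    ``filename_barcode`` (FILENAME source, C1-style one file per cell),
    or from the read-name prefix before the first ':' (READ_NAME source,
    10x ATAC preprocessing). Records missing a required barcode or UMI
    are skipped and tallied.
    """
    qc = qc if qc is not None else QCStats()
    path = str(path)
    if mode.barcode_source is BarcodeSource.FILENAME and not filename_barcode:
        filename_barcode = Path(path).name.split(".")[0]

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            qc.seen += 1
            if rec.is_unmapped:
                qc.unmapped += 1
                continue
            if rec.is_secondary:
                qc.secondary += 1
                continue
            if rec.is_supplementary:
                qc.supplementary += 1
                continue

            if mode.barcode_source is BarcodeSource.TAG:
                if rec.has_tag(BARCODE_TAG):
                    barcode = rec.get_tag(BARCODE_TAG)
                else:
                    qc.missing_barcode += 1
                    continue
            elif mode.barcode_source is BarcodeSource.READ_NAME:
                if rec.has_tag(BARCODE_TAG):
                    barcode = rec.get_tag(BARCODE_TAG)
                else:
                    name = rec.query_name or ""
                    barcode = name.split(":", 1)[0] if ":" in name else ""
                    if not barcode:
                        qc.missing_barcode += 1
                        continue
            else:
                barcode = filename_barcode

            umi = None
            if mode.umi_enabled:
                if rec.has_tag(UMI_TAG):
                    umi = rec.get_tag(UMI_TAG)
                else:
                    qc.missing_umi += 1
                    continue

            try:
                raw_blocks = rec.get_blocks()
            except (ValueError, TypeError):
                qc.bad_cigar += 1
                continue
            if not raw_blocks:
                qc.bad_cigar += 1
                continue
            chrom = rec.reference_name
            blocks = tuple(
                GenomicInterval(chrom, s, e) for s, e in raw_blocks if e > s
            )
            if not blocks:
                qc.bad_cigar += 1
                continue
            qc.kept += 1
            yield Alignment(rec.query_name, barcode, umi, chrom, blocks)


def _best(bases: Dict[str, int]) -> str:
    """Candidate with the most overlapped bases; ties -> smallest name."""
    return min(bases.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def decide_assignment(hits: QueryResult, mode: AssignmentMode) -> List[Assignment]:
    """Turn per-category overlaps into assignments under ``mode``.

    Returns a single-element list except under DUAL, which may credit
    both a gene and a TE for the same read.
    """
    if mode is AssignmentMode.GENE_PRIORITY:
        if hits.exon_bases:
            return [Assignment.gene(_best(hits.exon_bases))]
        if hits.te_bases:
            return [Assignment.te(_best(hits.te_bases))]
        return [Assignment.unassigned()]
    if mode is AssignmentMode.DUAL:
        out: List[Assignment] = []
        if hits.exon_bases:
            out.append(Assignment.gene(_best(hits.exon_bases)))
        if hits.te_bases:
            out.append(Assignment.te(_best(hits.te_bases)))
        return out or [Assignment.unassigned()]
    if mode is AssignmentMode.NOINTRONIC:
        if hits.exon_bases:
            return [Assignment.gene(_best(hits.exon_bases))]
        if hits.body_genes:
            return [Assignment.unassigned()]
        if hits.te_bases:
            return [Assignment.te(_best(hits.te_bases))]
        return [Assignment.unassigned()]
    raise ValueError(f"unknown assignment mode: {mode!r}")


def assign_read(
    aln: Alignment, index: FeatureIndex, mode: CountMode
) -> List[Assignment]:
    """Allocate one alignment to feature(s) under the run's mode."""
    return decide_assignment(index.query(aln.blocks), mode.assignment_mode)
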