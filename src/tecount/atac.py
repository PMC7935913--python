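"""scATAC-seq mode: TE-only index, positional dedup, read counting.

Chromatin-accessibility data has no UMIs; PCR duplicates are removed
positionally instead — at most one read per (cell, chromosome, leftmost
aligned position). The TE annotation is restricted to the transposon
classes (LINE, SINE, LTR, Retroposon, DNA), dropping satellites, simple
repeats and structural RNAs, and TE metagenes with very low total
counts can be dropped by a post-filter.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Set, Tuple, Union

from . import annotation_io
from .assign import QCStats, assign_read, decide_assignment
from .index import FeatureIndex, build_index
from .matrix import CountMatrix, accumulate, filter_features
from .models import Alignment, AssignmentMode, AtacParams, Category, TECopy

log = logging.getLogger(__name__)


def _sniff_rmsk(path: Union[str, Path]) -> bool:
    """True if the file looks like a full rmsk table (vs 4-column BED)."""
    with annotation_io.open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            return len(line.rstrip("\n").split("\t")) >= annotation_io._RMSK_MIN_COLS
    return False


def build_atac_index(
    te_source: Union[str, Path],
    params: Optional[AtacParams] = None,
) -> FeatureIndex:
    """Build a gene-free TE index for ATAC counting.

    ``te_source`` is an rmsk.txt table (class filter applied) or a
    4-column BED (classes unknown, every row kept). Refuses to build an
    empty index.
    """
    params = params or AtacParams()
    if _sniff_rmsk(te_source):
        tes: List[TECopy] = annotation_io.parse_rmsk(
            te_source, class_filter=set(params.te_classes)
        )
        filter_used: Optional[List[str]] = sorted(params.te_classes)
    else:
        tes = annotation_io.parse_te_bed(te_source)
        filter_used = None
    if not tes:
        raise ValueError(f"no TE annotations retained from {te_source}; refusing to build an empty index")
    return build_index(
        [], tes, metadata={"mode": "atac", "class_filter": filter_used}
    )


def dedup_positions(
    alignments: Iterable[Alignment], qc: Optional[QCStats] = None
) -> Iterator[Alignment]:
    """Keep one alignment per (cell, chromosome, leftmost position).

    First-seen wins; later duplicates are dropped and tallied. The scope
    is per cell, so two cells covering the same position both keep their
    read.
    """
    seen: Set[Tuple[str, str, int]] = set()
    for aln in alignments:
        key = (aln.barcode, aln.chrom, aln.blocks[0].start)
        if key in seen:
            if qc is not None:
                qc.positional_duplicates += 1
            continue
        seen.add(key)
        yield aln


def atac_count(
    alignments: Iterable[Alignment],
    index: FeatureIndex,
    params: Optional[AtacParams] = None,
    qc: Optional[QCStats] = None,
    unassigned_tally: Optional[list] = None,
) -> CountMatrix:
    """Deduplicate, assign against a gene-free index, count reads.

    With no genes in the index every assignment is TE or UNASSIGNED.
    Features with total counts below ``params.min_te_reads`` are dropped
    afterwards (set it to 0 to keep everything).
    """
    params = params or AtacParams()
    if index.has_genes:
        raise ValueError("atac_count requires a gene-free (TE-only) index")

    n_unassigned = 0
    records = []
    cells: Set[str] = set()
    from .models import CountMode  # local import to avoid cycle noise

    mode = CountMode(AssignmentMode.GENE_PRIORITY, umi_enabled=False)
    for aln in dedup_positions(alignments, qc=qc):
        cells.add(aln.barcode)
        for a in assign_read(aln, index, mode):
            if a.category is Category.UNASSIGNED:
                n_unassigned += 1
            else:
                records.append((aln.barcode, None, a))
    if unassigned_tally is not None:
        unassigned_tally.append(n_unassigned)
    mat = accumulate(
        records,
        index.catalog,
        umi_enabled=False,
        all_barcodes=cells,
        feature_types=index.feature_categories(),
    )
    return filter_features(mat, params.min_te_reads)
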