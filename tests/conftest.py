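"""Shared fixtures: a hand-built rule geometry and SAM helpers.

The toy annotation covers the four geometries the assignment rules
distinguish: a TE inside an exon, a TE inside an intron, an intergenic
TE, and a feature-free region.
"""
from __future__ import annotations

from typing import List, Sequence, Tuple

import pysam
import pytest

from tecount.index import FeatureIndex, build_index
from tecount.models import GeneModel, GenomicInterval, TECopy


@pytest.fixture(scope="session")
def toy_genes() -> List[GeneModel]:
    # GeneA: exon1 [100,200), intron [200,450), exon2 [450,500)
    return [
        GeneModel(
            "GID_A",
            "GeneA",
            (
                GenomicInterval("chr1", 100, 200),
                GenomicInterval("chr1", 450, 500),
            ),
            GenomicInterval("chr1", 100, 500),
        )
    ]


@pytest.fixture(scope="session")
def toy_tes() -> List[TECopy]:
    return [
        TECopy(GenomicInterval("chr1", 120, 180), "TEexon", "LTR"),    # inside exon1
        TECopy(GenomicInterval("chr1", 210, 270), "TEintron", "LINE"),  # inside intron
        TECopy(GenomicInterval("chr1", 5000, 5100), "TEinter", "SINE"),  # intergenic
    ]


@pytest.fixture(scope="session")
def toy_index(toy_genes, toy_tes) -> FeatureIndex:
    return build_index(toy_genes, toy_tes)


def write_sam(
    path,
    records: Sequence[dict],
    chrom_sizes: dict = None,
) -> str:
    """Write simple SAM records; each dict may set name, flag, chrom,
    pos (0-based), cigar, tags (list of (tag, value))."""
    chrom_sizes = chrom_sizes or {"chr1": 1_000_000, "chr2": 1_000_000}
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, rec in enumerate(records):
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.get("name", f"q{i:04d}")
            a.flag = rec.get("flag", 0)
            if not a.is_unmapped:
                a.reference_id = out.header.get_tid(rec.get("chrom", "chr1"))
                a.reference_start = rec["pos"]
                a.cigarstring = rec["cigar"]
            qlen = sum(
                n for op, n in (a.cigartuples or [(0, 50)]) if op in (0, 1, 4, 7, 8)
            )
            a.query_sequence = "A" * max(qlen, 1)
            a.mapping_quality = rec.get("mapq", 0)
            a.set_tags(rec.get("tags", []))
            out.write(a)
    return str(path)
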