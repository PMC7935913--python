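"""Parse and write gene and TE annotations.

Supported inputs: GTF (GENCODE dialect, 1-based inclusive -> converted to
0-based half-open), the UCSC RepeatMasker table dump (``rmsk.txt``), and
4-column BED. Plain or gzip files are both accepted (gzip detected by
magic bytes). Writers exist for all three formats so parsed annotations
round-trip.
"""
from __future__ import annotations

import gzip
import io
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, TextIO, Tuple, Union

from .models import (
    AnnotationParseError,
    GeneModel,
    GenomicInterval,
    TECopy,
)

log = logging.getLogger(__name__)

Source = Union[str, Path, TextIO, Iterable[str]]

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def open_text(path: Union[str, Path]) -> TextIO:
    """Open ``path`` as text, transparently decompressing gzip."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _as_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open_text(source) as fh:
            yield from fh
    else:
        yield from source


def _int_field(value: str, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise AnnotationParseError(
            f"line {lineno}: non-integer {what}: {value!r}"
        ) from None


def parse_gtf(source: Source) -> List[GeneModel]:
    """Parse a GTF stream into one :class:`GeneModel` per gene_id.

    ``exon`` rows provide the exon set; the ``gene`` row, when present,
    provides the gene-body span (else the union span of the exons is
    used). All other feature types are ignored. Genes with no exon rows
    are skipped with a warning.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    spans: Dict[str, GenomicInterval] = {}
    names: Dict[str, str] = {}
    chroms: Dict[str, str] = {}
    order: List[str] = []

    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise AnnotationParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        chrom, _src, feature = cols[0], cols[1], cols[2]
        if feature not in ("exon", "gene"):
            continue
        start1 = _int_field(cols[3], lineno, "start")
        end1 = _int_field(cols[4], lineno, "end")
        if end1 < start1:
            raise AnnotationParseError(f"line {lineno}: end < start")
        attrs = dict(_GTF_ATTR.findall(cols[8]))
        gene_id = attrs.get("gene_id")
        if not gene_id:
            raise AnnotationParseError(f"line {lineno}: missing gene_id attribute")
        if gene_id not in chroms:
            chroms[gene_id] = chrom
            order.append(gene_id)
        elif chroms[gene_id] != chrom:
            raise AnnotationParseError(
                f"line {lineno}: gene {gene_id} spans chromosomes "
                f"{chroms[gene_id]} and {chrom}"
            )
        names.setdefault(gene_id, attrs.get("gene_name", gene_id))
        iv = GenomicInterval(chrom, start1 - 1, end1)  # 1-based incl -> 0-based half-open
        if feature == "exon":
            exons.setdefault(gene_id, []).append(iv)
        else:
            spans[gene_id] = iv

    genes: List[GeneModel] = []
    for gid in order:
        exs = exons.get(gid)
        if not exs:
            log.warning("gene %s has no exon rows; skipped", gid)
            continue
        exs = sorted(set(exs))
        lo = min(e.start for e in exs)
        hi = max(e.end for e in exs)
        span = spans.get(gid)
        if span is not None:
            # widen to cover stray exons so containment always holds
            lo, hi = min(lo, span.start), max(hi, span.end)
        body = GenomicInterval(chroms[gid], lo, hi)
        genes.append(GeneModel(gid, names[gid], tuple(exs), body))
    return genes


# rmsk.txt field layout (1-based): 6 genoName, 7 genoStart, 8 genoEnd,
# 10 strand, 11 repName, 12 repClass
_RMSK_MIN_COLS = 12


def parse_rmsk(
    source: Source, class_filter: Optional[Set[str]] = None
) -> List[TECopy]:
    """Parse a UCSC RepeatMasker table dump into TE copies.

    genoStart is already 0-based, genoEnd exclusive (UCSC convention).
    ``class_filter`` keeps only rows whose repClass matches one of the
    given classes (substring match, so e.g. ``DNA?`` passes a ``DNA``
    filter); ``None`` keeps every row.
    """
    out: List[TECopy] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < _RMSK_MIN_COLS:
            raise AnnotationParseError(
                f"line {lineno}: expected >= {_RMSK_MIN_COLS} columns, got {len(cols)}"
            )
        start = _int_field(cols[6], lineno, "genoStart")
        end = _int_field(cols[7], lineno, "genoEnd")
        if end <= start:
            raise AnnotationParseError(f"line {lineno}: genoEnd <= genoStart")
        rep_class = cols[11]
        if class_filter is not None and not any(c in rep_class for c in class_filter):
            continue
        out.append(TECopy(GenomicInterval(cols[5], start, end), cols[10], rep_class))
    return out


def parse_te_bed(source: Source) -> List[TECopy]:
    """Parse a 4-column BED (chrom, start, end, repName) into TE copies.

    Repeat class is unknown for BED input (``te_class`` is None). Blank
    lines and track/browser/comment lines are skipped.
    """
    out: List[TECopy] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if (
            not line.strip()
            or line.startswith("#")
            or line.startswith("track")
            or line.startswith("browser")
        ):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise AnnotationParseError(
                f"line {lineno}: expected 4 tab-separated columns, got {len(cols)}"
            )
        start = _int_field(cols[1], lineno, "start")
        end = _int_field(cols[2], lineno, "end")
        if end <= start:
            raise AnnotationParseError(f"line {lineno}: end <= start")
        out.append(TECopy(GenomicInterval(cols[0], start, end), cols[3]))
    return out


def write_gtf(genes: Sequence[GeneModel], path: Union[str, Path]) -> None:
    """Write GeneModels as GTF (gene + exon rows, 1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.body.chrom}\ttecount\tgene\t{g.body.start + 1}\t{g.body.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )
            for ex in sorted(g.exons):
                fh.write(
                    f"{ex.chrom}\ttecount\texon\t{ex.start + 1}\t{ex.end}"
                    f"\t.\t+\t.\t{attrs}\n"
                )


def write_rmsk(tes: Sequence[TECopy], path: Union[str, Path]) -> None:
    """Write TE copies in the 17-column rmsk.txt table layout.

    Alignment-score and repeat-position columns carry placeholder zeros;
    the coordinate and name/class fields round-trip.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for te in tes:
            iv = te.interval
            cols = [
                "0", "0", "0", "0", "0",
                iv.chrom, str(iv.start), str(iv.end), "0", "+",
                te.subtype, te.te_class or "Unknown", te.te_class or "Unknown",
                "0", "0", "0", "0",
            ]
            fh.write("\t".join(cols) + "\n")


def write_te_bed(tes: Sequence[TECopy], path: Union[str, Path]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for te in tes:
            iv = te.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.subtype}\n")
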