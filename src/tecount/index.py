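"""Queryable genome overlay resolving aligned blocks to features.

The index holds three interval stores per chromosome — exons, gene
bodies, TE copies — plus an ordered feature catalog (all gene names,
then all TE subtypes). TE copies of the same subtype collapse onto one
catalog entry (the metagene); per-copy identity is not recoverable from
query results, by design.

Genes sharing a display name are likewise pooled under that name, so
overlap queries and the catalog are keyed by gene name throughout.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from intervaltree import IntervalTree

from .models import (
    GeneModel,
    GenomicInterval,
    IndexLoadError,
    IndexVersionError,
    TECopy,
)

log = logging.getLogger(__name__)

INDEX_FORMAT = "tecount-index"
INDEX_VERSION = 1


@dataclass
class QueryResult:
    """Per-category overlaps for one read's blocks.

    ``exon_bases`` / ``te_bases`` map feature name -> total overlapped
    bases summed over blocks; ``body_genes`` is the set of gene names
    whose body is touched by any block.
    """

    exon_bases: Dict[str, int] = field(default_factory=dict)
    body_genes: Set[str] = field(default_factory=set)
    te_bases: Dict[str, int] = field(default_factory=dict)


class FeatureIndex:
    """Genome overlay over genes and TE metagenes.

    Build with :func:`build_index`; query with :meth:`query`; persist
    with :meth:`save` / :func:`load_index`.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        tes: Sequence[TECopy],
        metadata: Optional[dict] = None,
    ):
        self.gene_models: Tuple[GeneModel, ...] = tuple(genes)
        self.te_copies: Tuple[TECopy, ...] = tuple(tes)
        self.metadata: dict = dict(metadata or {})

        self.gene_names: List[str] = sorted({g.gene_name for g in genes})
        self.te_subtypes: List[str] = sorted({t.subtype for t in tes})
        self.catalog: List[str] = self.gene_names + self.te_subtypes

        self._exon: Dict[str, IntervalTree] = {}
        self._body: Dict[str, IntervalTree] = {}
        self._te: Dict[str, IntervalTree] = {}
        for g in genes:
            for ex in g.exons:
                self._exon.setdefault(ex.chrom, IntervalTree()).addi(
                    ex.start, ex.end, g.gene_name
                )
            self._body.setdefault(g.body.chrom, IntervalTree()).addi(
                g.body.start, g.body.end, g.gene_name
            )
        for t in tes:
            iv = t.interval
            self._te.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, t.subtype
            )
        self._warned_chroms: Set[str] = set()

    # -- queries -----------------------------------------------------------

    @property
    def has_genes(self) -> bool:
        return bool(self.gene_names)

    def feature_categories(self) -> List[str]:
        """Category label (GENE/TE) for each catalog entry, in order."""
        return ["GENE"] * len(self.gene_names) + ["TE"] * len(self.te_subtypes)

    def query(self, blocks: Sequence[GenomicInterval]) -> QueryResult:
        """Resolve sorted, disjoint, same-chromosome blocks to features.

        Unknown chromosomes yield an empty result (logged once each).
        """
        res = QueryResult()
        chrom = blocks[0].chrom
        known = chrom in self._exon or chrom in self._body or chrom in self._te
        if not known:
            if chrom not in self._warned_chroms:
                self._warned_chroms.add(chrom)
                log.warning("chromosome %s absent from index; reads there unassigned", chrom)
            return res
        exon_tree = self._exon.get(chrom)
        body_tree = self._body.get(chrom)
        te_tree = self._te.get(chrom)
        for b in blocks:
            if exon_tree is not None:
                for hit in exon_tree.overlap(b.start, b.end):
                    ov = min(hit.end, b.end) - max(hit.begin, b.start)
                    res.exon_bases[hit.data] = res.exon_bases.get(hit.data, 0) + ov
            if body_tree is not None:
                for hit in body_tree.overlap(b.start, b.end):
                    res.body_genes.add(hit.data)
            if te_tree is not None:
                for hit in te_tree.overlap(b.start, b.end):
                    ov = min(hit.end, b.end) - max(hit.begin, b.start)
                    res.te_bases[hit.data] = res.te_bases.get(hit.data, 0) + ov
        return res

    # -- persistence -------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        doc = {
            "format": INDEX_FORMAT,
            "version": INDEX_VERSION,
            "metadata": self.metadata,
            "genes": [
                [
                    g.gene_id,
                    g.gene_name,
                    g.body.chrom,
                    g.body.start,
                    g.body.end,
                    [[e.start, e.end] for e in g.exons],
                ]
                for g in self.gene_models
            ],
            "tes": [
                [t.interval.chrom, t.interval.start, t.interval.end, t.subtype, t.te_class]
                for t in self.te_copies
            ],
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(doc, fh)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureIndex):
            return NotImplemented
        return (
            set(self.gene_models) == set(other.gene_models)
            and set(self.te_copies) == set(other.te_copies)
            and self.catalog == other.catalog
        )


def build_index(
    genes: Sequence[GeneModel],
    tes: Sequence[TECopy],
    metadata: Optional[dict] = None,
) -> FeatureIndex:
    """Build a :class:`FeatureIndex`, merging duplicate gene_ids.

    Two GeneModels sharing a gene_id on the same chromosome are merged
    (exon union, body union span); on different chromosomes this is an
    error.
    """
    merged: Dict[str, GeneModel] = {}
    for g in genes:
        prev = merged.get(g.gene_id)
        if prev is None:
            merged[g.gene_id] = g
            continue
        if prev.body.chrom != g.body.chrom:
            raise ValueError(
                f"duplicate gene_id {g.gene_id} on conflicting chromosomes "
                f"{prev.body.chrom} / {g.body.chrom}"
            )
        exons = tuple(sorted(set(prev.exons) | set(g.exons)))
        body = GenomicInterval(
            prev.body.chrom,
            min(prev.body.start, g.body.start),
            max(prev.body.end, g.body.end),
        )
        merged[g.gene_id] = GeneModel(g.gene_id, prev.gene_name, exons, body)
    return FeatureIndex(list(merged.values()), tes, metadata)


def checksum_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_index(path: Union[str, Path]) -> FeatureIndex:
    """Load an index written by :meth:`FeatureIndex.save`."""
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexLoadError(f"cannot read index file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != INDEX_FORMAT:
        raise IndexLoadError(f"{path} is not a {INDEX_FORMAT} file")
    if doc.get("version") != INDEX_VERSION:
        raise IndexVersionError(
            f"index {path} has version {doc.get('version')}, this build reads "
            f"version {INDEX_VERSION}; please rebuild the index"
        )
    genes = [
        GeneModel(
            gid,
            name,
            tuple(GenomicInterval(chrom, s, e) for s, e in exons),
            GenomicInterval(chrom, bs, be),
        )
        for gid, name, chrom, bs, be, exons in doc["genes"]
    ]
    tes = [
        TECopy(GenomicInterval(chrom, s, e), subtype, te_class)
        for chrom, s, e, subtype, te_class in doc["tes"]
    ]
    return FeatureIndex(genes, tes, doc.get("metadata"))
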