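"""Synthetic annotations and aligned reads with known ground truth.

The generator lays out a small genome (two chromosomes) of genes with
introns, plus TE copies in every geometry the assignment rules care
about: inside exons, inside introns, intergenic, and straddling an
exon-intron boundary. Reads are then simulated as post-alignment SAM
records (the tool's actual input boundary) with cell barcodes, UMIs,
spliced alignments, deliberately ambiguous placements, and injected PCR
duplicates.

Two properties of the layout matter for testing: TE copies are pairwise
separated by more than a read length, so any read overlaps at most one
copy (making per-copy and metagene counts provably consistent), and a
read-free "desert" region guarantees unassignable reads.

This module also carries the brute-force oracle: an index-free linear
scan over every annotation interval, with its own copy of the priority
and tie rules, used to validate the fast path.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from . import annotation_io
from .matrix import CountMatrix
from .models import (
    Alignment,
    Assignment,
    AssignmentMode,
    GeneModel,
    GenomicInterval,
    TECopy,
)

_CHROMS = ("chr1", "chr2")
_TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Retroposon")
_TE_SPACING = 220  # min separation between TE copies; > max read length
_MAX_READ = 90

SCENARIOS = ("intergenic", "in_intron", "in_exon", "exon_boundary")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults emulate a small droplet scRNA-seq run: ~13% of reads
    TE-derived, ~10% intronic, ~12% unassignable, a modest PCR duplicate
    rate, and a mix of unspliced and spliced exonic reads. The same seed
    always reproduces the same files.
    """

    n_genes: int = 50
    n_te_subtypes: int = 20
    copies_per_subtype: int = 10
    n_cells: int = 20
    reads_per_cell: int = 100
    duplicate_rate: float = 0.10
    spliced_fraction: float = 0.15
    te_read_fraction: float = 0.13
    intronic_read_fraction: float = 0.10
    intergenic_read_fraction: float = 0.12
    ambiguous_read_fraction: float = 0.02
    include_qc_records: bool = True
    seed: int = 0


@dataclass
class SyntheticAnnotation:
    """A generated annotation plus the layout facts tests rely on."""

    genes: List[GeneModel]
    tes: List[TECopy]
    scenarios: List[str]  # parallel to tes
    chrom_sizes: Dict[str, int]
    deserts: Dict[str, Tuple[int, int]]  # feature-free region per chromosome

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        """Write GTF, rmsk-format and BED4 files; returns their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "genes.gtf",
            "rmsk": outdir / "repeats.rmsk.txt",
            "bed": outdir / "repeats.bed",
        }
        annotation_io.write_gtf(self.genes, paths["gtf"])
        annotation_io.write_rmsk(self.tes, paths["rmsk"])
        annotation_io.write_te_bed(self.tes, paths["bed"])
        return paths

    def introns(self) -> List[GenomicInterval]:
        out = []
        for g in self.genes:
            exs = sorted(g.exons)
            for a, b in zip(exs, exs[1:]):
                if b.start > a.end:
                    out.append(GenomicInterval(a.chrom, a.end, b.start))
        return out


class _Host:
    """A region that can hold TE copies, filled left to right."""

    __slots__ = ("chrom", "cursor", "end")

    def __init__(self, chrom: str, start: int, end: int):
        self.chrom, self.cursor, self.end = chrom, start, end

    def place(self, length: int) -> Optional[Tuple[str, int, int]]:
        if self.cursor + length > self.end:
            return None
        iv = (self.chrom, self.cursor, self.cursor + length)
        self.cursor += length + _TE_SPACING
        return iv


def _place_in(hosts: List[_Host], length: int) -> Optional[Tuple[str, int, int]]:
    for h in hosts:
        iv = h.place(length)
        if iv is not None:
            return iv
    return None


def make_annotation(spec: FixtureSpec) -> SyntheticAnnotation:
    """Lay out genes and TE copies; every overlap scenario occurs when
    the requested copy count allows it."""
    rng = np.random.default_rng(spec.seed)
    genes: List[GeneModel] = []
    gap_hosts: List[_Host] = []
    exon_hosts: List[_Host] = []
    intron_hosts: List[_Host] = []
    boundary_hosts: List[_Host] = []  # one TE per exon/intron junction
    cursors = {c: 10_000 for c in _CHROMS}

    for i in range(spec.n_genes):
        chrom = _CHROMS[i % len(_CHROMS)]
        gap = int(rng.integers(1500, 4000))
        gstart, gend = cursors[chrom], cursors[chrom] + gap
        if gap > 700:
            gap_hosts.append(_Host(chrom, gstart + 250, gend - 250))
        pos = gend
        n_ex = int(rng.integers(2, 5))
        exons: List[GenomicInterval] = []
        for j in range(n_ex):
            # the first exon hosts in-exon TE copies and must leave a
            # clear >= _TE_SPACING gap before its junction boundary TE
            elen = int(rng.integers(600, 900)) if j == 0 else int(rng.integers(300, 800))
            exons.append(GenomicInterval(chrom, pos, pos + elen))
            pos += elen
            if j < n_ex - 1:
                pos += int(rng.integers(500, 1200))
        body = GenomicInterval(chrom, exons[0].start, exons[-1].end)
        genes.append(
            GeneModel(f"SYNG{i:05d}", f"Gene{i:04d}", tuple(exons), body)
        )
        cursors[chrom] = body.end
        # first exon hosts in-exon TEs; second exon's 3' junction hosts a
        # boundary TE; introns host from 300 bp in (clear of boundary TEs)
        exon_hosts.append(
            _Host(chrom, exons[0].start + 10, exons[0].end - 40 - _TE_SPACING)
        )
        if n_ex >= 2:
            boundary_hosts.append(_Host(chrom, exons[0].end - 40, exons[0].end + 100))
        for a, b in zip(exons, exons[1:]):
            intron_hosts.append(_Host(chrom, a.end + 300, b.start - 10))

    # overflow field for intergenic copies, then a feature-free desert
    te_fields: List[_Host] = []
    deserts: Dict[str, Tuple[int, int]] = {}
    chrom_sizes: Dict[str, int] = {}
    n_total = spec.n_te_subtypes * spec.copies_per_subtype
    for c in _CHROMS:
        f0 = cursors[c] + 5_000
        f1 = f0 + max(50_000, n_total * 400)
        te_fields.append(_Host(c, f0, f1))
        deserts[c] = (f1 + 10_000, f1 + 30_000)
        chrom_sizes[c] = f1 + 60_000

    pools = {
        "intergenic": gap_hosts + te_fields,
        "in_intron": intron_hosts,
        "in_exon": exon_hosts,
        "exon_boundary": boundary_hosts,
    }
    # weighted cycle, but the first four copies cover each scenario once
    pattern = (
        list(SCENARIOS)
        + ["intergenic"] * 4 + ["in_intron"] * 3 + ["in_exon", "exon_boundary"]
    )
    tes: List[TECopy] = []
    scenarios: List[str] = []
    for k in range(n_total):
        subtype_ix = k % spec.n_te_subtypes
        cls = _TE_CLASSES[subtype_ix % len(_TE_CLASSES)]
        subtype = f"{cls}_syn{subtype_ix:03d}"
        scenario = pattern[k % len(pattern)] if k < 4 else pattern[4 + (k - 4) % (len(pattern) - 4)]
        length = int(rng.integers(80, 141))
        placed = _place_in(pools[scenario], length)
        if placed is None:
            scenario = "intergenic"
            placed = _place_in(pools["intergenic"], length)
        if placed is None:
            raise RuntimeError("ran out of room placing TE copies; enlarge the layout")
        chrom, s, e = placed
        tes.append(TECopy(GenomicInterval(chrom, s, e), subtype, cls))
        scenarios.append(scenario)
    return SyntheticAnnotation(genes, tes, scenarios, chrom_sizes, deserts)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _make_barcodes(rng: np.random.Generator, n: int, length: int = 12) -> List[str]:
    out: Set[str] = set()
    while len(out) < n:
        out.add(_random_seq(rng, length))
    return sorted(out)


def simulate_reads(
    spec: FixtureSpec,
    ann: SyntheticAnnotation,
    sam_path: Union[str, Path],
) -> pd.DataFrame:
    """Write a SAM file of simulated reads; return the read table.

    The table has one row per record: read_name, barcode, umi, chrom,
    blocks (tuple of (start, end)), source category, and ``kept`` (False
    for the injected QC records a counter must skip).
    """
    rng = np.random.default_rng(spec.seed + 1)
    barcodes = _make_barcodes(rng, spec.n_cells)
    umis = lambda: _random_seq(rng, 12)  # noqa: E731

    introns = [iv for iv in ann.introns() if iv.length >= 150]
    spliceable = [g for g in ann.genes if len(g.exons) >= 2]
    serial = itertools.count()
    rows: List[dict] = []

    p_te = spec.te_read_fraction
    p_in = spec.intronic_read_fraction
    p_ig = spec.intergenic_read_fraction
    p_amb = spec.ambiguous_read_fraction
    p_ex = max(0.0, 1.0 - p_te - p_in - p_ig - p_amb)
    cats = ("te", "intron", "intergenic", "ambiguous", "exon")
    probs = np.array([p_te, p_in, p_ig, p_amb, p_ex])
    probs = probs / probs.sum()

    def new_read(bc: str) -> dict:
        cat = cats[rng.choice(len(cats), p=probs)]
        rlen = int(rng.integers(50, _MAX_READ + 1))
        if cat == "exon" and spliceable and rng.random() < spec.spliced_fraction:
            g = spliceable[int(rng.integers(len(spliceable)))]
            exs = sorted(g.exons)
            i = int(rng.integers(len(exs) - 1))
            l1 = int(rng.integers(20, 41))
            l2 = int(rng.integers(20, 41))
            blocks = (
                (exs[i].end - l1, exs[i].end),
                (exs[i + 1].start, exs[i + 1].start + l2),
            )
            chrom, cat = g.body.chrom, "spliced"
        elif cat == "exon":
            g = ann.genes[int(rng.integers(len(ann.genes)))]
            ex = g.exons[int(rng.integers(len(g.exons)))]
            start = int(rng.integers(ex.start, ex.end - rlen + 1))
            blocks, chrom = ((start, start + rlen),), ex.chrom
        elif cat == "intron":
            iv = introns[int(rng.integers(len(introns)))]
            rl = min(rlen, iv.length - 10)
            start = int(rng.integers(iv.start + 5, iv.end - rl - 4))
            blocks, chrom = ((start, start + rl),), iv.chrom
        elif cat == "te":
            te = ann.tes[int(rng.integers(len(ann.tes)))]
            iv = te.interval
            rl = min(rlen, iv.length - 10)
            start = int(rng.integers(iv.start, iv.end - rl + 1))
            blocks, chrom = ((start, start + rl),), iv.chrom
        elif cat == "ambiguous":
            # straddle the 5' edge of a TE copy into its host context
            te = ann.tes[int(rng.integers(len(ann.tes)))]
            iv = te.interval
            shift = int(rng.integers(5, 31))
            start = iv.start - shift
            blocks, chrom = ((start, start + rlen),), iv.chrom
        else:  # intergenic desert
            chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
            d0, d1 = ann.deserts[chrom]
            start = int(rng.integers(d0, d1 - rlen))
            blocks = ((start, start + rlen),)
        return {
            "barcode": bc,
            "umi": umis(),
            "chrom": chrom,
            "blocks": blocks,
            "source": cat,
        }

    for bc in barcodes:
        cell_reads: List[dict] = []
        for _ in range(spec.reads_per_cell):
            if cell_reads and rng.random() < spec.duplicate_rate:
                row = dict(cell_reads[int(rng.integers(len(cell_reads)))])
                row["source"] = "duplicate"
            else:
                row = new_read(bc)
            row = dict(row, read_name=f"r{next(serial):08d}", kept=True)
            cell_reads.append(row)
            rows.append(row)

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ann.chrom_sizes[c]} for c in _CHROMS],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        hdr = out.header
        for row in rows:
            out.write(_segment(hdr, row, rng))
        if spec.include_qc_records:
            for row in _qc_records(hdr, barcodes[0], ann, serial):
                rows.append(row[1])
                out.write(row[0])
    return pd.DataFrame(rows)


def _segment(hdr: pysam.AlignmentHeader, row: dict, rng: np.random.Generator):
    a = pysam.AlignedSegment(hdr)
    a.query_name = row["read_name"]
    a.flag = 0
    a.reference_id = hdr.get_tid(row["chrom"])
    blocks = row["blocks"]
    a.reference_start = blocks[0][0]
    a.mapping_quality = int(rng.choice((0, 255)))  # MAPQ 0 = multimapper, kept
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i:
            cig.append((3, s - blocks[i - 1][1]))  # N: splice gap
        cig.append((0, e - s))
    a.cigartuples = cig
    a.query_sequence = "A" * sum(e - s for s, e in blocks)
    tags = [("CR", row["barcode"])]
    if row["umi"] is not None:
        tags.append(("UR", row["umi"]))
    a.set_tags(tags)
    return a


def _qc_records(hdr, barcode: str, ann: SyntheticAnnotation, serial):
    """Records a counter must skip: unmapped, secondary, missing CR."""
    out = []
    g = ann.genes[0]
    ex = g.exons[0]

    um = pysam.AlignedSegment(hdr)
    um.query_name = f"r{next(serial):08d}"
    um.flag = 4
    um.query_sequence = "A" * 50
    um.set_tags([("CR", barcode), ("UR", "A" * 12)])
    out.append((um, {"read_name": um.query_name, "kept": False, "source": "qc:unmapped"}))

    sec = pysam.AlignedSegment(hdr)
    sec.query_name = f"r{next(serial):08d}"
    sec.flag = 256
    sec.reference_id = hdr.get_tid(ex.chrom)
    sec.reference_start = ex.start
    sec.cigartuples = [(0, 50)]
    sec.query_sequence = None
    sec.set_tags([("CR", barcode), ("UR", "C" * 12)])
    out.append((sec, {"read_name": sec.query_name, "kept": False, "source": "qc:secondary"}))

    nocb = pysam.AlignedSegment(hdr)
    nocb.query_name = f"r{next(serial):08d}"
    nocb.flag = 0
    nocb.reference_id = hdr.get_tid(ex.chrom)
    nocb.reference_start = ex.start + 5
    nocb.cigartuples = [(0, 50)]
    nocb.query_sequence = "A" * 50
    nocb.set_tags([("UR", "G" * 12)])
    out.append((nocb, {"read_name": nocb.query_name, "kept": False, "source": "qc:missing_barcode"}))
    return out


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_top(bases: Dict, ) -> object:
    ranked = sorted(bases.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[0][0]


class OracleScanner:
    """Index-free reference assigner: full scan over every interval.

    With ``per_copy=True`` TE features are (subtype, copy index) pairs
    instead of collapsed metagenes, for checking that metagene counts
    equal the sum over copies.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        tes: Sequence[TECopy],
        per_copy: bool = False,
    ):
        self.per_copy = per_copy
        exon_recs = []
        body_recs = []
        te_recs = []
        for g in genes:
            for ex in g.exons:
                exon_recs.append((ex.chrom, ex.start, ex.end, g.gene_name))
            body_recs.append((g.body.chrom, g.body.start, g.body.end, g.gene_name))
        for i, t in enumerate(tes):
            name = (t.subtype, i) if per_copy else t.subtype
            te_recs.append((t.interval.chrom, t.interval.start, t.interval.end, name))
        self._exon = self._tabulate(exon_recs)
        self._body = self._tabulate(body_recs)
        self._te = self._tabulate(te_recs)

    @staticmethod
    def _tabulate(recs):
        by_chrom: Dict[str, dict] = {}
        for chrom, s, e, name in recs:
            by_chrom.setdefault(chrom, {"s": [], "e": [], "names": [], "fid": {}, "id": []})
            ent = by_chrom[chrom]
            fid = ent["fid"].setdefault(name, len(ent["names"]))
            if fid == len(ent["names"]):
                ent["names"].append(name)
            ent["s"].append(s)
            ent["e"].append(e)
            ent["id"].append(fid)
        return {
            c: (
                np.asarray(ent["s"], dtype=np.int64),
                np.asarray(ent["e"], dtype=np.int64),
                np.asarray(ent["id"], dtype=np.intp),
                ent["names"],
            )
            for c, ent in by_chrom.items()
        }

    def _bases(self, table, chrom: str, blocks) -> Dict:
        ent = table.get(chrom)
        if ent is None:
            return {}
        starts, ends, fid, names = ent
        ov = np.zeros(len(starts))
        for s, e in blocks:
            ov += np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None)
        per_feat = np.bincount(fid, weights=ov, minlength=len(names))
        return {names[i]: int(per_feat[i]) for i in np.flatnonzero(per_feat)}

    def assign(self, chrom: str, blocks, mode: AssignmentMode) -> List[Assignment]:
        """Assign raw (start, end) blocks on ``chrom`` under ``mode``."""
        gene_bases = self._bases(self._exon, chrom, blocks)
        te_bases = self._bases(self._te, chrom, blocks)
        if mode is AssignmentMode.GENE_PRIORITY:
            if gene_bases:
                return [Assignment.gene(_oracle_top(gene_bases))]
            if te_bases:
                return [self._te_assignment(te_bases)]
            return [Assignment.unassigned()]
        if mode is AssignmentMode.DUAL:
            out = []
            if gene_bases:
                out.append(Assignment.gene(_oracle_top(gene_bases)))
            if te_bases:
                out.append(self._te_assignment(te_bases))
            return out or [Assignment.unassigned()]
        if mode is AssignmentMode.NOINTRONIC:
            if gene_bases:
                return [Assignment.gene(_oracle_top(gene_bases))]
            if self._bases(self._body, chrom, blocks):
                return [Assignment.unassigned()]
            if te_bases:
                return [self._te_assignment(te_bases)]
            return [Assignment.unassigned()]
        raise ValueError(f"unknown mode {mode!r}")

    def _te_assignment(self, te_bases: Dict) -> Assignment:
        top = _oracle_top(te_bases)
        if self.per_copy:
            subtype, i = top
            return Assignment.te(f"{subtype}|copy{i}")
        return Assignment.te(top)


def oracle_assign(
    blocks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    tes: Sequence[TECopy],
    mode: AssignmentMode,
) -> List[Assignment]:
    """One-shot oracle assignment for interval blocks (tiny inputs)."""
    scanner = OracleScanner(genes, tes)
    raw = [(b.start, b.end) for b in blocks]
    return scanner.assign(blocks[0].chrom, raw, mode)


def oracle_count(
    sam_path: Union[str, Path],
    genes: Sequence[GeneModel],
    tes: Sequence[TECopy],
    mode: AssignmentMode,
    umi_enabled: bool,
    positional_dedup: bool = False,
    filename_barcode: Optional[str] = None,
    per_copy: bool = False,
) -> CountMatrix:
    """Naive end-to-end recount of a SAM file, independent of the
    pipeline: linear-scan assignment, set-based dedup, dict counting.
    """
    scanner = OracleScanner(genes, tes, per_copy=per_copy)
    gene_feats = sorted({g.gene_name for g in genes})
    if per_copy:
        te_feats = sorted(f"{t.subtype}|copy{i}" for i, t in enumerate(tes))
    else:
        te_feats = sorted({t.subtype for t in tes})
    features = gene_feats + te_feats
    feat_ix = {f: j for j, f in enumerate(features)}

    counts: Dict[Tuple[str, int], int] = {}
    triples: Set[Tuple[str, int, str]] = set()
    positions: Set[Tuple[str, str, int]] = set()
    cells: Set[str] = set()

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if filename_barcode is not None:
                bc = filename_barcode
            elif rec.has_tag("CR"):
                bc = rec.get_tag("CR")
            else:
                continue
            umi = None
            if umi_enabled:
                if not rec.has_tag("UR"):
                    continue
                umi = rec.get_tag("UR")
            blocks = [(s, e) for s, e in rec.get_blocks() if e > s]
            if not blocks:
                continue
            chrom = rec.reference_name
            if positional_dedup:
                key = (bc, chrom, blocks[0][0])
                if key in positions:
                    continue
                positions.add(key)
            cells.add(bc)
            for a in scanner.assign(chrom, blocks, mode):
                if a.feature is None:
                    continue
                j = feat_ix[a.feature]
                if umi_enabled:
                    trip = (bc, j, umi)
                    if trip in triples:
                        continue
                    triples.add(trip)
                counts[(bc, j)] = counts.get((bc, j), 0) + 1

    barcodes = sorted(cells)
    import scipy.sparse as sp

    mat = sp.dok_matrix((len(barcodes), len(features)), dtype=np.int64)
    row_ix = {b: i for i, b in enumerate(barcodes)}
    for (bc, j), c in counts.items():
        mat[row_ix[bc], j] = c
    return CountMatrix(barcodes, features, mat.tocsr())


# ---------------------------------------------------------------------------
# rare-population fixture
# ---------------------------------------------------------------------------


def make_rare_population_fixture(
    sam_path: Union[str, Path],
    n_cells: int = 2000,
    marker_fraction: float = 0.01,
    reads_per_cell: int = 20,
    marker_reads: int = 6,
    seed: int = 0,
    marker_subtype: str = "MERVL-int",
):
    """A cell mixture in which a small subpopulation expresses a marker TE.

    Mirrors the MERVL/2C-like situation: ``marker_fraction`` of the
    cells draw ``marker_reads`` of their reads from copies of
    ``marker_subtype``; no other cell touches that subtype. Returns
    (annotation, marker barcodes).
    """
    spec = FixtureSpec(
        n_genes=12,
        n_te_subtypes=8,
        copies_per_subtype=5,
        seed=seed,
        include_qc_records=False,
    )
    ann = make_annotation(spec)
    # marker copies live beyond the desert, clear of everything else
    marker_copies = []
    for i in range(4):
        c = _CHROMS[i % 2]
        d1 = ann.deserts[c][1]
        s = d1 + 5_000 + i * 1_000
        marker_copies.append(TECopy(GenomicInterval(c, s, s + 500), marker_subtype, "LTR"))
    ann.tes.extend(marker_copies)
    ann.scenarios.extend(["intergenic"] * len(marker_copies))
    for c in _CHROMS:
        ann.chrom_sizes[c] += 20_000

    rng = np.random.default_rng(seed + 7)
    barcodes = _make_barcodes(rng, n_cells)
    n_marker = max(1, round(n_cells * marker_fraction))
    marker_cells = set(barcodes[:n_marker])

    non_marker_tes = [t for t in ann.tes if t.subtype != marker_subtype]
    serial = itertools.count()
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ann.chrom_sizes[c]} for c in _CHROMS],
    }

    def generic_read(bc):
        if rng.random() < 0.25:
            te = non_marker_tes[int(rng.integers(len(non_marker_tes)))]
            iv = te.interval
            rl = min(70, iv.length - 10)
        else:
            g = ann.genes[int(rng.integers(len(ann.genes)))]
            iv = g.exons[int(rng.integers(len(g.exons)))]
            rl = 70
        start = int(rng.integers(iv.start, iv.end - rl + 1))
        return {
            "read_name": f"m{next(serial):08d}",
            "barcode": bc,
            "umi": _random_seq(rng, 12),
            "chrom": iv.chrom,
            "blocks": ((start, start + rl),),
        }

    def marker_read(bc):
        te = marker_copies[int(rng.integers(len(marker_copies)))]
        iv = te.interval
        start = int(rng.integers(iv.start, iv.end - 70 + 1))
        return {
            "read_name": f"m{next(serial):08d}",
            "barcode": bc,
            "umi": _random_seq(rng, 12),
            "chrom": iv.chrom,
            "blocks": ((start, start + 70),),
        }

    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        hdr = out.header
        for bc in barcodes:
            n_mk = marker_reads if bc in marker_cells else 0
            for r in range(reads_per_cell):
                row = marker_read(bc) if r < n_mk else generic_read(bc)
                out.write(_segment(hdr, row, rng))
    return ann, sorted(marker_cells)
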