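"""Sparse cell x feature count matrix: accumulation, filtering, I/O.

Counting is UMI-aware: with UMIs enabled, a cell-feature count is the
number of distinct (barcode, feature, UMI) triples, which collapses PCR
duplicates; without UMIs it is the number of assigned reads. Cell rows
are kept in sorted barcode order so the matrix is invariant to input
read order.
"""
from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .models import Assignment, Category, CellFilterParams


class CountMatrix:
    """Cells (rows) x features (columns) integer counts.

    ``features`` follows the index catalog order (genes, then TE
    subtypes); ``feature_types`` optionally labels each column GENE/TE.
    """

    def __init__(
        self,
        barcodes: Sequence[str],
        features: Sequence[str],
        counts: sp.spmatrix,
        feature_types: Optional[Sequence[str]] = None,
    ):
        self.barcodes: List[str] = list(barcodes)
        self.features: List[str] = list(features)
        self.counts: sp.csr_matrix = sp.csr_matrix(counts, dtype=np.int64)
        self.feature_types: Optional[List[str]] = (
            list(feature_types) if feature_types is not None else None
        )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    # -- summaries ---------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape

    def total_counts(self) -> np.ndarray:
        """Total counts per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def detected_features(self) -> np.ndarray:
        """Number of nonzero features per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.barcodes, columns=self.features
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.barcodes == other.barcodes
            and self.features == other.features
            and (self.counts != other.counts).nnz == 0
        )

    def __repr__(self) -> str:
        return f"CountMatrix({len(self.barcodes)} cells x {len(self.features)} features)"


def accumulate(
    records: Iterable[Tuple[str, Optional[str], Assignment]],
    features: Sequence[str],
    umi_enabled: bool,
    all_barcodes: Optional[Iterable[str]] = None,
    feature_types: Optional[Sequence[str]] = None,
) -> CountMatrix:
    """Fold (barcode, umi, assignment) records into a count matrix.

    Records must exclude UNASSIGNED (the caller drops and tallies
    those). ``all_barcodes`` optionally forces rows for cells observed
    in the input even if none of their reads were assigned.
    """
    feat_ix: Dict[str, int] = {f: i for i, f in enumerate(features)}
    cells: Set[str] = set(all_barcodes) if all_barcodes is not None else set()
    pair_counts: Dict[Tuple[str, int], int] = {}
    seen_triples: Set[Tuple[str, int, str]] = set()

    for barcode, umi, assignment in records:
        if assignment.category is Category.UNASSIGNED:
            raise ValueError("UNASSIGNED records must be dropped before accumulate")
        cells.add(barcode)
        j = feat_ix[assignment.feature]
        if umi_enabled:
            key = (barcode, j, umi or "")
            if key in seen_triples:
                continue
            seen_triples.add(key)
        pair = (barcode, j)
        pair_counts[pair] = pair_counts.get(pair, 0) + 1

    barcodes = sorted(cells)
    row_ix = {b: i for i, b in enumerate(barcodes)}
    if pair_counts:
        rows, cols, data = zip(
            *(((row_ix[b], j, c)) for (b, j), c in pair_counts.items())
        )
    else:
        rows = cols = data = ()
    counts = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(barcodes), len(features)), dtype=np.int64
    ).tocsr()
    return CountMatrix(barcodes, features, counts, feature_types)


def filter_cells(matrix: CountMatrix, params: CellFilterParams) -> CountMatrix:
    """Apply cell-quality filtering.

    A cell is removed when it fails the total-count or detected-feature
    threshold (both thresholds must fail when ``params.combine == "and"``).
    Of the survivors, the ``expect_cells`` cells with the most detected
    features are kept, ties broken by total counts then barcode order.
    Columns are untouched.
    """
    totals = matrix.total_counts()
    detected = matrix.detected_features()
    fail_count = totals < params.min_count
    fail_genes = detected < params.min_genes
    removed = (
        fail_count | fail_genes if params.combine == "or" else fail_count & fail_genes
    )
    survivors = np.flatnonzero(~removed)
    if len(survivors) > params.expect_cells:
        order = sorted(
            survivors, key=lambda i: (-detected[i], -totals[i], i)
        )
        survivors = np.array(sorted(order[: params.expect_cells]), dtype=int)
    kept = [matrix.barcodes[i] for i in survivors]
    return CountMatrix(
        kept, matrix.features, matrix.counts[survivors, :], matrix.feature_types
    )


def filter_features(matrix: CountMatrix, min_total: int) -> CountMatrix:
    """Drop feature columns whose grand total is below ``min_total``."""
    if min_total <= 0:
        return matrix
    col_totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    keep = np.flatnonzero(col_totals >= min_total)
    return CountMatrix(
        matrix.barcodes,
        [matrix.features[j] for j in keep],
        matrix.counts[:, keep],
        [matrix.feature_types[j] for j in keep] if matrix.feature_types else None,
    )


SUPPORTED_FORMATS = ("csv", "mtx")


def write_matrix(matrix: CountMatrix, path: Union[str, Path], format: str = "csv") -> None:
    """Write the matrix as dense CSV or MatrixMarket triplets.

    CSV: one file, cells as rows, features as columns. MTX: ``path`` is
    a directory receiving matrix.mtx, barcodes.tsv and features.tsv
    (feature name, tab, GENE/TE category when known).
    """
    path = Path(path)
    if format == "csv":
        matrix.to_frame().to_csv(path)
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), matrix.counts.tocoo())
        (path / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
        types = matrix.feature_types or [""] * len(matrix.features)
        (path / "features.tsv").write_text(
            "".join(
                f"{f}\t{t}\n" if t else f"{f}\n"
                for f, t in zip(matrix.features, types)
            )
        )
    else:
        raise ValueError(
            f"unknown format {format!r}; supported formats: {', '.join(SUPPORTED_FORMATS)}"
        )


def read_matrix(path: Union[str, Path], format: Optional[str] = None) -> CountMatrix:
    """Read a matrix written by :func:`write_matrix` (format inferred)."""
    path = Path(path)
    if format is None:
        format = "mtx" if path.is_dir() else "csv"
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            [str(b) for b in df.index],
            [str(f) for f in df.columns],
            sp.csr_matrix(df.to_numpy(dtype=np.int64)),
        )
    if format == "mtx":
        counts = sp.csr_matrix(scipy.io.mmread(str(path / "matrix.mtx")))
        barcodes = (path / "barcodes.tsv").read_text().splitlines()
        feat_lines = (path / "features.tsv").read_text().splitlines()
        feats = [l.split("\t")[0] for l in feat_lines]
        types = [l.split("\t")[1] if "\t" in l else "" for l in feat_lines]
        ftypes = types if any(types) else None
        return CountMatrix(barcodes, feats, counts, ftypes)
    raise ValueError(
        f"unknown format {format!r}; supported formats: {', '.join(SUPPORTED_FORMATS)}"
    )
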