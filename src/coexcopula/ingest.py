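"""Reading, filtering and splitting of gene x cell count matrices.

Count matrices are unnormalized transcript counts with genes in rows and
cells in columns. Two on-disk layouts are supported: Matrix Market
coordinate triplets with one-ID-per-line gene/barcode sidecar files (the
common cellranger layout), and dense delimited text with gene IDs in the
first column and cell IDs in the header row.

Normalization here exists only to rank genes (HVG selection) and to build
PC embeddings downstream; copulas are always fit on the raw counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.io import mmread, mmwrite
from scipy import sparse


class FormatError(ValueError):
    """Input file does not match its declared layout."""


class EmptyResultError(ValueError):
    """A filtering step removed every gene."""


@dataclass
class CountMatrix:
    """Integer gene x cell transcript count matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    cell_ids : list of str
        Unique cell barcodes, one per column.
    counts : ndarray of shape (m, n)
        Nonnegative integer counts.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        m, n = self.counts.shape
        if m < 1 or n < 2:
            raise ValueError(f"need at least 1 gene and 2 cells, got {m}x{n}")
        if len(self.gene_ids) != m:
            raise FormatError(f"{len(self.gene_ids)} gene IDs for {m} rows")
        if len(self.cell_ids) != n:
            raise FormatError(f"{len(self.cell_ids)} cell IDs for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene IDs must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell IDs must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            [self.gene_ids[i] for i in index], list(self.cell_ids), self.counts[index]
        )

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            list(self.gene_ids), [self.cell_ids[i] for i in index], self.counts[:, index]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SplitPlan:
    """A reproducible collection of half-splits of cells.

    ``splits`` is a list of ``(train_idx, test_idx)`` integer-array pairs;
    within each pair the two sets are disjoint, cover all cells, and their
    sizes differ by at most one.
    """

    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def _read_id_file(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip() != ""]


def read_counts_mtx(matrix_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a Matrix Market triplet file with gene/barcode sidecars."""
    try:
        mat = mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    if not np.issubdtype(mat.dtype, np.integer):
        dense_check = mat.data
        if not np.all(dense_check == np.floor(dense_check)):
            raise ValueError("matrix contains non-integer values")
    if mat.data.size and mat.data.min() < 0:
        raise ValueError("matrix contains negative values")
    genes = _read_id_file(genes_path)
    cells = _read_id_file(barcodes_path)
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"genes file has {len(genes)} entries but header declares {mat.shape[0]} rows"
        )
    if len(cells) != mat.shape[1]:
        raise FormatError(
            f"barcodes file has {len(cells)} entries but header declares {mat.shape[1]} columns"
        )
    return CountMatrix(genes, cells, np.asarray(mat.todense()).astype(np.int64))


def write_counts_mtx(cm: CountMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write MTX triplets plus one-ID-per-line sidecars."""
    target = io.BytesIO()
    mmwrite(target, sparse.coo_matrix(cm.counts), field="integer")
    with open(matrix_path, "wb") as fh:
        fh.write(target.getvalue())
    for path, ids in ((genes_path, cm.gene_ids), (barcodes_path, cm.cell_ids)):
        with open(path, "w") as fh:
            fh.write("\n".join(ids) + "\n")


def read_counts_dense(path, delimiter: str = ",") -> CountMatrix:
    """Read a dense table: header row of cell IDs, first column gene IDs."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError("dense table has no data rows")
    header = lines[0].split(delimiter)
    cell_ids = header[1:]
    width = len(header)
    gene_ids: list[str] = []
    rows = []
    for ln in lines[1:]:
        parts = ln.split(delimiter)
        if len(parts) != width:
            raise FormatError(f"ragged row: expected {width} fields, got {len(parts)}")
        gene_ids.append(parts[0])
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"non-numeric count in row {parts[0]!r}") from exc
        if any(v != int(v) for v in vals):
            raise ValueError(f"fractional count in row {parts[0]!r}")
        rows.append([int(v) for v in vals])
    return CountMatrix(gene_ids, cell_ids, np.array(rows, dtype=np.int64))


def write_counts_dense(cm: CountMatrix, path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["gene"] + list(cm.cell_ids)) + "\n")
        for gid, row in zip(cm.gene_ids, cm.counts):
            fh.write(delimiter.join([gid] + [str(int(v)) for v in row]) + "\n")


def filter_genes(cm: CountMatrix, min_expr_frac: float) -> CountMatrix:
    """Drop genes expressed in fewer than ``min_expr_frac`` of cells.

    A gene is kept when its fraction of cells with count > 0 is at least
    ``min_expr_frac``; at threshold 0 only all-zero genes are removed
    (a gene must have strictly more than zero expressing cells).
    """
    if not 0 <= min_expr_frac <= 1:
        raise ValueError("min_expr_frac must be in [0, 1]")
    frac = (cm.counts > 0).mean(axis=1)
    keep = (frac >= min_expr_frac) & (frac > 0)
    if not keep.any():
        raise EmptyResultError("filtering removed every gene")
    return cm.subset_genes(np.flatnonzero(keep))


def drop_empty_cells(cm: CountMatrix) -> CountMatrix:
    """Remove cells with zero total count (they have no expression profile)."""
    keep = np.flatnonzero(cm.counts.sum(axis=0) > 0)
    if keep.size == cm.n_cells:
        return cm
    return cm.subset_cells(keep)


def log_normalize(cm: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """log1p of library-size-scaled counts: log(1 + scale * x / colsum).

    Used for HVG ranking and PC embeddings only; copula estimators consume
    raw counts.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = cm.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total count: {[cm.cell_ids[i] for i in zero]}")
    return np.log1p(scale * cm.counts / totals)


def select_hvgs(cm: CountMatrix, k: int, scale: float = 1e4) -> list[str]:
    """Top-k highly variable genes by residual from a mean-variance trend.

    The trend is a running median of per-gene variance against mean of
    log-normalized expression (window of ~1/3 of genes, so a small block
    of outlying genes cannot set its own trend); genes are ranked by
    variance minus trend, descending, ties broken by input order.
    """
    if k > cm.n_genes:
        raise ValueError(f"k={k} exceeds number of genes {cm.n_genes}")
    logx = log_normalize(cm, scale)
    mean = logx.mean(axis=1)
    var = logx.var(axis=1, ddof=1)
    order = np.argsort(mean, kind="stable")
    window = max(5, cm.n_genes // 3)
    half = window // 2
    trend = np.empty_like(var)
    sorted_var = var[order]
    for pos in range(cm.n_genes):
        lo = max(0, pos - half)
        hi = min(cm.n_genes, pos + half + 1)
        trend[order[pos]] = np.median(sorted_var[lo:hi])
    resid = var - trend
    ranked = np.argsort(-resid, kind="stable")
    return [cm.gene_ids[i] for i in ranked[:k]]


def make_splits(cm: CountMatrix, n_splits: int, seed: int) -> SplitPlan:
    """Random half-splits of cells into train/test, reproducible from seed."""
    n = cm.n_cells
    if n < 4:
        raise ValueError("need at least 4 cells to split")
    if n_splits < 1:
        raise ValueError("n_splits must be positive")
    rng = np.random.default_rng(seed)
    half = n // 2
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:half]), np.sort(perm[half:])))
    return SplitPlan(seed=seed, splits=splits)
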