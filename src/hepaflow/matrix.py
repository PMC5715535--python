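"""Expression-matrix container and TSV / MatrixMarket round-trip I/O.

The unit of expression throughout the package is FPKM (fragments per
kilobase of exon model per million mapped reads); "detected" conventionally
means FPKM > 1.  Matrices are stored genes x cells.  ERCC spike-in control
rows are flagged by a boolean mask and, on disk, by the ``ERCC-`` id prefix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

SPIKEIN_PREFIX = "ERCC-"


@dataclass
class ExpressionMatrix:
    """Genes x cells FPKM matrix with unique string identifiers.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative FPKM values; index = gene ids, columns = cell ids.
    spikein_mask : numpy.ndarray of bool
        One flag per gene row; True marks an ERCC spike-in control row.
        If omitted, rows whose id starts with ``ERCC-`` are flagged.
    """

    values: pd.DataFrame
    spikein_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spikein_mask is None:
            self.spikein_mask = np.array(
                [str(g).startswith(SPIKEIN_PREFIX) for g in self.values.index],
                dtype=bool,
            )
        else:
            self.spikein_mask = np.asarray(self.spikein_mask, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate cell id: {dup!r}")
        if len(self.spikein_mask) != len(idx):
            raise ValueError("spike-in mask length must equal gene count")
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value at gene {idx[i]!r}, cell {cols[j]!r}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_cells(self) -> int:
        return len(self.values.columns)

    def biological(self) -> "ExpressionMatrix":
        """Matrix restricted to non-spike-in gene rows."""
        keep = ~self.spikein_mask
        return ExpressionMatrix(self.values.loc[keep], self.spikein_mask[keep])

    def spikeins(self) -> "ExpressionMatrix":
        """Matrix restricted to spike-in control rows."""
        keep = self.spikein_mask
        return ExpressionMatrix(self.values.loc[keep], self.spikein_mask[keep])

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(cell_ids)], self.spikein_mask.copy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        sub = self.values.loc[list(gene_ids)]
        mask = self.spikein_mask[self.values.index.get_indexer(sub.index)]
        return ExpressionMatrix(sub, mask)

    def log2p1(self) -> pd.DataFrame:
        """log2(FPKM + 1) transform used for all correlation and clustering."""
        return np.log2(self.values + 1.0)

    def detected_gene_counts(self, threshold: float = 1.0) -> pd.Series:
        """Per-cell number of biological genes with FPKM > threshold."""
        bio = self.values.loc[~self.spikein_mask]
        return (bio > threshold).sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.array_equal(self.values.to_numpy(), other.values.to_numpy())
            and np.array_equal(self.spikein_mask, other.spikein_mask)
        )


def read_matrix(path: str, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV or MatrixMarket.

    TSV layout: header row of cell ids, first column gene ids.
    MatrixMarket layout: ``<path>`` is the ``.mtx`` file; row and column
    identifiers live beside it in ``<stem>_rows.txt`` / ``<stem>_cols.txt``.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem, _ = os.path.splitext(path)
        genes = _read_id_file(stem + "_rows.txt")
        cells = _read_id_file(stem + "_cols.txt")
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
        return ExpressionMatrix(df)
    raise ValueError(f"unknown matrix format: {format!r}")


def write_matrix(matrix: ExpressionMatrix, path: str, format: str = "tsv") -> None:
    """Write an expression matrix; inverse of :func:`read_matrix`."""
    if format == "tsv":
        matrix.values.to_csv(path, sep="\t")
        return
    if format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(matrix.values.to_numpy()))
        stem, _ = os.path.splitext(path)
        _write_id_file(stem + "_rows.txt", matrix.genes)
        _write_id_file(stem + "_cols.txt", matrix.cells)
        return
    raise ValueError(f"unknown matrix format: {format!r}")


def _read_id_file(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_id_file(path: str, ids) -> None:
    with open(path, "w") as fh:
        for name in ids:
            fh.write(f"{name}\n")
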