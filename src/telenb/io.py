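"""Count-matrix I/O and quality-control filtering.

Matrices are genes x cells with integer entries.  Supported formats:
MatrixMarket (``.mtx`` with ``<stem>_genes.tsv`` / ``<stem>_cells.tsv``
label sidecars) and dense CSV (genes as rows, first column gene labels,
header row of cell labels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

__all__ = ["CountMatrix", "read_counts", "write_counts", "qc_filter"]


@dataclass
class CountMatrix:
    values: np.ndarray
    genes: list[str]
    cells: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x cells)")
        if not np.issubdtype(self.values.dtype, np.integer):
            bad = np.argwhere(self.values != np.floor(self.values))
            if bad.size:
                g, c = bad[0]
                raise ValueError(
                    f"non-integer entry at gene {self.genes[g]!r}, cell {self.cells[c]!r}"
                )
            self.values = self.values.astype(np.int64)
        if np.any(self.values < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.genes) != self.values.shape[0] or len(self.cells) != self.values.shape[1]:
            raise ValueError("label lengths must match matrix dimensions")
        self.genes = list(self.genes)
        self.cells = list(self.cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def totals_per_cell(self) -> np.ndarray:
        return self.values.sum(axis=0)


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_genes.tsv"), Path(f"{stem}_cells.tsv")


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Read a count matrix; format inferred from the extension if omitted."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        gpath, cpath = _sidecars(path)
        for p in (path, gpath, cpath):
            if not p.exists():
                raise FileNotFoundError(f"missing {p}")
        mat = sio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        if not np.allclose(mat, np.round(mat)):
            raise ValueError(f"{path}: matrix contains non-integer entries")
        genes = pd.read_csv(gpath, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cpath, sep="\t", header=None)[0].astype(str).tolist()
        if len(genes) != mat.shape[0] or len(cells) != mat.shape[1]:
            raise ValueError(
                f"label counts ({len(genes)} genes, {len(cells)} cells) do not "
                f"match matrix shape {mat.shape}"
            )
        return CountMatrix(np.asarray(np.round(mat), dtype=np.int64), genes, cells)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(df.to_numpy(), df.index.astype(str).tolist(),
                           df.columns.astype(str).tolist())
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(matrix: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a count matrix losslessly (integers preserved exactly)."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        sio.mmwrite(path, sparse.coo_matrix(matrix.values), field="integer")
        gpath, cpath = _sidecars(path)
        pd.Series(matrix.genes).to_csv(gpath, sep="\t", index=False, header=False)
        pd.Series(matrix.cells).to_csv(cpath, sep="\t", index=False, header=False)
        return
    if fmt == "csv":
        pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.cells).to_csv(path)
        return
    raise ValueError(f"unknown format {fmt!r}")


def qc_filter(matrix: CountMatrix, min_gene_fraction_per_cell: float = 0.30,
              min_cell_fraction_per_gene: float = 0.01):
    """Standard QC: drop cells expressing fewer than 30% of genes, then drop
    genes expressed in fewer than 1% of the *surviving* cells.

    Returns the filtered matrix and a report dict.  Cells are filtered
    first so gene prevalence is measured on retained cells.
    """
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    nonzero = matrix.values > 0
    cell_frac = nonzero.mean(axis=0)
    keep_cells = cell_frac >= min_gene_fraction_per_cell
    if not keep_cells.any():
        raise ValueError("QC removed every cell")
    gene_frac = nonzero[:, keep_cells].mean(axis=1)
    keep_genes = gene_frac >= min_cell_fraction_per_gene
    out = CountMatrix(
        matrix.values[np.ix_(keep_genes, keep_cells)],
        [g for g, k in zip(matrix.genes, keep_genes) if k],
        [c for c, k in zip(matrix.cells, keep_cells) if k],
    )
    report = {
        "n_cells_in": len(matrix.cells), "n_cells_removed": int((~keep_cells).sum()),
        "n_genes_in": len(matrix.genes), "n_genes_removed": int((~keep_genes).sum()),
        "n_cells_out": len(out.cells), "n_genes_out": len(out.genes),
    }
    return out, report
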