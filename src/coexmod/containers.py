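"""Core in-memory containers shared across the pipeline.

The central object is :class:`CountMatrix`: a sparse genes x cells matrix of
raw (integer) UMI counts together with gene/cell identifiers and a per-cell
sample-metadata table.  Genes are rows, cells are columns, matching the 10x
on-disk convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: metadata columns every CountMatrix carries for each cell
CELL_META_COLUMNS = (
    "sample_id",
    "condition",
    "stage",
    "timepoint",
    "replicate",
    "experiment",
)


@dataclass
class CountMatrix:
    """Sparse non-negative integer genes x cells count matrix.

    Parameters
    ----------
    counts
        CSR matrix of shape ``(n_genes, n_cells)`` with integer entries >= 0.
    gene_ids
        Unique gene identifiers, length ``n_genes``.
    cell_ids
        Unique cell barcodes, length ``n_cells``.
    cell_meta
        DataFrame indexed by ``cell_ids`` with at least the columns in
        :data:`CELL_META_COLUMNS`.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {g}"
            )
        if len(self.cell_ids) != c:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != matrix columns {c}"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene identifiers are not unique")
        if len(set(self.cell_ids)) != c:
            raise ValueError("cell identifiers are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if self.counts.nnz and not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if len(self.cell_meta) != c:
            raise ValueError("cell_meta rows do not match number of cells")
        if not np.array_equal(np.asarray(self.cell_meta.index, dtype=object),
                              self.cell_ids):
            raise ValueError("cell_meta index must equal cell_ids")

    # -- shapes ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    # -- subsetting -----------------------------------------------------
    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a new CountMatrix keeping cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx].tocsr(),
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        """Return a new CountMatrix keeping genes where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[idx, :].tocsr(),
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
        )

    def cell_totals(self) -> np.ndarray:
        """Total counts per cell (library size), length n_cells."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        """Total counts per gene, length n_genes."""
        return np.asarray(self.counts.sum(axis=1)).ravel()
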