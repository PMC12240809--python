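"""Cell- and gene-level quality-control filters.

Cells are dropped when most of their reads come from their few most
expressed genes (``pct_counts_in_top_20_genes`` >= 25 by default) or when
their total read count is an outlier (median +/- k MADs on log10 totals).
Genes are dropped when expressed in fewer than ``min_cells_per_gene`` cells.
The pipeline always filters cells first, then genes, and records the number
removed under each criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CountMatrix

log = logging.getLogger(__name__)

__all__ = ["QCConfig", "pct_counts_top_n", "filter_cells", "filter_genes",
           "cell_qc_table"]


@dataclass
class QCConfig:
    """Thresholds for the QC filters.

    ``max_pct_top20`` is a strict keep-condition: a cell is kept only when
    the percentage of its counts in its ``n_top_genes`` most expressed genes
    is strictly below the threshold.  ``read_count_outlier_k`` is the MAD
    multiplier of the robust read-depth window; the exact outlier rule for
    read counts is a package decision (median +/- k MAD of log10 totals).
    """

    max_pct_top20: float = 25.0
    min_cells_per_gene: int = 50
    n_top_genes: int = 20
    read_count_outlier_k: float = 5.0

    def validate(self) -> None:
        if not (0.0 < self.max_pct_top20 <= 100.0):
            raise ValueError("max_pct_top20 must be in (0, 100]")
        if self.min_cells_per_gene < 1 or self.n_top_genes < 1:
            raise ValueError("count thresholds must be >= 1")
        if self.read_count_outlier_k <= 0:
            raise ValueError("read_count_outlier_k must be > 0")


def pct_counts_top_n(cell_counts: np.ndarray, n: int) -> float:
    """Percent of a cell's counts carried by its ``n`` most expressed genes.

    Ties at the n-th value are resolved by taking the ``n`` largest values
    regardless of gene identity.
    """
    x = np.asarray(cell_counts, dtype=float).ravel()
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot score an all-zero cell")
    if n >= x.size:
        return 100.0
    top = np.partition(x, -n)[-n:]
    return 100.0 * top.sum() / total


def _pct_top_per_cell(cm: CountMatrix, n: int) -> np.ndarray:
    csc = cm.counts.tocsc()
    out = np.empty(cm.n_cells)
    for j in range(cm.n_cells):
        col = csc.data[csc.indptr[j]:csc.indptr[j + 1]]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"cell {cm.cell_ids[j]!r} has zero counts")
        if col.size <= n:
            out[j] = 100.0
        else:
            out[j] = 100.0 * np.partition(col, -n)[-n:].sum() / total
    return out


def cell_qc_table(cm: CountMatrix, qc: QCConfig):
    """Per-cell QC metrics and pass/fail flags (no filtering applied)."""
    import pandas as pd

    qc.validate()
    totals = cm.cell_totals()
    pct = _pct_top_per_cell(cm, qc.n_top_genes)
    logt = np.log10(np.maximum(totals, 1))
    med = np.median(logt)
    mad = np.median(np.abs(logt - med))
    if mad == 0:
        depth_ok = np.ones(cm.n_cells, dtype=bool)
    else:
        depth_ok = np.abs(logt - med) <= qc.read_count_outlier_k * mad
    top_ok = pct < qc.max_pct_top20
    return pd.DataFrame({
        "total_counts": totals,
        "pct_counts_top_n": pct,
        "pass_pct_top": top_ok,
        "pass_depth": depth_ok,
        "pass": top_ok & depth_ok,
    }, index=pd.Index(cm.cell_ids, name="cell_id"))


def filter_cells(cm: CountMatrix, qc: QCConfig) -> CountMatrix:
    """Drop concentrated-count and read-depth-outlier cells."""
    if cm.n_cells == 0:
        raise ValueError("empty matrix")
    table = cell_qc_table(cm, qc)
    keep = table["pass"].to_numpy()
    n_top = int((~table["pass_pct_top"]).sum())
    n_depth = int((~table["pass_depth"]).sum())
    log.info("filter_cells: %d/%d removed (%d pct-top, %d depth outlier)",
             (~keep).sum(), cm.n_cells, n_top, n_depth)
    if not keep.any():
        raise ValueError(
            "all cells removed by QC; review max_pct_top20 / outlier k"
        )
    return cm.subset_cells(keep)


def filter_genes(cm: CountMatrix, qc: QCConfig) -> CountMatrix:
    """Drop genes expressed (count > 0) in fewer than the minimum cells."""
    if cm.n_genes == 0:
        raise ValueError("empty matrix")
    qc.validate()
    n_expressing = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    keep = n_expressing >= qc.min_cells_per_gene
    log.info("filter_genes: %d/%d removed (< %d expressing cells)",
             (~keep).sum(), cm.n_genes, qc.min_cells_per_gene)
    if not keep.any():
        raise ValueError(
            "all genes removed by QC; review min_cells_per_gene"
        )
    return cm.subset_genes(keep)
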