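"""Cell-state pseudobulking.

Cells are log-CP10K normalized, embedded with PCA, connected in a
k-nearest-neighbour graph and partitioned into small "cell states" (about
10 cells each by default) with Leiden community detection; the Leiden
resolution is auto-tuned by bisection until the mean state size lands in a
window around the target.  Raw counts of the member cells of each state are
then pooled into pseudobulk transcriptomes, which serve as the observations
for downstream co-expression analysis.  Pooling preserves raw counts
exactly, so column sums of the pseudobulk matrix conserve the input totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix

log = logging.getLogger(__name__)

__all__ = [
    "CellStatePartition",
    "PseudobulkMatrix",
    "normalize_log_cp10k",
    "cluster_cell_states",
    "pool_states",
    "pseudobulk_pipeline",
]


@dataclass
class CellStatePartition:
    """Assignment of every cell to exactly one cell state."""

    cell_ids: np.ndarray
    labels: np.ndarray  # int state index per cell
    method_params: dict = field(default_factory=dict)
    warn: bool = False  # True when the size window could not be reached

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("cell_ids and labels length mismatch")
        # relabel to dense 0..n_states-1, all states non-empty by construction
        uniq, dense = np.unique(self.labels, return_inverse=True)
        self.labels = dense
        self._n_states = len(uniq)

    @property
    def n_states(self) -> int:
        return self._n_states

    @property
    def state_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self._n_states)

    @property
    def assignment(self) -> dict:
        return dict(zip(self.cell_ids, (f"state{l}" for l in self.labels)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids,
             "state_id": [f"state{l}" for l in self.labels]}
        )


@dataclass
class PseudobulkMatrix:
    """Pooled raw counts per cell state plus their log-CP10K normalization."""

    pooled_counts: np.ndarray  # genes x states, integer
    norm_expr: np.ndarray      # genes x states, log CP10K
    gene_ids: np.ndarray
    state_ids: np.ndarray
    partition: CellStatePartition

    @property
    def n_states(self) -> int:
        return self.pooled_counts.shape[1]


def normalize_log_cp10k(cm: CountMatrix | sp.spmatrix | np.ndarray) -> np.ndarray:
    """Scale every cell (column) to 10,000 total counts, then log1p.

    Returns a dense genes x cells float matrix.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else sp.csr_matrix(cm)
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if (totals <= 0).any():
        raise ValueError("zero-total cell: run QC before normalizing")
    dense = np.asarray(counts.todense(), dtype=float)
    return np.log1p(dense / totals[None, :] * 1e4)


def _leiden(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def cluster_cell_states(
    norm: np.ndarray,
    cell_ids: np.ndarray | None = None,
    target_state_size: int = 10,
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    size_window: tuple[float, float] = (0.8, 1.2),
    max_bisect: int = 25,
) -> CellStatePartition:
    """Partition cells into ~``target_state_size``-cell states.

    ``norm`` is a genes x cells matrix (log CP10K).  PCA is computed on
    cells; Leiden runs on the kNN graph in PC space with the resolution
    bisected until the mean state size falls inside
    ``size_window x target``.  Deterministic given ``seed``.
    """
    X = np.asarray(norm, dtype=float).T  # cells x features
    n_cells = X.shape[0]
    if n_cells < 2 * target_state_size:
        raise ValueError(
            f"need at least {2 * target_state_size} cells, got {n_cells}"
        )
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(n_cells)], dtype=object)

    n_comp = min(n_pcs, n_cells - 1, X.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    k = min(n_neighbors, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j))
             for i in range(n_cells) for j in idx[i, 1:]}
    graph = ig.Graph(n=n_cells, edges=sorted(edges), directed=False)

    lo_size, hi_size = (size_window[0] * target_state_size,
                        size_window[1] * target_state_size)

    def mean_size(labels: np.ndarray) -> float:
        return n_cells / len(np.unique(labels))

    # exponential bracket: higher resolution -> more states -> smaller mean
    res_lo, res_hi = 1e-3, 1.0
    labels_hi = _leiden(graph, res_hi, seed)
    tries = 0
    while mean_size(labels_hi) > hi_size and tries < 20:
        res_hi *= 4.0
        labels_hi = _leiden(graph, res_hi, seed)
        tries += 1
    labels_lo = _leiden(graph, res_lo, seed)
    tries = 0
    while mean_size(labels_lo) < lo_size and tries < 20:
        res_lo /= 4.0
        labels_lo = _leiden(graph, res_lo, seed)
        tries += 1

    best = labels_hi
    best_res = res_hi
    best_gap = abs(mean_size(labels_hi) - target_state_size)
    for cand, cres in ((labels_lo, res_lo),):
        gap = abs(mean_size(cand) - target_state_size)
        if gap < best_gap:
            best, best_res, best_gap = cand, cres, gap

    warn = True
    for _ in range(max_bisect):
        if lo_size <= mean_size(best) <= hi_size:
            warn = False
            break
        mid = float(np.sqrt(res_lo * res_hi))
        labels_mid = _leiden(graph, mid, seed)
        m = mean_size(labels_mid)
        gap = abs(m - target_state_size)
        if gap < best_gap:
            best, best_res, best_gap = labels_mid, mid, gap
        if m > target_state_size:
            res_lo = mid  # states too big: raise resolution floor
        else:
            res_hi = mid
        if res_hi / res_lo < 1.0 + 1e-9:
            break
    if lo_size <= mean_size(best) <= hi_size:
        warn = False
    if warn:
        log.warning(
            "cluster_cell_states: mean size %.2f outside window [%g, %g]",
            mean_size(best), lo_size, hi_size,
        )
    return CellStatePartition(
        cell_ids=cell_ids,
        labels=best,
        method_params={
            "n_pcs": n_comp,
            "n_neighbors": k,
            "resolution": best_res,
            "seed": seed,
            "target_state_size": target_state_size,
        },
        warn=warn,
    )


def pool_states(cm: CountMatrix, part: CellStatePartition) -> PseudobulkMatrix:
    """Pool raw counts of each state's member cells into one column."""
    if len(part.cell_ids) != cm.n_cells or not np.array_equal(
        part.cell_ids, cm.cell_ids
    ):
        extra = set(part.cell_ids) - set(cm.cell_ids)
        if extra:
            raise ValueError(
                f"partition contains unknown cells, e.g. {sorted(extra)[:3]}"
            )
        raise ValueError("partition must cover exactly the matrix's cells")
    n_states = part.n_states
    ind = sp.csr_matrix(
        (np.ones(cm.n_cells), (np.arange(cm.n_cells), part.labels)),
        shape=(cm.n_cells, n_states),
    )
    pooled = np.asarray((cm.counts @ ind).todense(), dtype=np.int64)
    norm = normalize_log_cp10k(sp.csr_matrix(pooled))
    state_ids = np.array([f"state{j}" for j in range(n_states)], dtype=object)
    return PseudobulkMatrix(
        pooled_counts=pooled,
        norm_expr=norm,
        gene_ids=cm.gene_ids,
        state_ids=state_ids,
        partition=part,
    )


def pseudobulk_pipeline(
    cm: CountMatrix,
    target_state_size: int = 10,
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
) -> PseudobulkMatrix:
    """Normalize, cluster into cell states and pool, in one call."""
    norm = normalize_log_cp10k(cm)
    part = cluster_cell_states(
        norm,
        cell_ids=cm.cell_ids,
        target_state_size=target_state_size,
        seed=seed,
        n_pcs=n_pcs,
        n_neighbors=n_neighbors,
    )
    return pool_states(cm, part)
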