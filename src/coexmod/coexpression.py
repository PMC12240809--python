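"""Gene-gene Pearson correlation, bait rankings and mutual-rank networks.

The mutual rank of a gene pair is the geometric mean of the two directed
correlation ranks,

    mr_ij = sqrt(rank_ij * rank_ji),

where ``rank_ij`` is the rank of gene j among gene i's correlation partners
(1 = most correlated, self excluded, ties averaged).  Pairs with mutual rank
strictly below a threshold (20 by default) form the edges of the
co-expression network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "CorrelationRanking",
    "MutualRankNetwork",
    "pcc_matrix",
    "rank_to_bait",
    "mutual_rank",
    "mr_edges",
    "compare_rankings",
]


@dataclass
class CorrelationMatrix:
    """Symmetric PCC matrix with a validity mask for zero-variance genes."""

    pcc: np.ndarray
    gene_ids: np.ndarray
    valid: np.ndarray  # bool per gene; invalid genes have NaN rows/cols

    def index_of(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} not in correlation matrix")
        return int(hits[0])


@dataclass
class CorrelationRanking:
    """Descending-PCC ranks of all valid genes relative to one bait gene."""

    bait: str
    ranks: pd.Series      # gene_id -> rank (1 = most correlated, ties averaged)
    pcc_values: pd.Series  # gene_id -> PCC with the bait

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"rank": self.ranks, "pcc": self.pcc_values})
        # stable report order: rank ascending, then gene id
        return df.sort_values(["rank"], kind="stable").rename_axis("gene")


@dataclass
class MutualRankNetwork:
    """Symmetric mutual-rank matrix plus its thresholded edge list."""

    mr: np.ndarray            # NaN on the diagonal
    gene_ids: np.ndarray
    edge_threshold: float = 20.0
    edges: pd.DataFrame = field(default=None, repr=False)


def pcc_matrix(expr: np.ndarray, gene_ids: np.ndarray | None = None
               ) -> CorrelationMatrix:
    """Pearson correlation across samples for every gene pair.

    ``expr`` is genes x samples with at least 3 samples.  Genes with zero
    variance are flagged invalid and their rows/columns set to NaN.
    """
    X = np.asarray(expr, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a genes x samples matrix with >= 3 samples")
    n_genes = X.shape[0]
    if gene_ids is None:
        gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)],
                            dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    sd = X.std(axis=1)
    valid = sd > 0
    if not valid.any():
        raise ValueError("all genes have zero variance")
    pcc = np.full((n_genes, n_genes), np.nan)
    sub = np.corrcoef(X[valid])
    pcc[np.ix_(valid, valid)] = np.atleast_2d(sub)
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.info("pcc_matrix: %d zero-variance genes flagged invalid",
                 n_invalid)
    return CorrelationMatrix(pcc=pcc, gene_ids=gene_ids, valid=valid)


def rank_to_bait(corr: CorrelationMatrix, bait: str) -> CorrelationRanking:
    """Rank all valid non-self genes by descending PCC to the bait."""
    b = corr.index_of(bait)
    if not corr.valid[b]:
        raise ValueError(f"bait {bait!r} has zero variance")
    others = corr.valid.copy()
    others[b] = False
    genes = corr.gene_ids[others]
    vals = corr.pcc[b, others]
    ranks = rankdata(-vals, method="average")
    return CorrelationRanking(
        bait=bait,
        ranks=pd.Series(ranks, index=pd.Index(genes, name="gene")),
        pcc_values=pd.Series(vals, index=pd.Index(genes, name="gene")),
    )


def mutual_rank(corr: CorrelationMatrix,
                edge_threshold: float = 20.0) -> MutualRankNetwork:
    """Mutual-rank matrix over the valid genes of a correlation matrix.

    Per-row descending-PCC ranks exclude self; ties get average ranks, which
    keeps mr symmetric in expectation.  Invalid genes keep NaN rows.
    """
    n = len(corr.gene_ids)
    mr = np.full((n, n), np.nan)
    vidx = np.flatnonzero(corr.valid)
    sub = corr.pcc[np.ix_(vidx, vidx)]
    m = len(vidx)
    if m >= 2:
        neg = -sub
        # self forced to the bottom so it never perturbs the others' ranks
        np.fill_diagonal(neg, np.inf)
        R = rankdata(neg, method="average", axis=1)
        M = np.sqrt(R * R.T)
        np.fill_diagonal(M, np.nan)
        mr[np.ix_(vidx, vidx)] = M
    net = MutualRankNetwork(mr=mr, gene_ids=corr.gene_ids,
                            edge_threshold=edge_threshold)
    net.edges = mr_edges(net, edge_threshold)
    return net


def mr_edges(net: MutualRankNetwork, threshold: float = 20.0) -> pd.DataFrame:
    """Undirected edges (i < j) with mutual rank strictly below threshold."""
    if threshold <= 1.0:
        log.warning("mr_edges: threshold <= 1 yields an empty network "
                    "(mutual ranks are >= 1)")
    iu, ju = np.triu_indices(len(net.gene_ids), k=1)
    vals = net.mr[iu, ju]
    keep = np.isfinite(vals) & (vals < threshold)
    df = pd.DataFrame({
        "gene_i": net.gene_ids[iu[keep]],
        "gene_j": net.gene_ids[ju[keep]],
        "mr": vals[keep],
    })
    return df.sort_values("mr", kind="stable", ignore_index=True)


def compare_rankings(rank_a: CorrelationRanking, rank_b: CorrelationRanking,
                     genes: list[str]) -> tuple[pd.DataFrame, dict]:
    """Per-gene comparison of two bait rankings (a = reference, b = test).

    ``improved`` flags genes whose rank under b is strictly smaller (better)
    than under a.  Genes missing from either ranking are listed with NaN and
    excluded from the summary.
    """
    rows = []
    for g in genes:
        ra = rank_a.ranks.get(g, np.nan)
        rb = rank_b.ranks.get(g, np.nan)
        rows.append({"gene": g, "rank_a": ra, "rank_b": rb})
    df = pd.DataFrame(rows).set_index("gene")
    present = df.notna().all(axis=1)
    absent = df.index[~present].tolist()
    if absent:
        log.warning("compare_rankings: %d genes absent from a ranking: %s",
                    len(absent), absent[:5])
    df["improved"] = present & (df["rank_b"] < df["rank_a"])
    sub = df[present]
    fold = sub["rank_a"] / sub["rank_b"]
    summary = {
        "n_compared": int(present.sum()),
        "n_absent": len(absent),
        "n_improved": int(df["improved"].sum()),
        "frac_improved": float(df["improved"].sum() / present.sum())
        if present.any() else float("nan"),
        "median_fold_change": float(fold.median()) if present.any()
        else float("nan"),
    }
    return df, summary
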