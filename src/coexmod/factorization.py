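"""Consensus non-negative matrix factorization into gene expression modules.

The cell x gene matrix (restricted to highly variable genes, scaled to unit
variance without centering) is factorized as ``X ~ U V`` with usage
``U >= 0`` (cells x k) and spectra ``V >= 0`` (k x genes) by multiplicative
updates on the squared Frobenius objective, which is provably non-increasing
at every update.  Many seeded restarts are pooled: component spectra are
L2-normalized, outlier components (large mean distance to their nearest 30%
neighbours) discarded, the survivors clustered into k groups, and per-group
median spectra form the consensus.  Usage is refit against the consensus by
non-negative least squares, and full-genome gene scores are recovered by
non-negative regression of every gene's normalized expression on the usage,
so genes outside the HVG set still receive module ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances, silhouette_samples

from .containers import CountMatrix

log = logging.getLogger(__name__)

__all__ = [
    "FactorizationConfig",
    "ModuleDecomposition",
    "select_hvg",
    "nmf_single",
    "consensus_nmf",
    "factorize_counts",
    "scan_k",
]

_EPS = 1e-12


@dataclass
class FactorizationConfig:
    """Knobs of the consensus factorization.

    ``k`` is the total number of modules; ``k_scan`` the values swept when
    assessing sensitivity to that choice.  ``density_threshold`` is the
    maximum allowed mean distance of a component to its nearest 30%
    neighbours among the pooled restart components (L2-normalized spectra).
    """

    k: int = 200
    k_scan: tuple[int, ...] = (50, 100, 125, 150, 200, 300, 400)
    n_hvg: int = 2000
    n_restarts: int = 20
    density_threshold: float = 0.5
    neighbor_frac: float = 0.30
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class ModuleDecomposition:
    """Consensus modules: gene scores (W), cell usage (H) and diagnostics."""

    gene_scores: pd.DataFrame      # genes x k, all genes, non-negative
    usage: pd.DataFrame            # cells x k, non-negative
    spectra_hvg: np.ndarray        # k x n_hvg consensus spectra (L2 rows)
    hvg_set: list[str]
    objective: float               # squared Frobenius error of consensus fit
    component_stability: np.ndarray  # per-module mean silhouette
    config: FactorizationConfig = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.gene_scores.shape[1]

    @property
    def module_ids(self) -> list[str]:
        return list(self.gene_scores.columns)


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def select_hvg(cm: CountMatrix, n_top: int, n_bins: int = 20
               ) -> tuple[np.ndarray, np.ndarray]:
    """Pick over-dispersed genes and return the scaled cells x genes matrix.

    Genes are scored by the residual of their variance/mean dispersion
    within mean-expression bins (robust z against the bin median).  The
    top ``n_top`` genes are kept and each is scaled to unit variance —
    counts are divided by their standard deviation, never centered, so the
    matrix stays non-negative.

    Returns ``(gene_index, X_scaled)`` with ``X_scaled`` cells x genes.
    """
    G = cm.n_genes
    if n_top > G:
        log.warning("select_hvg: n_top %d > n_genes %d, clamping", n_top, G)
        n_top = G
    dense = np.asarray(cm.counts.todense(), dtype=float)  # genes x cells
    mean = dense.mean(axis=1)
    var = dense.var(axis=1)
    disp = np.where(mean > 0, var / np.maximum(mean, _EPS), 0.0)
    order = np.argsort(mean, kind="stable")
    score = np.full(G, -np.inf)
    expressed = mean > 0
    expr_order = order[expressed[order]]
    n_expr = len(expr_order)
    # keep at least ~10 genes per bin so the bin median is meaningful
    bins = np.array_split(expr_order, max(1, min(n_bins, n_expr // 10)))
    for b in bins:
        if len(b) == 0:
            continue
        d = disp[b]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        score[b] = (d - med) / (1.4826 * mad + _EPS)
    top = np.argsort(-score, kind="stable")[:n_top]
    top = np.sort(top)
    sub = dense[top]  # hvg x cells
    sd = sub.std(axis=1)
    sd[sd == 0] = 1.0
    X = (sub / sd[:, None]).T  # cells x hvg
    return top, X


# ---------------------------------------------------------------------------
# single NMF run (multiplicative updates)
# ---------------------------------------------------------------------------

def nmf_single(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    return_history: bool = False,
):
    """One NMF run: ``X (cells x genes) ~ U (cells x k) @ V (k x genes)``.

    Multiplicative updates on the squared Frobenius objective
    ``||X - U V||_F^2`` from a seeded uniform initialization scaled by
    ``sqrt(mean(X) / k)``.  Stops when the relative objective change drops
    below ``tol`` or after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.min() < 0:
        raise ValueError("X must be non-negative")
    n, g = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= min(n, g):
        raise ValueError(f"k={k} must be below min(X.shape)={min(n, g)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    U = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    V = rng.uniform(_EPS, 1.0, size=(k, g)) * scale

    def objective(U, V):
        R = X - U @ V
        return float(np.einsum("ij,ij->", R, R))

    history = [objective(U, V)]
    prev = history[0]
    for _ in range(max_iter):
        U *= (X @ V.T) / np.maximum(U @ (V @ V.T), _EPS)
        V *= (U.T @ X) / np.maximum((U.T @ U) @ V, _EPS)
        obj = objective(U, V)
        history.append(obj)
        if prev > 0 and (prev - obj) / prev < tol:
            prev = obj
            break
        prev = obj
    if return_history:
        return U, V, prev, np.asarray(history)
    return U, V, prev


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A w - b||, w >= 0 for every column b of B; returns
    (B.shape[1], A.shape[1])."""
    out = np.empty((B.shape[1], A.shape[1]))
    for j in range(B.shape[1]):
        out[j], _ = nnls(A, B[:, j])
    return out


# ---------------------------------------------------------------------------
# consensus over restarts
# ---------------------------------------------------------------------------

def consensus_nmf(
    X: np.ndarray,
    cfg: FactorizationConfig,
    density_filter: bool = True,
):
    """Consensus factorization of a non-negative cells x genes matrix.

    Returns ``(U, V, objective, stability)`` where ``V`` (k x genes) holds
    the L2-normalized consensus spectra (per-cluster medians of the pooled,
    density-filtered restart spectra) and ``U`` the usage refit by NNLS.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    spectra = []
    for i in range(cfg.n_restarts):
        _, V, _ = nmf_single(X, cfg.k, seed=cfg.seed + i,
                             max_iter=cfg.max_iter, tol=cfg.tol)
        spectra.append(V)
    S = np.vstack(spectra)  # (restarts*k) x genes
    norms = np.linalg.norm(S, axis=1)
    S = S[norms > 0]
    S = S / np.linalg.norm(S, axis=1, keepdims=True)

    keep = np.ones(len(S), dtype=bool)
    if density_filter and len(S) > 1:
        D = pairwise_distances(S)
        # neighbourhood sized to the restarts: each stable component has one
        # replicate per restart, so its nearest ~30% of n_restarts neighbours
        # are its own replicates
        nn = max(1, int(cfg.neighbor_frac * cfg.n_restarts))
        nn = min(nn, len(S) - 1)
        part = np.partition(D + np.diag(np.full(len(S), np.inf)), nn - 1,
                            axis=1)
        local_density = np.sort(part[:, :nn], axis=1).mean(axis=1) \
            if nn > 1 else part[:, 0]
        thr = cfg.density_threshold
        keep = local_density <= thr
        # relax until at least k components survive (spec: re-cluster with a
        # relaxed threshold rather than fail on empty clusters)
        while keep.sum() < cfg.k and thr < 2.0:
            thr *= 1.25
            keep = local_density <= thr
            log.warning("consensus_nmf: density threshold relaxed to %.3f",
                        thr)
        if keep.sum() < cfg.k:
            keep = np.ones(len(S), dtype=bool)
            log.warning("consensus_nmf: density filter disabled "
                        "(too few surviving components)")
    S_kept = S[keep]

    if cfg.n_restarts == 1 or len(S_kept) == cfg.k:
        labels = np.arange(len(S_kept)) % cfg.k
        V_cons = S_kept.copy()
        stability = np.ones(cfg.k)
    else:
        km = KMeans(n_clusters=cfg.k, random_state=cfg.seed, n_init=10)
        labels = km.fit_predict(S_kept)
        V_cons = np.vstack([
            np.median(S_kept[labels == c], axis=0) for c in range(cfg.k)
        ])
        if len(np.unique(labels)) > 1:
            sil = silhouette_samples(S_kept, labels)
            stability = np.array([
                sil[labels == c].mean() if (labels == c).any() else np.nan
                for c in range(cfg.k)
            ])
        else:
            stability = np.full(cfg.k, np.nan)
    vnorm = np.linalg.norm(V_cons, axis=1)
    vnorm[vnorm == 0] = 1.0
    V_cons = V_cons / vnorm[:, None]

    U = _nnls_rows(V_cons.T, X.T)  # cells x k
    R = X - U @ V_cons
    objective = float(np.einsum("ij,ij->", R, R))
    return U, V_cons, objective, stability


def factorize_counts(cm: CountMatrix, cfg: FactorizationConfig
                     ) -> ModuleDecomposition:
    """HVG selection + consensus NMF + full-genome gene-score recovery."""
    hvg_idx, X = select_hvg(cm, cfg.n_hvg)
    U, V, objective, stability = consensus_nmf(X, cfg)

    # normalize usage rows so gene scores are comparable across cells
    row = U.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    U_norm = U / row

    # full-genome scores: non-negative regression of every gene's CP10K
    # expression on the normalized usage
    counts = np.asarray(cm.counts.todense(), dtype=float)
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    cp10k = counts / totals[None, :] * 1e4  # genes x cells
    W = _nnls_rows(U_norm, cp10k.T)  # genes x k
    # usage rows sum to one, so a module-invariant (baseline) expression
    # component fits with equal weight in every module; remove it so module
    # tops reflect module-specific expression, keeping scores non-negative
    W = W - W.min(axis=1, keepdims=True)

    module_ids = [f"module{j + 1}" for j in range(cfg.k)]
    gene_index = pd.Index(cm.gene_ids, name="gene")
    dec = ModuleDecomposition(
        gene_scores=pd.DataFrame(W, index=gene_index, columns=module_ids),
        usage=pd.DataFrame(U_norm, index=pd.Index(cm.cell_ids, name="cell"),
                           columns=module_ids),
        spectra_hvg=V,
        hvg_set=list(cm.gene_ids[hvg_idx]),
        objective=objective,
        component_stability=stability,
        config=cfg,
    )
    return dec


def scan_k(
    cm: CountMatrix,
    cfg: FactorizationConfig,
    baits: list[str] | None = None,
    top_n: int = 100,
    min_baits: int = 3,
) -> tuple[pd.DataFrame, dict[int, ModuleDecomposition]]:
    """Run the consensus factorization for every k in ``cfg.k_scan``.

    Returns a summary table (objective, mean stability and — when baits are
    given — the number of bait-dominated modules) plus the decompositions.
    """
    from dataclasses import replace

    from .prioritization import bait_module_table, find_bait_modules

    rows = []
    decs: dict[int, ModuleDecomposition] = {}
    lim = min(cm.n_cells, cm.n_genes, cfg.n_hvg)
    for k in cfg.k_scan:
        if k >= lim:
            log.warning("scan_k: skipping k=%d >= min matrix dim %d", k, lim)
            continue
        sub = replace(cfg, k=int(k))
        dec = factorize_counts(cm, sub)
        decs[int(k)] = dec
        row = {
            "k": int(k),
            "objective": dec.objective,
            "mean_stability": float(np.nanmean(dec.component_stability)),
        }
        if baits:
            table = bait_module_table(dec, baits)
            row["n_bait_modules"] = len(
                find_bait_modules(table, top_n=top_n, min_baits=min_baits)
            )
        rows.append(row)
    return pd.DataFrame(rows), decs
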