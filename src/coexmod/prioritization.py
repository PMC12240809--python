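"""Module-based candidate prioritization.

Given a module decomposition and a list of known pathway ("bait") genes,
this module finds the bait-dominated modules (>= ``min_baits`` baits among a
module's ``top_n`` genes), tabulates within-module bait ranks, counts
enzyme-family members among module tops, and assembles ranked candidate
lists of uncharacterized genes from the bait modules.

"Module rank" of a gene is its 1-based position when the module's gene
scores are sorted descending; ties break by gene order in the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factorization import ModuleDecomposition

log = logging.getLogger(__name__)

__all__ = [
    "FamilyAnnotation",
    "BaitModuleTable",
    "module_gene_ranks",
    "bait_module_table",
    "find_bait_modules",
    "family_enrichment",
    "candidate_list",
]


@dataclass
class FamilyAnnotation:
    """Gene -> enzyme-family label map over a closed label set."""

    mapping: dict[str, str]
    families: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen = tuple(sorted(set(self.mapping.values())))
        if not self.families:
            self.families = seen
        else:
            unknown = set(seen) - set(self.families)
            if unknown:
                raise ValueError(f"labels outside declared set: {unknown}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_col: str = "gene",
                   family_col: str = "family") -> "FamilyAnnotation":
        return cls(dict(zip(df[gene_col], df[family_col])))


@dataclass
class BaitModuleTable:
    """Within-module ranks of every bait gene (NaN = bait not in universe)."""

    ranks: pd.DataFrame   # baits x modules
    missing: list[str]    # baits absent from the gene universe


def _rank_matrix(dec: ModuleDecomposition) -> pd.DataFrame:
    """Dense genes x modules matrix of within-module ranks (1 = top)."""
    scores = dec.gene_scores.to_numpy()
    n, k = scores.shape
    ranks = np.empty((n, k), dtype=int)
    for j in range(k):
        order = np.argsort(-scores[:, j], kind="stable")
        ranks[order, j] = np.arange(1, n + 1)
    return pd.DataFrame(ranks, index=dec.gene_scores.index,
                        columns=dec.gene_scores.columns)


def module_gene_ranks(dec: ModuleDecomposition, module_id: str
                      ) -> pd.DataFrame:
    """Genes of one module sorted by descending score: (rank, gene, score)."""
    if module_id not in dec.gene_scores.columns:
        raise KeyError(f"unknown module {module_id!r}")
    col = dec.gene_scores[module_id]
    order = np.argsort(-col.to_numpy(), kind="stable")
    return pd.DataFrame({
        "rank": np.arange(1, len(col) + 1),
        "gene": col.index.to_numpy()[order],
        "score": col.to_numpy()[order],
    })


def bait_module_table(dec: ModuleDecomposition, baits: list[str]
                      ) -> BaitModuleTable:
    """Full bait x module matrix of within-module ranks."""
    ranks = _rank_matrix(dec)
    present = [b for b in baits if b in ranks.index]
    missing = [b for b in baits if b not in ranks.index]
    if missing:
        log.warning("bait_module_table: %d baits missing from gene "
                    "universe: %s", len(missing), missing[:5])
    table = ranks.reindex(baits).astype(float)
    return BaitModuleTable(ranks=table, missing=missing)


def pathway_set_module_ranks(dec: ModuleDecomposition,
                             gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Median within-module rank of each named gene set, per module.

    Summarizes how strongly a whole pathway (e.g. MEP vs mevalonate) ranks
    in each module; the median is robust to one stray member.
    """
    ranks = _rank_matrix(dec)
    rows = {}
    for name, genes in gene_sets.items():
        hit = [g for g in genes if g in ranks.index]
        rows[name] = ranks.loc[hit].median(axis=0) if hit else pd.Series(
            np.nan, index=ranks.columns)
    return pd.DataFrame(rows).T.rename_axis("gene_set")


def find_bait_modules(table: BaitModuleTable, top_n: int = 100,
                      min_baits: int = 3) -> list[str]:
    """Modules with >= ``min_baits`` baits ranked within ``top_n``.

    Sorted by bait count (descending) then median bait rank (ascending).
    """
    hits = table.ranks <= top_n
    counts = hits.sum(axis=0)
    out = []
    for mod in table.ranks.columns:
        c = int(counts[mod])
        if c >= min_baits:
            med = float(table.ranks.loc[hits[mod], mod].median())
            out.append((mod, c, med))
    out.sort(key=lambda t: (-t[1], t[2], t[0]))
    return [mod for mod, _, _ in out]


def family_enrichment(dec: ModuleDecomposition, fam: FamilyAnnotation,
                      top_n: int = 100) -> pd.DataFrame:
    """Count enzyme-family members among each module's top ``top_n`` genes.

    Returns a modules x families count table with a ``total`` column,
    sorted by total descending.
    """
    if not fam.mapping:
        log.warning("family_enrichment: empty annotation, all counts zero")
    families = list(fam.families)
    rows = []
    for mod in dec.module_ids:
        top = module_gene_ranks(dec, mod).head(top_n)["gene"]
        labels = [fam.mapping.get(g) for g in top]
        counts = {f: labels.count(f) for f in families}
        counts["total"] = sum(counts.values())
        rows.append(pd.Series(counts, name=mod))
    df = pd.DataFrame(rows).rename_axis("module")
    return df.sort_values("total", ascending=False, kind="stable")


def candidate_list(
    dec: ModuleDecomposition,
    module_ids: list[str],
    known: list[str],
    fam: FamilyAnnotation | None = None,
    families_of_interest: list[str] | None = None,
    top_n: int = 100,
) -> pd.DataFrame:
    """Ranked screening list from the top genes of the named modules.

    Takes the union of each module's ``top_n`` genes, drops the ``known``
    baits, optionally keeps only genes annotated to ``families_of_interest``
    and returns a deterministic table sorted by within-module rank (a gene
    appearing in several modules keeps its best-ranked occurrence).
    """
    known_set = set(known)
    rows = []
    for mod in module_ids:
        top = module_gene_ranks(dec, mod).head(top_n)
        for rank, gene, score in top.itertuples(index=False):
            if gene in known_set:
                continue
            family = fam.mapping.get(gene) if fam else None
            if families_of_interest is not None and \
                    family not in set(families_of_interest):
                continue
            rows.append({"module": mod, "rank": int(rank), "gene": gene,
                         "score": float(score), "family": family})
    df = pd.DataFrame(rows,
                      columns=["module", "rank", "gene", "score", "family"])
    if df.empty:
        return df
    df = df.sort_values(["rank", "module", "gene"],
                        kind="stable").drop_duplicates("gene")
    return df.reset_index(drop=True)
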