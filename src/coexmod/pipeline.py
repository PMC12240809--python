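"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the toggled stages — simulate, qc, pseudobulk,
coexpress, factorize, prioritize, compare — in order, writes every stage's
tables under the output root, and records a manifest (parameters, seed,
output checksums) so that two runs with the same config are bitwise
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coexpression, factorization, prioritization, pseudobulk, qc, sim
from .io import write_10x_mtx

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage toggles plus every stage's parameters, seeded once."""

    out_root: str = "pipeline_out"
    seed: int = 0

    stages: tuple[str, ...] = (
        "simulate", "qc", "pseudobulk", "coexpress", "factorize",
        "prioritize", "compare",
    )

    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    target_state_size: int = 10
    mr_threshold: float = 20.0
    bait_gene: str | None = None           # anchor for rankings
    baits: tuple[str, ...] = ()            # known pathway genes
    factorization: factorization.FactorizationConfig = field(
        default_factory=factorization.FactorizationConfig)
    top_n: int = 100
    min_baits: int = 3
    bulk_group_keys: tuple[str, ...] = ("sample_id",)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = sim.SimConfig(**kwargs["sim"])
        if "qc" in kwargs:
            kwargs["qc"] = qc.QCConfig(**kwargs["qc"])
        if "factorization" in kwargs:
            kwargs["factorization"] = factorization.FactorizationConfig(
                **kwargs["factorization"])
        for key in ("stages", "baits", "bulk_group_keys"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _params(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if dataclasses.is_dataclass(v):
                out[f.name] = _params(v)
            elif isinstance(v, dict):
                out[f.name] = {str(k): str(x) for k, x in v.items()}
            elif isinstance(v, (tuple, list)):
                out[f.name] = list(v)
            else:
                out[f.name] = v
        return out
    return {"value": str(obj)}


class StageError(RuntimeError):
    """Raised when a pipeline stage fails or a dependency is missing."""


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the toggled stages and return the output manifest."""
    out_root = Path(cfg.out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.stages)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": [],
        "parameters": _params(cfg),
        "outputs": {},
    }

    cm = truth = None
    pb = None
    dec = None
    corr_rank_sc = None

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = {
            str(p.relative_to(out_root)): _sha256(p) for p in paths
        }

    try:
        if "simulate" in stages:
            simcfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            cm, truth = sim.generate_dataset(simcfg)
            d = out_root / "simulate"
            write_10x_mtx(cm, d)
            truth.sample_design.to_csv(d / "sample_design.tsv", sep="\t",
                                       index=False)
            np.savetxt(d / "program_loadings.tsv", truth.program_loadings,
                       delimiter="\t")
            record("simulate", sorted(d.iterdir()))

        if "qc" in stages:
            if cm is None:
                raise StageError("qc requires the simulate stage (no input "
                                 "matrix in memory)")
            report = qc.cell_qc_table(cm, cfg.qc)
            cm = qc.filter_cells(cm, cfg.qc)
            cm = qc.filter_genes(cm, cfg.qc)
            d = out_root / "qc"
            d.mkdir(exist_ok=True)
            report.to_csv(d / "cell_qc_report.tsv", sep="\t")
            write_10x_mtx(cm, d / "filtered")
            record("qc", sorted(p for p in d.rglob("*") if p.is_file()))

        if "pseudobulk" in stages:
            if cm is None:
                raise StageError("pseudobulk requires a count matrix "
                                 "(simulate/qc stages)")
            pb = pseudobulk.pseudobulk_pipeline(
                cm, target_state_size=cfg.target_state_size, seed=cfg.seed)
            d = out_root / "pseudobulk"
            d.mkdir(exist_ok=True)
            pb.partition.to_frame().to_csv(d / "cell_states.tsv", sep="\t",
                                           index=False)
            import pandas as pd
            pd.DataFrame(pb.pooled_counts, index=pb.gene_ids,
                         columns=pb.state_ids).to_csv(
                d / "pooled_counts.tsv", sep="\t")
            record("pseudobulk", sorted(d.iterdir()))

        if "coexpress" in stages:
            if pb is None:
                raise StageError("coexpress requires the pseudobulk stage")
            corr = coexpression.pcc_matrix(pb.norm_expr, pb.gene_ids)
            net = coexpression.mutual_rank(corr, cfg.mr_threshold)
            d = out_root / "coexpress"
            d.mkdir(exist_ok=True)
            net.edges.to_csv(d / "mr_edges.tsv", sep="\t", index=False)
            paths = [d / "mr_edges.tsv"]
            if cfg.bait_gene is not None:
                corr_rank_sc = coexpression.rank_to_bait(corr, cfg.bait_gene)
                corr_rank_sc.table().to_csv(d / "bait_ranking.tsv", sep="\t")
                paths.append(d / "bait_ranking.tsv")
            record("coexpress", paths)

        if "factorize" in stages:
            if cm is None:
                raise StageError("factorize requires a count matrix")
            dec = factorization.factorize_counts(cm, cfg.factorization)
            d = out_root / "factorize"
            d.mkdir(exist_ok=True)
            dec.gene_scores.to_csv(d / "gene_scores.tsv", sep="\t")
            dec.usage.to_csv(d / "usage.tsv", sep="\t")
            import pandas as pd
            pd.DataFrame({
                "module": dec.module_ids,
                "stability": dec.component_stability,
            }).to_csv(d / "stability.tsv", sep="\t", index=False)
            record("factorize", sorted(d.iterdir()))

        if "prioritize" in stages:
            if dec is None:
                raise StageError(
                    "prioritize requires the factorize stage; enable "
                    "'factorize' or provide a decomposition")
            baits = list(cfg.baits)
            table = prioritization.bait_module_table(dec, baits)
            mods = prioritization.find_bait_modules(
                table, top_n=cfg.top_n, min_baits=cfg.min_baits)
            cands = prioritization.candidate_list(
                dec, mods, known=baits, top_n=cfg.top_n)
            d = out_root / "prioritize"
            d.mkdir(exist_ok=True)
            table.ranks.to_csv(d / "bait_module_ranks.tsv", sep="\t")
            cands.to_csv(d / "candidates.tsv", sep="\t", index=False)
            (d / "bait_modules.txt").write_text("\n".join(mods) + "\n")
            record("prioritize", sorted(d.iterdir()))

        if "compare" in stages:
            if cm is None or corr_rank_sc is None:
                raise StageError(
                    "compare requires simulate and coexpress (with a bait "
                    "gene) to have run")
            bulk = sim.generate_bulk(cm, list(cfg.bulk_group_keys))
            corr_b = coexpression.pcc_matrix(
                np.log1p(bulk.to_numpy() /
                         bulk.to_numpy().sum(axis=0, keepdims=True) * 1e4),
                cm.gene_ids)
            rank_b = coexpression.rank_to_bait(corr_b, cfg.bait_gene)
            genes = list(cfg.baits) if cfg.baits else list(
                corr_rank_sc.ranks.index)
            df, summary = coexpression.compare_rankings(
                rank_b, corr_rank_sc, genes)
            d = out_root / "compare"
            d.mkdir(exist_ok=True)
            df.to_csv(d / "rank_comparison.tsv", sep="\t")
            (d / "summary.json").write_text(json.dumps(summary, indent=2))
            record("compare", sorted(d.iterdir()))
    except StageError:
        manifest["failed"] = True
        (out_root / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise

    (out_root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest
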