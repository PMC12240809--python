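"""Synthetic multiplexed-perturbation single-cell count generator.

Emulates the statistical structure of a pooled elicitation experiment read
out by single-nucleus RNA-seq: a full-factorial sample design
(condition x developmental stage x time point x replicate), additive gene
expression programs whose per-cell usage follows a Dirichlet over the
programs active in that cell, condition-gated programs expressed only in
designated (condition, stage) combinations and — optionally — only in a
random subset of cells of those samples, a per-gene baseline, log-normal
library sizes and negative-binomial counts.

The default factorial design is 17 conditions x 2 stages x 4 time points x
2 replicates = 272 samples (136 distinct perturbations, 2 replicates each).

Known pathway ("bait") genes are planted into designated programs with an
elevated loading quantile so that top-of-module recovery is testable against
the returned :class:`SyntheticTruth`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_multi_experiment",
    "generate_bulk",
    "expected_profiles",
]


@dataclass
class SimConfig:
    """Parameters of one simulated multiplexed-perturbation experiment.

    The factorial design (``n_conditions x n_stages x n_timepoints x
    n_replicates``) defines the samples.  Programs are additive non-negative
    expression programs; ``gated_programs`` maps a program index to the list
    of ``(condition_idx, stage_idx)`` combinations in which it may be used —
    everywhere else its usage is exactly zero.  Ungated programs are active
    in every cell, so a simple "background" program is expressed by leaving
    at least one program ungated.
    """

    n_genes: int = 1000
    n_programs: int = 10
    n_conditions: int = 17
    n_stages: int = 2
    n_timepoints: int = 4
    n_replicates: int = 2
    cells_per_sample: int | None = 20
    n_cells_total: int | None = None

    # per-gene baseline rates ~ Gamma(baseline_shape, rate=baseline_rate)
    baseline_shape: float = 0.4
    baseline_rate: float = 2.0
    #: fraction of a cell's expected expression coming from the baseline
    baseline_weight: float = 0.3

    #: fraction of genes loaded (non-zero) per program
    program_sparsity: float = 0.08
    # program gene loadings ~ Gamma(loading_shape, rate=loading_rate)
    loading_shape: float = 2.0
    loading_rate: float = 1.0

    #: program -> list of (condition_idx, stage_idx) where it is usable
    gated_programs: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    #: probability that a cell of a designated sample activates a gated program
    active_cell_fraction: float = 1.0
    #: when True, gated activation ramps linearly over the time course:
    #: the probability is scaled by (t+1)/n_timepoints, emulating an
    #: elicitation response that builds over days
    time_ramp: bool = False

    #: bait gene index -> program index; bait loadings are raised to the
    #: ``bait_quantile`` of the program's non-zero loadings
    bait_assignment: dict[int, int] = field(default_factory=dict)
    bait_quantile: float = 0.95
    #: hub gene index -> programs; a hub gene (e.g. the scaffold-forming
    #: synthase shared by every phase of a pathway) is planted at the bait
    #: quantile in several programs at once
    hub_genes: dict[int, tuple[int, ...]] = field(default_factory=dict)

    #: Dirichlet concentration for usage over a cell's active programs
    dirichlet_alpha: float = 0.3

    #: negative-binomial dispersion (variance = mu + disp * mu^2); 0 = Poisson
    nb_dispersion: float = 0.1
    # log-normal library size
    libsize_mu: float = float(np.log(3000.0))
    libsize_sigma: float = 0.35

    experiment: str = "exp1"
    seed: int = 0

    # -- derived --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return (self.n_conditions * self.n_stages * self.n_timepoints
                * self.n_replicates)

    @property
    def n_perturbations(self) -> int:
        """Distinct (condition, stage, timepoint) combinations."""
        return self.n_conditions * self.n_stages * self.n_timepoints

    def validate(self) -> None:
        for name in ("n_genes", "n_programs", "n_conditions", "n_stages",
                     "n_timepoints", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cells_per_sample is None and self.n_cells_total is None:
            raise ValueError("set cells_per_sample or n_cells_total")
        if self.cells_per_sample is not None and self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if self.n_cells_total is not None and self.n_cells_total < 1:
            raise ValueError("n_cells_total must be >= 1")
        if not (0.0 < self.program_sparsity <= 1.0):
            raise ValueError("program_sparsity must be in (0, 1]")
        if not (0.0 <= self.baseline_weight < 1.0):
            raise ValueError("baseline_weight must be in [0, 1)")
        if not (0.0 < self.active_cell_fraction <= 1.0):
            raise ValueError("active_cell_fraction must be in (0, 1]")
        for g, k in self.bait_assignment.items():
            if not (0 <= g < self.n_genes):
                raise ValueError(f"bait gene {g} outside [0, {self.n_genes})")
            if not (0 <= k < self.n_programs):
                raise ValueError(f"bait program {k} outside [0, {self.n_programs})")
        for g, ks in self.hub_genes.items():
            if not (0 <= g < self.n_genes):
                raise ValueError(f"hub gene {g} outside [0, {self.n_genes})")
            if any(not (0 <= k < self.n_programs) for k in ks):
                raise ValueError(f"hub gene {g} names an unknown program")
        for k, combos in self.gated_programs.items():
            if not (0 <= k < self.n_programs):
                raise ValueError(f"gated program {k} outside program range")
            for (c, s) in combos:
                if not (0 <= c < self.n_conditions and 0 <= s < self.n_stages):
                    raise ValueError(
                        f"gating ({c}, {s}) outside design for program {k}"
                    )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset, for recovery tests.

    ``program_loadings`` columns are the normalized (sum-to-one) gene
    profiles actually mixed into cells; ``cell_usage`` rows are the realized
    Dirichlet usages (zero for gated programs outside their designation).
    """

    program_loadings: np.ndarray  # genes x K, column sums 1
    baseline: np.ndarray          # genes, sums to 1
    sample_design: pd.DataFrame   # one row per sample
    cell_usage: np.ndarray        # cells x K, rows sum to 1 (or all-zero)
    cell_sample: np.ndarray       # sample_id per cell
    library_size: np.ndarray      # realized expected library size per cell
    bait_assignment: dict[int, int]
    config: SimConfig
    seed: int

    def program_genes(self, k: int) -> np.ndarray:
        """Indices of genes loaded (non-zero) in program ``k``."""
        return np.flatnonzero(self.program_loadings[:, k] > 0)


def _sample_design(cfg: SimConfig) -> pd.DataFrame:
    conds = [f"C{i + 1:02d}" for i in range(cfg.n_conditions)]
    stages = ["young", "mature"][: cfg.n_stages] or ["young"]
    if cfg.n_stages > 2:
        stages = [f"stage{i + 1}" for i in range(cfg.n_stages)]
    tps = [f"d{i + 1}" for i in range(cfg.n_timepoints)]
    reps = [f"r{i + 1}" for i in range(cfg.n_replicates)]
    rows = []
    for (ci, c), (si, s), (ti, t), r in itertools.product(
        enumerate(conds), enumerate(stages), enumerate(tps), reps
    ):
        rows.append({
            "sample_id": f"{c}_{s}_{t}_{r}",
            "condition": c,
            "stage": s,
            "timepoint": t,
            "replicate": r,
            "condition_idx": ci,
            "stage_idx": si,
            "timepoint_idx": ti,
        })
    return pd.DataFrame(rows)


def _cells_per_sample(cfg: SimConfig) -> np.ndarray:
    n_samples = cfg.n_samples
    if cfg.n_cells_total is not None:
        base, rem = divmod(cfg.n_cells_total, n_samples)
        sizes = np.full(n_samples, base, dtype=int)
        sizes[:rem] += 1
        if base == 0 and rem < n_samples:
            # fewer cells than samples: trailing samples are empty
            pass
        return sizes
    return np.full(n_samples, cfg.cells_per_sample, dtype=int)


def _draw_loadings(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    G, K = cfg.n_genes, cfg.n_programs
    m = max(1, int(round(cfg.program_sparsity * G)))
    L = np.zeros((G, K))
    for k in range(K):
        genes = rng.choice(G, size=m, replace=False)
        L[genes, k] = rng.gamma(cfg.loading_shape, 1.0 / cfg.loading_rate,
                                size=m)
    # plant baits with an elevated loading quantile in their program; a bait
    # maps to exactly one program, so its loading elsewhere is zeroed
    for g, k in cfg.bait_assignment.items():
        nz = L[:, k][L[:, k] > 0]
        hi = np.quantile(nz, cfg.bait_quantile) if nz.size else 1.0
        L[g, :] = 0.0
        L[g, k] = max(L[g, k], hi)
    for g, ks in cfg.hub_genes.items():
        for k in ks:
            nz = L[:, k][L[:, k] > 0]
            hi = np.quantile(nz, cfg.bait_quantile) if nz.size else 1.0
            L[g, k] = max(L[g, k], hi)
    col = L.sum(axis=0)
    col[col == 0] = 1.0
    return L / col


def expected_profiles(truth: SyntheticTruth) -> np.ndarray:
    """Expected per-cell expression fractions (genes x cells).

    ``p_cg = baseline_weight * b_g + (1 - baseline_weight) * (L u_c)_g``,
    renormalized per cell; cells whose usage is all-zero fall back to the
    baseline.  Multiplying by the cell's library size gives the
    negative-binomial mean actually used during sampling.
    """
    cfg = truth.config
    mix = truth.program_loadings @ truth.cell_usage.T  # genes x cells
    used = truth.cell_usage.sum(axis=1) > 0
    p = (cfg.baseline_weight * truth.baseline[:, None]
         + (1.0 - cfg.baseline_weight) * mix)
    p[:, ~used] = truth.baseline[:, None]
    p /= p.sum(axis=0, keepdims=True)
    return p


def generate_dataset(cfg: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate one experiment; fully reproducible from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = _sample_design(cfg)
    sizes = _cells_per_sample(cfg)

    b = rng.gamma(cfg.baseline_shape, 1.0 / cfg.baseline_rate,
                  size=cfg.n_genes)
    b = np.maximum(b, 1e-12)
    b /= b.sum()
    L = _draw_loadings(cfg, rng)

    K = cfg.n_programs
    gated = set(cfg.gated_programs)
    ungated = np.array(sorted(set(range(K)) - gated), dtype=int)
    designated = {
        k: set(map(tuple, combos)) for k, combos in cfg.gated_programs.items()
    }

    blocks: list[sp.csr_matrix] = []
    usage_rows: list[np.ndarray] = []
    cell_sample: list[str] = []
    cell_ids: list[str] = []
    libsizes: list[np.ndarray] = []

    for row, n_cells in zip(design.itertuples(index=False), sizes):
        if n_cells == 0:
            continue
        key = (row.condition_idx, row.stage_idx)
        sample_gated = np.array(
            sorted(k for k in gated if key in designated[k]), dtype=int
        )
        p_active = cfg.active_cell_fraction
        if cfg.time_ramp:
            p_active *= (row.timepoint_idx + 1) / cfg.n_timepoints
        U = np.zeros((n_cells, K))
        for i in range(n_cells):
            active = list(ungated)
            for k in sample_gated:
                if p_active >= 1.0 or rng.random() < p_active:
                    active.append(int(k))
            if active:
                active = np.array(sorted(active), dtype=int)
                U[i, active] = rng.dirichlet(
                    np.full(len(active), cfg.dirichlet_alpha)
                )
        mix = L @ U.T  # genes x cells
        p = (cfg.baseline_weight * b[:, None]
             + (1.0 - cfg.baseline_weight) * mix)
        empty = U.sum(axis=1) == 0
        if empty.any():
            p[:, empty] = b[:, None]
        p /= p.sum(axis=0, keepdims=True)

        lib = rng.lognormal(cfg.libsize_mu, cfg.libsize_sigma, size=n_cells)
        mu = p * lib[None, :]
        if cfg.nb_dispersion > 0:
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        blocks.append(sp.csr_matrix(counts.astype(np.int64)))
        usage_rows.append(U)
        libsizes.append(lib)
        cell_sample.extend([row.sample_id] * n_cells)
        start = len(cell_ids)
        cell_ids.extend(
            f"{cfg.experiment}:{row.sample_id}:c{start + i:06d}"
            for i in range(n_cells)
        )

    counts = sp.hstack(blocks, format="csr")
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)],
                        dtype=object)
    cell_ids_arr = np.array(cell_ids, dtype=object)
    meta_map = design.set_index("sample_id")
    cell_sample_arr = np.array(cell_sample, dtype=object)
    cell_meta = meta_map.loc[cell_sample_arr, [
        "condition", "stage", "timepoint", "replicate"
    ]].copy()
    cell_meta.insert(0, "sample_id", cell_sample_arr)
    cell_meta["experiment"] = cfg.experiment
    cell_meta.index = pd.Index(cell_ids_arr)

    cm = CountMatrix(counts=counts, gene_ids=gene_ids,
                     cell_ids=cell_ids_arr, cell_meta=cell_meta)
    truth = SyntheticTruth(
        program_loadings=L,
        baseline=b,
        sample_design=design.drop(
            columns=["condition_idx", "stage_idx", "timepoint_idx"]),
        cell_usage=np.vstack(usage_rows),
        cell_sample=cell_sample_arr,
        library_size=np.concatenate(libsizes),
        bait_assignment=dict(cfg.bait_assignment),
        config=cfg,
        seed=cfg.seed,
    )
    return cm, truth


def generate_multi_experiment(
    configs: list[SimConfig],
) -> tuple[CountMatrix, list[SyntheticTruth]]:
    """Concatenate several simulated experiments (cohorts) on shared genes.

    All configs must agree on ``n_genes`` and carry distinct ``experiment``
    labels.  Gene identities are shared; each cohort has its own design,
    programs and seed, mirroring independently collected libraries.
    """
    if not configs:
        raise ValueError("no experiment configs given")
    n_genes = {c.n_genes for c in configs}
    if len(n_genes) != 1:
        raise ValueError("all cohorts must share n_genes")
    labels = [c.experiment for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("experiment labels must be distinct")
    cms, truths = [], []
    for cfg in configs:
        cm, truth = generate_dataset(cfg)
        cms.append(cm)
        truths.append(truth)
    counts = sp.hstack([c.counts for c in cms], format="csr")
    cell_ids = np.concatenate([c.cell_ids for c in cms])
    cell_meta = pd.concat([c.cell_meta for c in cms], axis=0)
    merged = CountMatrix(counts=counts, gene_ids=cms[0].gene_ids,
                         cell_ids=cell_ids, cell_meta=cell_meta)
    return merged, truths


def generate_bulk(cm: CountMatrix, group_keys: list[str]) -> pd.DataFrame:
    """Sum cells into in-silico bulk samples by metadata key tuples.

    Each bulk column is the elementwise sum of the counts of the cells
    sharing the ``group_keys`` tuple.  Columns are ordered by sorted key
    tuple and named by joining the key values with ``"|"``.
    """
    for key in group_keys:
        if key not in cm.cell_meta.columns:
            raise KeyError(f"group key {key!r} not in cell metadata")
    keys_df = cm.cell_meta[list(group_keys)]
    if keys_df.isna().any().any():
        bad = keys_df.columns[keys_df.isna().any()].tolist()
        raise ValueError(f"missing values in group keys {bad}")
    tuples = list(map(tuple, keys_df.itertuples(index=False)))
    groups = sorted(set(tuples))
    index_of = {t: j for j, t in enumerate(groups)}
    col = np.array([index_of[t] for t in tuples])
    ind = sp.csr_matrix(
        (np.ones(cm.n_cells), (np.arange(cm.n_cells), col)),
        shape=(cm.n_cells, len(groups)),
    )
    pooled = np.asarray((cm.counts @ ind).todense(), dtype=np.int64)
    names = ["|".join(map(str, t)) for t in groups]
    return pd.DataFrame(pooled, index=pd.Index(cm.gene_ids, name="gene"),
                        columns=names)
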