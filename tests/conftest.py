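import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from coexmod import CountMatrix, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured simulated dataset: 144 cells, 120 genes,
    4 programs of which one is gated to a single (condition, stage)."""
    cfg = SimConfig(
        n_genes=120,
        n_programs=4,
        n_conditions=3,
        n_stages=2,
        n_timepoints=2,
        n_replicates=2,
        cells_per_sample=6,
        program_sparsity=0.15,
        bait_assignment={5: 0, 17: 0, 40: 1},
        gated_programs={0: [(0, 0)]},
        seed=123,
    )
    return generate_dataset(cfg)


@pytest.fixture
def small_cm(small_sim):
    return small_sim[0]


def make_cm(counts, gene_ids=None, cell_ids=None, sample_ids=None):
    """Hand-built CountMatrix from a dense array (genes x cells)."""
    counts = np.asarray(counts)
    g, c = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(c)]
    if sample_ids is None:
        sample_ids = ["s0"] * c
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": ["C01"] * c,
        "stage": ["young"] * c,
        "timepoint": ["d1"] * c,
        "replicate": ["r1"] * c,
        "experiment": ["exp1"] * c,
    }, index=pd.Index(cell_ids))
    return CountMatrix(
        counts=sp.csr_matrix(counts.astype(np.int64)),
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
        cell_meta=meta,
    )


@pytest.fixture
def cm_factory():
    return make_cm
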