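"""Simulator: factorial design, gating, noise model and in-silico bulk."""

import numpy as np
import pandas as pd
import pytest

from coexmod import SimConfig, generate_bulk, generate_dataset, \
    generate_multi_experiment
from coexmod.sim import expected_profiles


class TestDesign:
    def test_default_design_has_272_samples_and_136_perturbations(self):
        cfg = SimConfig(n_genes=50, n_programs=2, cells_per_sample=1, seed=0)
        cm, truth = generate_dataset(cfg)
        assert cfg.n_samples == 272
        assert cfg.n_perturbations == 136
        assert truth.sample_design["sample_id"].nunique() == 272
        perturb = truth.sample_design[["condition", "stage", "timepoint"]]
        assert len(perturb.drop_duplicates()) == 136
        assert cm.cell_meta["sample_id"].nunique() == 272

    def test_total_cell_budget_is_distributed_exactly(self):
        cfg = SimConfig(n_genes=30, n_programs=2, cells_per_sample=None,
                        n_cells_total=1001, seed=1)
        cm, _ = generate_dataset(cfg)
        assert cm.n_cells == 1001

    def test_cohort_concatenation_reaches_printed_totals(self):
        shared = dict(n_genes=40, n_programs=2)
        cohorts = [
            SimConfig(**shared, n_cells_total=100, cells_per_sample=None,
                      experiment="elicited", seed=1),
            SimConfig(**shared, n_conditions=1, n_stages=1, n_timepoints=1,
                      n_replicates=1, n_cells_total=40,
                      cells_per_sample=None, experiment="naive_young",
                      seed=2),
        ]
        cm, truths = generate_multi_experiment(cohorts)
        assert cm.n_cells == 140
        assert set(cm.cell_meta["experiment"]) == {"elicited", "naive_young"}
        assert len(truths) == 2


class TestCounts:
    def test_same_seed_reproduces_bitwise_different_seed_differs(self):
        cfg = SimConfig(n_genes=60, n_programs=3, n_conditions=2,
                        n_timepoints=1, cells_per_sample=4, seed=7)
        cm1, _ = generate_dataset(cfg)
        cm2, _ = generate_dataset(cfg)
        assert (cm1.counts != cm2.counts).nnz == 0
        cfg_other = SimConfig(**{**cfg.__dict__, "seed": 8})
        cm3, _ = generate_dataset(cfg_other)
        assert (cm1.counts != cm3.counts).nnz > 0

    def test_single_program_expected_matrix_has_rank_one(self):
        cfg = SimConfig(n_genes=40, n_programs=1, n_conditions=2,
                        n_stages=1, n_timepoints=1, n_replicates=1,
                        cells_per_sample=5, baseline_weight=0.0,
                        nb_dispersion=0.0, libsize_sigma=0.0, seed=3)
        _, truth = generate_dataset(cfg)
        p = expected_profiles(truth)
        mu = p * truth.library_size[None, :]
        s = np.linalg.svd(mu, compute_uv=False)
        assert s[1] / s[0] < 1e-10

    def test_raising_a_loading_raises_the_expected_count(self):
        cfg = SimConfig(n_genes=30, n_programs=2, n_conditions=1,
                        n_stages=1, n_timepoints=1, n_replicates=1,
                        cells_per_sample=10, seed=5)
        _, truth = generate_dataset(cfg)
        g = truth.program_genes(0)[0]
        base = expected_profiles(truth)
        bumped = truth.program_loadings.copy()
        bumped[g, 0] *= 2.0
        truth2 = type(truth)(**{**truth.__dict__,
                                "program_loadings": bumped})
        up = expected_profiles(truth2)
        uses = truth.cell_usage[:, 0] > 0
        assert np.all(up[g, uses] > base[g, uses])

    def test_gated_program_usage_is_zero_outside_designation(self,
                                                             small_sim):
        cm, truth = small_sim
        designated = (
            (cm.cell_meta["condition"] == "C01")
            & (cm.cell_meta["stage"] == "young")
        ).to_numpy()
        assert np.all(truth.cell_usage[~designated, 0] == 0)
        assert truth.cell_usage[designated, 0].sum() > 0

    def test_counts_are_nonnegative_integers(self, small_cm):
        assert small_cm.counts.data.min() >= 0
        assert np.issubdtype(small_cm.counts.dtype, np.integer)

    def test_bait_genes_load_only_their_program_at_high_quantile(
            self, small_sim):
        _, truth = small_sim
        bait_set = set(truth.bait_assignment)
        for g, k in truth.bait_assignment.items():
            col = truth.program_loadings[:, k]
            nonbait = np.array([col[i] for i in np.flatnonzero(col > 0)
                                if i not in bait_set])
            assert col[g] >= np.quantile(nonbait, 0.90)
            others = np.delete(np.arange(truth.program_loadings.shape[1]), k)
            assert np.all(truth.program_loadings[g, others] == 0)


class TestValidation:
    def test_bait_outside_gene_range_rejected(self):
        cfg = SimConfig(n_genes=10, n_programs=2, cells_per_sample=1,
                        bait_assignment={10: 0})
        with pytest.raises(ValueError, match="bait gene"):
            generate_dataset(cfg)

    def test_zero_cells_per_sample_rejected(self):
        cfg = SimConfig(n_genes=10, n_programs=2, cells_per_sample=0)
        with pytest.raises(ValueError, match="cells_per_sample"):
            generate_dataset(cfg)


class TestBulk:
    def test_single_group_equals_row_sums(self, small_cm):
        bulk = generate_bulk(small_cm, ["experiment"])
        assert bulk.shape[1] == 1
        np.testing.assert_array_equal(
            bulk.iloc[:, 0].to_numpy(), small_cm.gene_totals())

    def test_toy_two_group_columns_match_hand_sums(self, cm_factory):
        counts = np.array([[1, 2, 3, 4],
                           [0, 5, 0, 7],
                           [9, 0, 1, 1]])
        cm = cm_factory(counts, sample_ids=["a", "b", "a", "b"])
        bulk = generate_bulk(cm, ["sample_id"])
        np.testing.assert_array_equal(bulk["a"], counts[:, [0, 2]].sum(1))
        np.testing.assert_array_equal(bulk["b"], counts[:, [1, 3]].sum(1))
        assert list(bulk.columns) == ["a", "b"]

    def test_grand_total_is_conserved_for_any_grouping(self, small_cm):
        for keys in (["sample_id"], ["condition", "stage"], ["timepoint"]):
            bulk = generate_bulk(small_cm, keys)
            assert bulk.to_numpy().sum() == small_cm.counts.sum()

    def test_unknown_group_key_is_named_in_error(self, small_cm):
        with pytest.raises(KeyError, match="tissue"):
            generate_bulk(small_cm, ["tissue"])
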