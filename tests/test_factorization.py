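"""HVG selection, multiplicative-update NMF and the consensus wrapper."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from coexmod import (FactorizationConfig, SimConfig, consensus_nmf,
                     factorize_counts, generate_dataset, nmf_single,
                     scan_k, select_hvg)


class TestSelectHvg:
    def test_higher_variance_at_equal_mean_scores_higher(self, cm_factory):
        rng = np.random.default_rng(0)
        quiet = rng.poisson(5.0, size=(1, 200))
        # same mean, doubled variance: mixture of 0 and 10
        loud = (rng.random(size=(1, 200)) < 0.5).astype(int) * 10
        filler = rng.poisson(5.0, size=(30, 200))
        counts = np.vstack([quiet, loud, filler])
        cm = cm_factory(counts)
        idx, _ = select_hvg(cm, n_top=5)
        assert 1 in idx

    def test_constant_gene_never_selected(self, cm_factory):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=(20, 100))
        counts[7] = 3  # constant
        cm = cm_factory(counts)
        idx, _ = select_hvg(cm, n_top=10)
        assert 7 not in idx

    def test_planted_high_dispersion_set_recovered(self, cm_factory):
        rng = np.random.default_rng(2)
        counts = rng.poisson(4.0, size=(1000, 300))
        planted = rng.choice(1000, size=50, replace=False)
        onoff = rng.random(size=(50, 300)) < 0.2
        counts[planted] = rng.poisson(20.0, size=(50, 300)) * onoff
        cm = cm_factory(counts)
        idx, X = select_hvg(cm, n_top=50)
        assert len(set(idx) & set(planted)) >= 45
        assert X.shape == (300, 50)
        assert X.min() >= 0

    def test_n_top_clamped_with_warning(self, cm_factory):
        rng = np.random.default_rng(3)
        cm = cm_factory(rng.poisson(3.0, size=(10, 50)))
        idx, X = select_hvg(cm, n_top=100)
        assert len(idx) == 10


class TestNmfSingle:
    def test_planted_factorization_recovered(self):
        rng = np.random.default_rng(4)
        U = rng.gamma(2.0, size=(60, 4))
        V = rng.gamma(2.0, size=(4, 30))
        X = U @ V
        _, _, obj = nmf_single(X, k=4, seed=0, max_iter=2000, tol=1e-10)
        rel = np.sqrt(obj) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_rank_one_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.gamma(1.0, size=(4, 4))
        _, V, obj = nmf_single(X, k=1, seed=1, max_iter=5000, tol=1e-12)
        # brute-force rank-1 fit: best scaling along a grid of directions
        grid = np.linspace(0.0, 1.5, 12)
        best = np.inf
        for v in itertools.product(grid, repeat=4):
            v = np.array(v)
            if not v.any():
                continue
            u = np.maximum(X @ v, 0) / (v @ v)
            best = min(best, np.linalg.norm(X - np.outer(u, v)) ** 2)
        assert obj <= best + 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_never_increases(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.gamma(1.5, size=(40, 25))
        _, _, _, hist = nmf_single(X, k=5, seed=seed, max_iter=200,
                                   tol=1e-12, return_history=True)
        diffs = np.diff(hist)
        assert np.all(diffs <= 1e-8 * hist[0])

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nmf_single(-np.ones((5, 5)), k=2)

    def test_k_at_least_matrix_rank_rejected(self):
        with pytest.raises(ValueError, match="below"):
            nmf_single(np.ones((4, 5)), k=4)


class TestConsensus:
    def test_single_restart_equals_single_run_up_to_scale(self):
        rng = np.random.default_rng(6)
        X = rng.gamma(1.5, size=(50, 30))
        cfg = FactorizationConfig(k=3, n_restarts=1, seed=11, n_hvg=30)
        U_c, V_c, _, _ = consensus_nmf(X, cfg, density_filter=False)
        _, V_s, _ = nmf_single(X, k=3, seed=11, max_iter=cfg.max_iter,
                               tol=cfg.tol)
        V_s = V_s / np.linalg.norm(V_s, axis=1, keepdims=True)
        # match columns by cosine; each consensus spectrum must equal one
        # single-run spectrum
        C = V_c @ V_s.T
        ri, ci = linear_sum_assignment(-C)
        assert np.all(C[ri, ci] > 1 - 1e-8)

    def test_injected_outlier_spectrum_removed_by_density_filter(self):
        rng = np.random.default_rng(7)
        U = rng.gamma(2.0, size=(80, 3))
        V = np.zeros((3, 30))
        for k in range(3):
            V[k, 10 * k:10 * (k + 1)] = rng.gamma(2.0, size=10)
        X = U @ V + rng.random(size=(80, 30)) * 0.01
        spectra = []
        for i in range(6):
            _, Vi, _ = nmf_single(X, 3, seed=20 + i)
            spectra.append(Vi)
        S = np.vstack(spectra)
        outlier = rng.random(size=30)
        S = np.vstack([S, outlier])
        S = S / np.linalg.norm(S, axis=1, keepdims=True)
        from sklearn.metrics import pairwise_distances
        D = pairwise_distances(S)
        nn = 2
        np.fill_diagonal(D, np.inf)
        dens = np.sort(D, axis=1)[:, :nn].mean(axis=1)
        assert dens[-1] > 0.5          # the outlier fails the density rule
        assert np.median(dens[:-1]) < 0.5

    def test_small_planted_recovery(self):
        cfg_sim = SimConfig(
            n_genes=200, n_programs=4, n_conditions=4, n_stages=1,
            n_timepoints=1, n_replicates=2, cells_per_sample=50,
            program_sparsity=0.1, seed=42)
        cm, truth = generate_dataset(cfg_sim)
        cfg = FactorizationConfig(k=4, n_hvg=150, n_restarts=6, seed=3)
        dec = factorize_counts(cm, cfg)
        W = dec.gene_scores.to_numpy()
        L = truth.program_loadings
        Wn = W / np.maximum(np.linalg.norm(W, axis=0), 1e-12)
        Ln = L / np.maximum(np.linalg.norm(L, axis=0), 1e-12)
        C = Ln.T @ Wn
        ri, ci = linear_sum_assignment(-C)
        assert C[ri, ci].mean() >= 0.8

    def test_identical_seeds_reproduce_identical_modules(self):
        rng = np.random.default_rng(8)
        X = rng.gamma(1.5, size=(40, 25))
        cfg = FactorizationConfig(k=3, n_restarts=4, seed=5)
        _, V1, o1, _ = consensus_nmf(X, cfg)
        _, V2, o2, _ = consensus_nmf(X, cfg)
        np.testing.assert_array_equal(V1, V2)
        assert o1 == o2


@pytest.fixture(scope="module")
def planted():
    cfg_sim = SimConfig(
        n_genes=150, n_programs=4, n_conditions=4, n_stages=1,
        n_timepoints=1, n_replicates=2, cells_per_sample=40,
        program_sparsity=0.12, baseline_weight=0.1,
        dirichlet_alpha=0.1, nb_dispersion=0.05, seed=17)
    return generate_dataset(cfg_sim)


class TestScanK:
    def test_best_restart_objective_non_increasing_in_k(self, planted):
        cm, _ = planted
        _, X = select_hvg(cm, 120)
        objs = []
        for k in (2, 4, 8):
            best = min(nmf_single(X, k, seed=s, max_iter=400)[2]
                       for s in range(4))
            objs.append(best)
        assert objs[0] >= objs[1] - 1e-6 * objs[0]
        assert objs[1] >= objs[2] - 1e-6 * objs[1]

    def test_stability_peaks_at_true_k(self, planted):
        cm, _ = planted
        cfg = FactorizationConfig(k=4, k_scan=(2, 4, 8), n_hvg=120,
                                  n_restarts=5, seed=2)
        summary, _ = scan_k(cm, cfg)
        best_k = summary.loc[summary["mean_stability"].idxmax(), "k"]
        assert best_k == 4

    def test_single_k_scan_matches_direct_consensus(self, planted):
        cm, _ = planted
        cfg = FactorizationConfig(k=4, k_scan=(4,), n_hvg=120,
                                  n_restarts=3, seed=2)
        summary, decs = scan_k(cm, cfg)
        direct = factorize_counts(cm, cfg)
        assert summary.loc[0, "objective"] == direct.objective
        np.testing.assert_array_equal(decs[4].gene_scores.to_numpy(),
                                      direct.gene_scores.to_numpy())

    def test_k_exceeding_dimensions_skipped(self, planted):
        cm, _ = planted
        cfg = FactorizationConfig(k=4, k_scan=(4, 1000), n_hvg=120,
                                  n_restarts=2, seed=2)
        summary, decs = scan_k(cm, cfg)
        assert list(summary["k"]) == [4]
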