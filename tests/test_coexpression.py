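"""Correlation, bait rankings and the mutual-rank network."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from coexmod import (MutualRankNetwork, compare_rankings, mr_edges,
                     mutual_rank, pcc_matrix, rank_to_bait)


def naive_mutual_rank(pcc):
    """Brute-force double loop: directed ranks (self excluded, average
    ties), geometric mean.  Independent of the vectorized path."""
    n = pcc.shape[0]
    ranks = np.zeros((n, n))
    for i in range(n):
        others = [j for j in range(n) if j != i]
        r = rankdata([-pcc[i, j] for j in others], method="average")
        for pos, j in enumerate(others):
            ranks[i, j] = r[pos]
    mr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                mr[i, j] = np.sqrt(ranks[i, j] * ranks[j, i])
    return mr


class TestPccMatrix:
    def test_duplicated_and_negated_genes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        expr = np.vstack([base, base, -base])
        corr = pcc_matrix(expr)
        assert corr.pcc[0, 1] == pytest.approx(1.0)
        assert corr.pcc[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula_per_pair(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=(10, 8))
        corr = pcc_matrix(expr)
        for i in range(10):
            for j in range(10):
                x, y = expr[i] - expr[i].mean(), expr[j] - expr[j].mean()
                expected = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert corr.pcc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_flagged_invalid(self):
        expr = np.vstack([np.ones(5), np.arange(5.0)])
        corr = pcc_matrix(expr)
        assert not corr.valid[0] and corr.valid[1]
        assert np.isnan(corr.pcc[0, 1])

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pcc_matrix(np.ones((4, 2)))


class TestRankToBait:
    def test_profile_duplicate_of_bait_ranks_first(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=10)
        expr = np.vstack([base, base + 1e-9 * rng.normal(size=10),
                          rng.normal(size=(4, 10))])
        ranking = rank_to_bait(pcc_matrix(expr), "g00001")
        assert ranking.ranks["g00000"] == 1.0
        assert "g00001" not in ranking.ranks.index

    def test_hand_ordered_fixture(self):
        # bait g0; correlations engineered so g1 > g2 > g3 > g4
        t = np.linspace(0, 1, 6)
        expr = np.vstack([t, t + 0.01 * np.sin(9 * t), t ** 2,
                          np.cos(3 * t), -t])
        ranking = rank_to_bait(pcc_matrix(expr), "g00000")
        ordered = ranking.table().index.tolist()
        assert ordered == ["g00001", "g00002", "g00003", "g00004"]
        assert list(ranking.table()["rank"]) == [1, 2, 3, 4]

    def test_mutually_tied_genes_share_average_rank(self):
        base = np.arange(6.0)
        other = np.array([2.0, 5, 1, 4, 0, 3])
        expr = np.vstack([base, other, other, other])
        ranking = rank_to_bait(pcc_matrix(expr), "g00000")
        assert set(ranking.ranks) == {2.0}  # (1+2+3)/3

    def test_zero_variance_bait_rejected(self):
        expr = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="zero variance"):
            rank_to_bait(pcc_matrix(expr), "g00000")


class TestMutualRank:
    def test_geometric_mean_of_directed_ranks(self):
        # reciprocal best partners have mr exactly 1
        rng = np.random.default_rng(3)
        base = rng.normal(size=12)
        expr = np.vstack([base, base + 1e-6 * rng.normal(size=12),
                          rng.normal(size=(5, 12))])
        net = mutual_rank(pcc_matrix(expr))
        assert net.mr[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        expr = rng.normal(size=(10, 7))
        corr = pcc_matrix(expr)
        net = mutual_rank(corr)
        expected = naive_mutual_rank(corr.pcc)
        np.testing.assert_allclose(net.mr, expected, atol=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(size=(15, 9))
        net = mutual_rank(pcc_matrix(expr))
        off = ~np.eye(15, dtype=bool)
        np.testing.assert_allclose(net.mr, net.mr.T, atol=1e-12)
        assert np.all(net.mr[off] >= 1.0)
        assert np.all(net.mr[off] <= 14.0)

    def test_permuting_genes_permutes_the_network(self):
        rng = np.random.default_rng(10)
        expr = rng.normal(size=(8, 6))
        net = mutual_rank(pcc_matrix(expr))
        perm = rng.permutation(8)
        net_p = mutual_rank(pcc_matrix(
            expr[perm], gene_ids=np.array([f"g{i:05d}" for i in perm],
                                          dtype=object)))
        np.testing.assert_allclose(net_p.mr, net.mr[np.ix_(perm, perm)],
                                   atol=1e-12)


class TestMrEdges:
    def _net(self, mr_vals):
        n = mr_vals.shape[0]
        ids = np.array([f"g{i:05d}" for i in range(n)], dtype=object)
        return MutualRankNetwork(mr=mr_vals, gene_ids=ids)

    def test_threshold_is_strict(self):
        mr = np.full((3, 3), np.nan)
        mr[0, 1] = mr[1, 0] = 19.99
        mr[0, 2] = mr[2, 0] = 20.0
        mr[1, 2] = mr[2, 1] = 25.0
        edges = mr_edges(self._net(mr), threshold=20.0)
        assert len(edges) == 1
        assert tuple(edges.iloc[0][["gene_i", "gene_j"]]) == ("g00000",
                                                             "g00001")

    def test_threshold_one_yields_empty_graph(self):
        rng = np.random.default_rng(11)
        net = mutual_rank(pcc_matrix(rng.normal(size=(6, 5))))
        assert len(mr_edges(net, threshold=1.0)) == 0

    def test_edges_match_brute_force_filter(self):
        rng = np.random.default_rng(12)
        net = mutual_rank(pcc_matrix(rng.normal(size=(6, 5))))
        edges = mr_edges(net, threshold=3.0)
        expected = {(i, j) for i in range(6) for j in range(i + 1, 6)
                    if net.mr[i, j] < 3.0}
        got = {(int(r.gene_i[1:]), int(r.gene_j[1:]))
               for r in edges.itertuples()}
        assert got == expected
        assert list(edges["mr"]) == sorted(edges["mr"])


class TestCompareRankings:
    def _ranking(self, mapping, bait="bait"):
        from coexmod import CorrelationRanking
        s = pd.Series(mapping, dtype=float)
        return CorrelationRanking(bait=bait, ranks=s,
                                  pcc_values=s * 0.0)

    def test_all_improved_and_identical_cases(self):
        a = self._ranking({"x": 10, "y": 30})
        b = self._ranking({"x": 2, "y": 3})
        df, summary = compare_rankings(a, b, ["x", "y"])
        assert summary["n_improved"] == 2
        df2, summary2 = compare_rankings(a, a, ["x", "y"])
        assert summary2["n_improved"] == 0
        assert summary2["median_fold_change"] == pytest.approx(1.0)

    def test_missing_gene_listed_but_excluded_from_summary(self):
        a = self._ranking({"x": 10})
        b = self._ranking({"x": 5, "z": 1})
        df, summary = compare_rankings(a, b, ["x", "z"])
        assert summary["n_compared"] == 1
        assert summary["n_absent"] == 1
        assert np.isnan(df.loc["z", "rank_a"])
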