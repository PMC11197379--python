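import numpy as np
import pandas as pd
import pytest

from smnchart import (
    ExpressionMatrix,
    accumulate_smn_expression,
    distance_to_group,
    find_spatial_neighborhood,
    neighbor_composition,
    neighbor_enrichment_test,
    smn_distance,
    spatial_gradient,
)
from smnchart.neighborhood import graph_distance_matrix, group_distance_profile
from smnchart.smn import SMNGraph


def make_graph(n, edges, labels=None):
    ids = [f"c{i}" for i in range(n)]
    return SMNGraph(
        node_ids=ids,
        edges={frozenset((ids[a], ids[b])) for a, b in edges},
        k_requested=1,
        node_labels={ids[i]: l for i, l in enumerate(labels)} if labels else None,
    )


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return make_graph(n, edges), edges


def floyd_warshall_oracle(n, edges):
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for a, b in edges:
        D[a, b] = D[b, a] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


class TestSmnDistance:
    def test_path_graph(self):
        g = make_graph(3, [(0, 1), (1, 2)])
        assert smn_distance(g, "c0", "c2") == 2

    def test_self_distance_zero(self):
        g = make_graph(3, [(0, 1), (1, 2)])
        assert smn_distance(g, "c1", "c1") == 0

    def test_unreachable_is_infinite(self):
        g = make_graph(4, [(0, 1)])
        assert np.isinf(smn_distance(g, "c0", "c3"))

    def test_unknown_node_rejected(self):
        g = make_graph(2, [(0, 1)])
        with pytest.raises(KeyError):
            smn_distance(g, "c0", "zz")

    def test_matches_floyd_warshall(self):
        g, edges = random_graph(30, 0.12, seed=0)
        expected = floyd_warshall_oracle(30, edges)
        got = graph_distance_matrix(g).to_numpy()
        np.testing.assert_array_equal(got, expected)


class TestDistanceToGroup:
    def test_mean_of_two(self):
        g = make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        # from c0: c1 at distance 1, c3 at distance 3
        assert distance_to_group(g, "c0", ["c1", "c3"], k=2) == 2.0

    def test_nearest_only(self):
        g = make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert distance_to_group(g, "c0", ["c1", "c3"], k=1) == 1.0

    def test_empty_group_rejected(self):
        g = make_graph(2, [(0, 1)])
        with pytest.raises(ValueError):
            distance_to_group(g, "c0", [], k=1)

    def test_matches_brute_force(self):
        g, edges = random_graph(25, 0.15, seed=1)
        fw = floyd_warshall_oracle(25, edges)
        rng = np.random.default_rng(2)
        members = rng.choice(25, size=12, replace=False)
        A = [f"c{m}" for m in members]
        for x in range(25):
            d = np.sort(fw[x, members])
            d = d[np.isfinite(d)]
            expected = d[:5].mean() if d.size else np.inf
            got = distance_to_group(g, f"c{x}", A, k=5)
            assert got == pytest.approx(expected)

    def test_profile_matches_pointwise(self):
        g, _ = random_graph(15, 0.2, seed=3)
        A = ["c0", "c3", "c7"]
        prof = group_distance_profile(g, A, k=2)
        for x in g.node_ids:
            assert prof.values[x] == pytest.approx(
                distance_to_group(g, x, A, k=2)
            )

    def test_adding_edge_never_increases_distance(self):
        g, edges = random_graph(12, 0.15, seed=4)
        A = ["c1", "c5"]
        before = group_distance_profile(g, A, k=2).values
        candidates = [
            (i, j)
            for i in range(12)
            for j in range(i + 1, 12)
            if (i, j) not in edges
        ]
        extra = candidates[0]
        g2 = make_graph(12, edges + [extra])
        after = group_distance_profile(g2, A, k=2).values
        assert np.all(after.to_numpy() <= before.to_numpy() + 1e-12)


class TestAccumulateExpression:
    def _expr(self, counts, n):
        return ExpressionMatrix(
            counts=np.asarray(counts, dtype=float),
            gene_ids=[f"g{i}" for i in range(len(counts))],
            obs_ids=[f"c{i}" for i in range(n)],
        )

    def test_two_neighbor_sum(self):
        # c0's neighbors are c1 ([1,3]) and c2 ([2,4]) -> [3, 7]
        g = make_graph(3, [(0, 1), (0, 2)])
        expr = self._expr([[0, 1, 2], [0, 3, 4]], 3)
        acc = accumulate_smn_expression(expr, g)
        np.testing.assert_allclose(acc.loc["c0"], [3, 7])

    def test_isolated_cell_zero_row(self, caplog):
        g = make_graph(3, [(0, 1)])
        expr = self._expr([[1, 1, 1]], 3)
        acc = accumulate_smn_expression(expr, g)
        np.testing.assert_allclose(acc.loc["c2"], [0])

    def test_matches_adjacency_product(self):
        g, edges = random_graph(20, 0.2, seed=5)
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 6, size=(7, 20)).astype(float)
        expr = self._expr(counts, 20)
        adj = np.zeros((20, 20))
        for a, b in edges:
            adj[a, b] = adj[b, a] = 1
        expected = adj @ counts.T
        acc = accumulate_smn_expression(expr, g)
        np.testing.assert_allclose(acc.to_numpy(), expected)


class TestFindSpatialNeighborhood:
    def _blobs(self, seed=0):
        """Two compositionally distinct groups: disjoint elevated gene blocks."""
        rng = np.random.default_rng(seed)
        acc = np.abs(rng.normal(loc=1.0, scale=0.3, size=(60, 12)))
        acc[:30, :6] += 30.0
        acc[30:, 6:] += 30.0
        return pd.DataFrame(acc, index=[f"c{i}" for i in range(60)])

    def test_two_blobs_recovered(self):
        acc = self._blobs()
        res = find_spatial_neighborhood(acc, K_range=range(2, 6), seed=0)
        assert res.K == 2
        labels = res.labels.to_numpy()
        assert len(set(labels[:30])) == 1
        assert len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_forced_k(self):
        acc = self._blobs()
        res = find_spatial_neighborhood(acc, K_range=[3], seed=0)
        assert res.K == 3

    def test_permutation_invariant_partition(self):
        acc = self._blobs()
        res = find_spatial_neighborhood(acc, K_range=range(2, 5), seed=0)
        perm = np.random.default_rng(1).permutation(len(acc))
        res2 = find_spatial_neighborhood(acc.iloc[perm], K_range=range(2, 5), seed=0)
        # same partition up to label names: compare co-membership
        l1 = res.labels.loc[acc.index].to_numpy()
        l2 = res2.labels.loc[acc.index].to_numpy()
        same1 = l1[:, None] == l1[None, :]
        same2 = l2[:, None] == l2[None, :]
        np.testing.assert_array_equal(same1, same2)

    def test_markers_identify_blob_genes(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(2.0, size=(40, 10)).astype(float)
        base[:20, 0] += 50  # gene 0 marks cluster of first 20 cells
        acc = pd.DataFrame(base, index=[f"c{i}" for i in range(40)])
        res = find_spatial_neighborhood(acc, K_range=[2], seed=0)
        cluster_of_first = res.labels.iloc[0]
        top = res.markers[int(cluster_of_first)].iloc[0]
        assert top["gene"] == 0 or str(top["gene"]) == "0"


class TestComposition:
    def test_single_type(self):
        g = make_graph(3, [(0, 1), (1, 2)], labels=["t", "t", "t"])
        table = neighbor_composition(g, g.node_labels)
        assert table.fractions.loc["t", "t"] == 1.0

    def test_bipartite_types(self):
        g = make_graph(4, [(0, 2), (0, 3), (1, 2)], labels=["A", "A", "B", "B"])
        table = neighbor_composition(g, g.node_labels)
        assert table.fractions.loc["A", "B"] == 1.0
        assert table.fractions.loc["A", "A"] == 0.0

    def test_rows_sum_to_one_and_match_tally(self):
        g, edges = random_graph(15, 0.25, seed=7)
        rng = np.random.default_rng(8)
        types = ["x", "y", "z"]
        ann = {n: types[rng.integers(0, 3)] for n in g.node_ids}
        table = neighbor_composition(g, ann)
        sums = table.fractions.sum(axis=1)
        for t, s in sums.items():
            if table.counts.loc[t].sum() > 0:
                assert s == pytest.approx(1.0)
        # brute-force tally over the types that actually occur
        present = list(table.counts.index)
        tally = {(a, b): 0 for a in present for b in present}
        for i, j in edges:
            ti, tj = ann[f"c{i}"], ann[f"c{j}"]
            tally[(ti, tj)] += 1
            tally[(tj, ti)] += 1
        for a in present:
            for b in present:
                assert table.counts.loc[a, b] == tally[(a, b)]

    def test_unannotated_rejected(self):
        g = make_graph(3, [(0, 1)], labels=["a", "a", "a"])
        with pytest.raises(ValueError):
            neighbor_composition(g, {"c0": "a", "c1": "a"})


class TestEnrichment:
    def test_constructed_enrichment(self):
        # query cells c0..c3 each have two T neighbors; others have none
        edges = [(0, 8), (0, 9), (1, 8), (1, 9), (2, 8), (2, 9), (3, 8), (3, 9), (4, 5), (6, 7)]
        labels = ["Q"] * 4 + ["O"] * 4 + ["T"] * 2
        g = make_graph(10, edges, labels=labels)
        res = neighbor_enrichment_test(g, g.node_labels, "Q")
        top = res.iloc[0]
        assert top["neighbor_type"] == "T"
        others = res[res["neighbor_type"] != "T"]
        assert top["padj"] < others["padj"].min()

    def test_identical_distributions_flat_p(self):
        # every cell, query or not, has exactly one neighbor of type "t"
        edges = [(0, 4), (1, 5), (2, 4), (3, 5), (4, 5)]
        labels = ["q", "q", "o", "o", "t", "t"]
        g = make_graph(6, edges, labels=labels)
        res = neighbor_enrichment_test(g, g.node_labels, "q")
        row = res[res["neighbor_type"] == "t"].iloc[0]
        assert row["pvalue"] == pytest.approx(1.0)

    def test_single_neighbor_type_identity_adjustment(self):
        g = make_graph(4, [(0, 1), (1, 2), (2, 3)], labels=["t"] * 4)
        res = neighbor_enrichment_test(g, g.node_labels, "t")
        assert len(res) == 1
        assert res.iloc[0]["padj"] == res.iloc[0]["pvalue"]


class TestSpatialGradient:
    def _layered_line(self, n=30):
        """Path graph whose position index is also a gene's expression."""
        edges = [(i, i + 1) for i in range(n - 1)]
        g = make_graph(n, edges)
        counts = np.vstack([np.arange(n, dtype=float), np.ones(n)])
        expr = ExpressionMatrix(
            counts=counts, gene_ids=["position_gene", "flat_gene"],
            obs_ids=[f"c{i}" for i in range(n)],
        )
        return g, expr

    def test_monotone_gene_tracks_distance(self):
        from scipy.stats import spearmanr

        g, expr = self._layered_line()
        trace, dist = spatial_gradient(
            g, expr, reference_group=["c0"], genes=["position_gene"], k=1, window=1
        )
        rho = spearmanr(trace["position_gene"], dist).statistic
        assert rho > 0.8

    def test_constant_gene_flat(self):
        g, expr = self._layered_line()
        trace, _ = spatial_gradient(
            g, expr, reference_group=["c0"], genes=["flat_gene"], k=1, window=5
        )
        assert trace["flat_gene"].nunique() == 1

    def test_reference_all_cells_zero_distance(self):
        g, expr = self._layered_line(10)
        trace, dist = spatial_gradient(
            g, expr, reference_group=list(g.node_ids), genes=["flat_gene"], k=1
        )
        assert np.all(dist.to_numpy() == 0)
        assert list(trace.index) == list(g.node_ids)

    def test_missing_gene_rejected(self):
        g, expr = self._layered_line(5)
        with pytest.raises(KeyError):
            spatial_gradient(g, expr, ["c0"], genes=["absent"])
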