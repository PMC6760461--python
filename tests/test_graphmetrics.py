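"""Graph measures against exhaustive oracles; surrogate null models."""

import networkx as nx
import numpy as np
import pytest

import hyperconn as hc
from hyperconn.graphmetrics import SurrogateEnsemble

from conftest import random_simple_graph


def floyd_warshall_path_length(m):
    """Brute-force oracle: mean finite shortest-path over ordered pairs."""
    n = m.shape[0]
    INF = float("inf")
    d = [[0 if i == j else (1 if m[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    vals = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF]
    return sum(vals) / len(vals)


def triangle_clustering(m):
    """Brute-force oracle: per-node triangle counting."""
    n = m.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if m[i][j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if m[nbrs[a]][nbrs[b]]
        )
        cs.append(links / (k * (k - 1) / 2))
    return sum(cs) / n


class TestPathLength:
    def test_complete_graph_has_unit_path_length(self):
        m = 1 - np.eye(4, dtype=int)
        assert hc.characteristic_path_length(m) == pytest.approx(1.0)

    def test_three_node_path_hand_enumeration(self):
        m = np.zeros((3, 3), dtype=int)
        m[0, 1] = m[1, 0] = m[1, 2] = m[2, 1] = 1
        assert hc.characteristic_path_length(m) == pytest.approx(4 / 3)

    def test_matches_floyd_warshall_oracle_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            m = random_simple_graph(rng, n, p=float(rng.uniform(0.15, 0.7)))
            assert hc.characteristic_path_length(m) == pytest.approx(
                floyd_warshall_path_length(m)
            )

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            hc.characteristic_path_length(np.zeros((4, 4), dtype=int))


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        m = 1 - np.eye(3, dtype=int)
        assert hc.mean_clustering_coefficient(m) == pytest.approx(1.0)

    def test_star_graph_has_zero_clustering(self):
        m = np.zeros((5, 5), dtype=int)
        m[0, 1:] = m[1:, 0] = 1
        assert hc.mean_clustering_coefficient(m) == pytest.approx(0.0)

    def test_k4_minus_edge_matches_triangle_counting(self):
        m = 1 - np.eye(4, dtype=int)
        m[0, 1] = m[1, 0] = 0
        assert hc.mean_clustering_coefficient(m) == pytest.approx(
            triangle_clustering(m)
        )

    def test_matches_oracles_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 16))
            m = random_simple_graph(rng, n, p=float(rng.uniform(0.2, 0.7)))
            mine = hc.mean_clustering_coefficient(m)
            assert mine == pytest.approx(triangle_clustering(m))
            assert mine == pytest.approx(
                nx.average_clustering(nx.from_numpy_array(m), count_zeros=True)
            )


class TestSurrogates:
    @pytest.mark.parametrize("kind", ["random", "lattice"])
    def test_degree_sequence_preserved_single_brain(self, kind):
        rng = np.random.default_rng(12)
        m = random_simple_graph(rng, 20, p=0.25)
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(20)], matrix=m, brain_sizes=(20,)
        )
        ens = hc.generate_surrogates(adj, kind, n_surrogates=10, seed=0)
        for s in ens.matrices:
            np.testing.assert_array_equal(s.sum(axis=0), m.sum(axis=0))
            assert np.array_equal(s, s.T)
            assert np.all(np.diag(s) == 0)

    @pytest.mark.parametrize("kind", ["random", "lattice"])
    def test_block_degree_sequences_preserved_hyperbrain(self, kind, hyper_lps):
        adj = hc.binarize(hyper_lps)
        ens = hc.generate_surrogates(adj, kind, n_surrogates=5, seed=1)
        m = adj.matrix
        for s in ens.matrices:
            for sl_a, sl_b in [
                (slice(0, 26), slice(0, 26)),
                (slice(26, 52), slice(26, 52)),
                (slice(0, 26), slice(26, 52)),
                (slice(26, 52), slice(0, 26)),
            ]:
                np.testing.assert_array_equal(
                    s[sl_a, sl_b].sum(axis=1), m[sl_a, sl_b].sum(axis=1)
                )

    def test_random_rewiring_changes_the_graph(self):
        rng = np.random.default_rng(13)
        m = random_simple_graph(rng, 30, p=0.2)
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(30)], matrix=m, brain_sizes=(30,)
        )
        ens = hc.generate_surrogates(adj, "random", n_surrogates=3, seed=2)
        assert any(not np.array_equal(s, m) for s in ens.matrices)

    def test_ring_lattice_is_fixed_point_of_latticization(self):
        n = 20
        g = nx.watts_strogatz_graph(n, 4, 0.0)  # pure ring lattice
        m = nx.to_numpy_array(g, dtype=int)
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(n)], matrix=m, brain_sizes=(n,)
        )
        ens = hc.generate_surrogates(adj, "lattice", n_surrogates=3, seed=3)
        l0 = hc.characteristic_path_length(m)
        c0 = hc.mean_clustering_coefficient(m)
        assert ens.mean_path_length == pytest.approx(l0, rel=0.05)
        assert ens.mean_clustering == pytest.approx(c0, rel=0.05)

    def test_watts_strogatz_orderings(self):
        """Small-world inputs sit between their random and lattice nulls."""
        rng = np.random.default_rng(14)
        l_ok = c_ok = 0
        n_seeds = 12
        for k in range(n_seeds):
            g = nx.connected_watts_strogatz_graph(
                26, 4, 0.2, seed=int(rng.integers(1 << 30))
            )
            m = nx.to_numpy_array(g, dtype=int)
            adj = hc.AdjacencyMatrix(
                labels=[f"n{i}" for i in range(26)], matrix=m, brain_sizes=(26,)
            )
            rnd = hc.generate_surrogates(adj, "random", 8, seed=k)
            lat = hc.generate_surrogates(adj, "lattice", 8, seed=k)
            l_obs = hc.characteristic_path_length(adj)
            c_obs = hc.mean_clustering_coefficient(adj)
            if rnd.mean_path_length < l_obs < lat.mean_path_length:
                l_ok += 1
            if rnd.mean_clustering < c_obs < lat.mean_clustering:
                c_ok += 1
        assert l_ok >= n_seeds - 2
        assert c_ok >= n_seeds - 2

    def test_too_sparse_block_copies_with_warning(self):
        m = np.zeros((6, 6), dtype=int)
        m[0, 1] = m[1, 0] = 1
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(6)], matrix=m, brain_sizes=(6,)
        )
        with pytest.warns(UserWarning, match="too few edges"):
            ens = hc.generate_surrogates(adj, "random", 2, seed=4)
        np.testing.assert_array_equal(ens.matrices[0], m)


class TestNormalizedMeasures:
    def ens(self, L=None, C=None):
        return SurrogateEnsemble(
            kind="random",
            matrices=[],
            mean_path_length=L if L is not None else 1.0,
            mean_clustering=C if C is not None else 0.5,
        )

    def test_ratio_convention_arithmetic(self):
        assert hc.normalized_global_efficiency(2.0, self.ens(L=1.0)) == 0.5
        assert hc.normalized_global_efficiency(1.0, self.ens(L=1.0)) == 1.0
        # shorter-than-random paths clip at 1
        assert hc.normalized_global_efficiency(0.8, self.ens(L=1.0)) == 1.0
        assert hc.normalized_clustering(0.3, None, self.ens(C=0.6)) == 0.5
        assert hc.normalized_clustering(0.0, None, self.ens(C=0.6)) == 0.0
        assert hc.normalized_clustering(0.9, None, self.ens(C=0.6)) == 1.0

    def test_interpolation_convention(self):
        rand, latt = self.ens(L=1.5, C=0.1), self.ens(L=3.0, C=0.7)
        assert hc.normalized_global_efficiency(
            1.5, rand, latt, "interpolation"
        ) == 1.0
        assert hc.normalized_global_efficiency(
            2.25, rand, latt, "interpolation"
        ) == 0.5
        assert hc.normalized_clustering(0.4, rand, latt, "interpolation") == (
            pytest.approx(0.5)
        )

    def test_degenerate_interpolation_rejected(self):
        same = self.ens(L=2.0)
        with pytest.raises(ValueError, match="degenerate"):
            hc.normalized_global_efficiency(1.0, same, same, "interpolation")

    @pytest.mark.parametrize(
        "g,c,expected", [(1.0, 1.0, 1.0), (0.0, 0.7, 0.0), (0.8, 0.5, 0.4)]
    )
    def test_small_world_index_is_product(self, g, c, expected):
        assert hc.small_world_index(g, c) == pytest.approx(expected)

    def test_small_world_index_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            hc.small_world_index(1.2, 0.5)


class TestDensityAndIIR:
    def test_density_examples(self, small_adjacency):
        assert hc.connection_density(small_adjacency) == pytest.approx(0.4)
        empty = hc.AdjacencyMatrix(
            labels=["a", "b", "c"], matrix=np.zeros((3, 3), int), brain_sizes=(3,)
        )
        assert hc.connection_density(empty) == 0.0

    def test_complete_hyperbrain_density_denominator(self):
        full = 1 - np.eye(52, dtype=int)
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(52)],
            matrix=full,
            brain_sizes=(26, 26),
        )
        assert adj.n_edges == 1326
        assert hc.connection_density(adj) == pytest.approx(1.0)

    def test_iir_hand_example(self):
        # 10 + 12 intra edges and 11 inter edges -> IIR = 2
        rng = np.random.default_rng(15)
        m = np.zeros((12, 12), dtype=int)

        def add_intra(block, count, rng):
            added = 0
            while added < count:
                i, j = rng.integers(block.start, block.stop, 2)
                if i != j and not m[i, j]:
                    m[i, j] = m[j, i] = 1
                    added += 1

        add_intra(slice(0, 6), 10, rng)
        add_intra(slice(6, 12), 12, rng)
        added = 0
        while added < 11:
            i = int(rng.integers(0, 6))
            j = int(rng.integers(6, 12))
            if not m[i, j]:
                m[i, j] = m[j, i] = 1
                added += 1
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(12)], matrix=m, brain_sizes=(6, 6)
        )
        assert hc.intra_inter_ratio(adj) == pytest.approx(2.0)

    def test_iir_undefined_when_no_inter_edges(self):
        m = np.zeros((8, 8), dtype=int)
        m[0, 1] = m[1, 0] = m[4, 5] = m[5, 4] = 1
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(8)], matrix=m, brain_sizes=(4, 4)
        )
        with pytest.warns(UserWarning, match="IIR undefined"):
            assert np.isnan(hc.intra_inter_ratio(adj))

    def test_balanced_counts_give_unit_ratio(self):
        m = np.zeros((6, 6), dtype=int)
        m[0, 1] = m[1, 0] = 1  # 1 intra-J1
        m[3, 4] = m[4, 3] = 1  # 1 intra-J2
        m[0, 3] = m[3, 0] = m[1, 4] = m[4, 1] = 1  # 2 inter
        adj = hc.AdjacencyMatrix(
            labels=[f"n{i}" for i in range(6)], matrix=m, brain_sizes=(3, 3)
        )
        assert hc.intra_inter_ratio(adj) == pytest.approx(1.0)
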