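import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import eigh as scipy_eigh

from passnet.spatial import UndefinedMetricError
from passnet.topology import (algebraic_connectivity, average_shortest_path,
                              eigenvector_centrality, largest_eigenvalue,
                              symmetrized_weights, weighted_clustering)

import _oracles as oracle


def complete_graph(n=11, w=1.0):
    A = np.full((n, n), float(w))
    np.fill_diagonal(A, 0.0)
    return A


def star_graph(n=11, w=1.0):
    A = np.zeros((n, n))
    A[0, 1:] = A[1:, 0] = w
    return A


def random_digraph(rng, n=11, density=0.4, max_w=5):
    W = rng.integers(0, max_w + 1, size=(n, n)).astype(float)
    W[rng.random((n, n)) > density] = 0.0
    np.fill_diagonal(W, 0.0)
    return W


class TestSymmetrization:
    def test_pairwise_totals(self):
        W = np.zeros((11, 11))
        W[0, 1], W[1, 0] = 3, 1
        A = symmetrized_weights(W)
        assert A[0, 1] == A[1, 0] == 4

    def test_symmetric_input_doubles(self):
        A = complete_graph(w=2.0)
        np.testing.assert_array_equal(symmetrized_weights(A), 2 * A)

    def test_output_is_symmetric(self):
        W = random_digraph(np.random.default_rng(0))
        A = symmetrized_weights(W)
        np.testing.assert_array_equal(A, A.T)


class TestWeightedClustering:
    def test_uniform_complete_graph_is_one(self):
        assert weighted_clustering(complete_graph()) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        assert weighted_clustering(star_graph()) == pytest.approx(0.0)

    def test_four_node_toy_vs_triple_loop(self):
        W = np.array([[0, 3, 1, 0],
                      [1, 0, 2, 0],
                      [0, 0, 0, 4],
                      [2, 0, 1, 0]], dtype=float)
        assert weighted_clustering(W) == pytest.approx(
            oracle.clustering_triple_loop(symmetrized_weights(W)))

    def test_exhaustive_small_graphs_vs_triple_loop(self):
        # every symmetric 4-node graph with weights in {0..3}
        idx = list(itertools.combinations(range(4), 2))
        for weights in itertools.product(range(4), repeat=len(idx)):
            A = np.zeros((4, 4))
            for (i, j), w in zip(idx, weights):
                A[i, j] = A[j, i] = w
            got = weighted_clustering(A / 2.0)  # /2: A is already symmetric
            want = oracle.clustering_triple_loop(A)
            assert got == pytest.approx(want, abs=1e-12)

    def test_sampled_five_node_graphs_vs_triple_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            W = rng.integers(0, 4, size=(5, 5)).astype(float)
            np.fill_diagonal(W, 0.0)
            A = symmetrized_weights(W)
            assert weighted_clustering(W) == pytest.approx(
                oracle.clustering_triple_loop(A), abs=1e-12)

    def test_binary_graph_reduces_to_unweighted_clustering(self):
        # on a {0,1} symmetric graph the formula counts closed triples
        # over connected pairs of neighbours: the classical coefficient
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = (rng.random((7, 7)) < 0.5).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            got = weighted_clustering(A / 2.0)
            # independent unweighted computation
            cs = []
            for i in range(7):
                nbrs = np.flatnonzero(A[i])
                k = nbrs.size
                if k < 2:
                    cs.append(0.0)
                    continue
                links = sum(A[u, v] for u, v in
                            itertools.combinations(nbrs, 2))
                cs.append(2 * links / (k * (k - 1)))
            assert got == pytest.approx(float(np.mean(cs)), abs=1e-12)


class TestShortestPath:
    def test_uniform_complete_digraph(self):
        d, rf = average_shortest_path(complete_graph(w=1.0))
        assert d == pytest.approx(1.0)
        assert rf == 1.0

    def test_forced_indirect_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 2] = 2.0
        dist = oracle.shortest_paths_enumeration(W)
        assert dist[0, 2] == pytest.approx(1.0)   # 1/2 + 1/2
        d, rf = average_shortest_path(W)
        assert d == pytest.approx(dist[np.isfinite(dist) &
                                       ~np.eye(3, dtype=bool)].mean())
        assert rf == pytest.approx(3 / 6)

    def test_exhaustive_three_node_digraphs(self):
        cells = [(i, j) for i in range(3) for j in range(3) if i != j]
        for weights in itertools.product(range(3), repeat=len(cells)):
            W = np.zeros((3, 3))
            for (i, j), w in zip(cells, weights):
                W[i, j] = w
            if not W.any():
                continue
            d, rf = average_shortest_path(W)
            want_d, want_rf = oracle.average_path_enumeration(W)
            assert d == pytest.approx(want_d)
            assert rf == pytest.approx(want_rf)

    def test_sampled_six_node_digraphs_vs_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(150):
            W = random_digraph(rng, n=6, density=0.5, max_w=4)
            if not W.any():
                continue
            d, rf = average_shortest_path(W)
            want_d, want_rf = oracle.average_path_enumeration(W)
            assert d == pytest.approx(want_d)
            assert rf == pytest.approx(want_rf)

    def test_no_links_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            average_shortest_path(np.zeros((11, 11)))


class TestLargestEigenvalue:
    @pytest.mark.parametrize("w", [1.0, 2.5])
    def test_complete_graph_closed_form(self, w):
        # symmetrizing doubles each link: K11 at weight 2w -> lambda1 = 10*2w
        assert largest_eigenvalue(complete_graph(w=w) / 2) == \
            pytest.approx(10 * w)

    def test_empty_network(self):
        assert largest_eigenvalue(np.zeros((11, 11))) == 0.0

    def test_strength_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            W = random_digraph(rng)
            A = symmetrized_weights(W)
            lam1 = largest_eigenvalue(W)
            s = A.sum(axis=1)
            assert lam1 >= max(s.mean(), np.sqrt(s.max())) - 1e-9
            assert lam1 <= s.max() + 1e-9

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            W = random_digraph(rng, n=8)
            lam, _ = oracle.power_iteration(symmetrized_weights(W))
            assert largest_eigenvalue(W) == pytest.approx(lam, rel=1e-8)


class TestAlgebraicConnectivity:
    def test_two_disconnected_cliques(self):
        A = np.zeros((6, 6))
        A[:3, :3] = complete_graph(3, w=2.0)
        A[3:, 3:] = complete_graph(3, w=5.0)
        assert algebraic_connectivity(A / 2) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("w", [1.0, 3.0])
    def test_complete_graph_closed_form(self, w):
        assert algebraic_connectivity(complete_graph(11, w=w) / 2) == \
            pytest.approx(11 * w)

    def test_matches_independent_dense_eigensolver(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            W = random_digraph(rng)
            A = symmetrized_weights(W)
            L = np.diag(A.sum(axis=1)) - A
            want = sorted(scipy_eigh(L, eigvals_only=True))[1]
            assert algebraic_connectivity(W) == pytest.approx(
                max(want, 0.0), abs=1e-8)

    def test_zero_iff_disconnected(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            W = random_digraph(rng, n=7, density=0.25)
            lam2 = algebraic_connectivity(W)
            connected = oracle.connected_union_find(W)
            if connected:
                assert lam2 > 1e-9
            else:
                assert lam2 == pytest.approx(0.0, abs=1e-9)


class TestEigenvectorCentrality:
    def test_uniform_complete_graph(self):
        ec, ec_max, ec_disp = eigenvector_centrality(complete_graph())
        np.testing.assert_allclose(ec, 1 / np.sqrt(11), atol=1e-12)
        assert ec_max == pytest.approx(1 / np.sqrt(11))
        assert ec_disp == pytest.approx(0.0, abs=1e-12)

    def test_star_closed_form(self):
        ec, ec_max, _ = eigenvector_centrality(star_graph())
        assert ec_max == pytest.approx(1 / np.sqrt(2))
        np.testing.assert_allclose(ec[1:], 1 / (np.sqrt(2) * np.sqrt(10)),
                                   atol=1e-10)
        lam, v = oracle.power_iteration(symmetrized_weights(star_graph()))
        np.testing.assert_allclose(ec, v, atol=1e-8)

    def test_disconnected_network_follows_dominant_component(self):
        A = np.zeros((11, 11))
        A[:3, :3] = complete_graph(3, w=1.0)    # lambda1 = 2 (after sym: 4)
        A[3:8, 3:8] = complete_graph(5, w=2.0)  # dominant component
        ec, _, _ = eigenvector_centrality(A)
        assert np.allclose(ec[:3], 0.0, atol=1e-9)
        assert np.allclose(ec[8:], 0.0, atol=1e-9)
        assert (ec[3:8] > 0.1).all()

    def test_empty_network_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            eigenvector_centrality(np.zeros((11, 11)))

    def test_unit_norm_and_nonnegative(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            W = random_digraph(rng)
            if not W.any():
                continue
            ec, ec_max, ec_disp = eigenvector_centrality(W)
            assert np.linalg.norm(ec) == pytest.approx(1.0)
            assert (ec >= 0).all()
            assert ec_max == pytest.approx(ec.max())
            assert ec_disp == pytest.approx(float(ec.std(ddof=0)))


@given(st.integers(1, 20), st.integers(0, 2 ** 32 - 1))
def test_scale_covariance(k, seed):
    """Multiplying all pass counts by k: C, ec unchanged; lambda1 and
    lambda2 scale by k; d scales by 1/k."""
    W = random_digraph(np.random.default_rng(seed))
    if not W.any():
        return
    kW = k * W
    assert weighted_clustering(kW) == pytest.approx(weighted_clustering(W))
    assert largest_eigenvalue(kW) == pytest.approx(k * largest_eigenvalue(W))
    assert algebraic_connectivity(kW) == pytest.approx(
        k * algebraic_connectivity(W), abs=1e-8)
    d1, rf1 = average_shortest_path(W)
    dk, rfk = average_shortest_path(kW)
    assert dk == pytest.approx(d1 / k)
    assert rfk == rf1
    ec1, m1, s1 = eigenvector_centrality(W)
    eck, mk, sk = eigenvector_centrality(kW)
    np.testing.assert_allclose(eck, ec1, atol=1e-9)
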