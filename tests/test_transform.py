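import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import pinvh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

import networkx as nx

from netsig import (
    WeightedGraph,
    adjacency_distance,
    distance_to_graph,
    double_center,
    graph_signals,
    graph_to_signals,
    laplacian,
    make_erdos_renyi,
    make_k_regular,
    make_weighted_sbm,
    BlockSpec,
    resistance_distance,
    signals_to_distance,
    stress,
    validate_distance,
)
from netsig.graph import GraphConnectivityError, GraphValidationError
from netsig.transform import (
    DistanceMatrix,
    GraphSignals,
    InvalidResistanceError,
    NotPSDError,
    segment_plateaus,
    stress_raw,
)
from conftest import random_connected_weighted


class TestLaplacian:
    def test_two_node(self, two_node):
        assert np.allclose(laplacian(two_node), [[0.5, -0.5], [-0.5, 0.5]])

    def test_triangle_spectrum(self, unit_triangle):
        eigs = np.sort(np.linalg.eigvalsh(laplacian(unit_triangle)))
        assert np.allclose(eigs, [0, 3, 3], atol=1e-10)

    def test_empty_graph(self):
        assert np.all(laplacian(WeightedGraph(np.zeros((4, 4)))) == 0)


class TestResistanceDistance:
    def test_single_edge_is_inverse_weight(self, two_node):
        assert abs(resistance_distance(two_node).values[0, 1] - 2.0) < 1e-10

    def test_unit_triangle_two_thirds(self, unit_triangle):
        r = resistance_distance(unit_triangle).values
        off = r[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 2 / 3, atol=1e-10)

    def test_series_additivity_on_path(self, unit_path3):
        r = resistance_distance(unit_path3).values
        assert abs(r[0, 2] - 2.0) < 1e-10
        assert abs(r[0, 1] + r[1, 2] - r[0, 2]) < 1e-10

    def test_disconnected_rejected(self):
        g = WeightedGraph(np.zeros((3, 3)))
        with pytest.raises(GraphConnectivityError):
            resistance_distance(g)

    def test_dominated_by_shortest_path_with_tree_equality(self):
        # R <= hop distance for binary graphs; equality on trees (unique paths)
        for seed in range(10):
            g = make_erdos_renyi(20, 0.3, seed=seed, require_connected=True)
            r = resistance_distance(g).values
            sp = shortest_path(csr_matrix(g.weights), unweighted=True)
            assert np.all(r <= sp + 1e-8)
        for seed in range(20):
            t = nx.random_labeled_tree(15, seed=seed)
            w = nx.to_numpy_array(t)
            g = WeightedGraph(w, is_binary=True)
            r = resistance_distance(g).values
            sp = shortest_path(csr_matrix(w), unweighted=True)
            assert np.allclose(r, sp, atol=1e-8)


class TestAdjacencyDistance:
    def test_complete_graph_all_ones(self, unit_triangle):
        d = adjacency_distance(unit_triangle).values
        assert np.all(d[~np.eye(3, dtype=bool)] == 1)

    def test_four_cycle_hop_counts(self):
        g = make_k_regular(4, 2)
        d = adjacency_distance(g).values
        assert d[0, 1] == 1 and d[0, 2] == 2 and d[0, 3] == 1

    def test_two_node_edge(self):
        g = WeightedGraph(np.array([[0, 1], [1, 0]], dtype=float), is_binary=True)
        assert np.array_equal(adjacency_distance(g).values, [[0, 1], [1, 0]])

    def test_rejects_weighted_graph(self, two_node):
        with pytest.raises(GraphValidationError):
            adjacency_distance(two_node)


class TestDoubleCenter:
    def test_rows_sum_to_zero(self):
        g = random_connected_weighted(12, seed=0)
        b = double_center(resistance_distance(g)).values
        assert np.max(np.abs(b.sum(axis=1))) < 1e-10

    def test_equals_laplacian_pseudoinverse(self):
        for seed in range(5):
            g = random_connected_weighted(15, seed=seed)
            b = double_center(resistance_distance(g)).values
            assert np.allclose(b, pinvh(laplacian(g)), atol=1e-8)

    def test_two_node_hand_value(self):
        d = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), flavor="resistance")
        assert np.allclose(double_center(d).values, [[0.25, -0.25], [-0.25, 0.25]])


class TestGraphToSignals:
    def test_connected_graph_yields_n_minus_one_signals(self):
        for seed in range(20):
            g = random_connected_weighted(np.random.default_rng(seed).integers(5, 25), seed)
            assert graph_signals(g).n_signals == g.n_nodes - 1

    def test_signal_invariants(self):
        g = random_connected_weighted(20, seed=4)
        s = graph_signals(g)
        x, lam = s.signals, s.eigenvalues
        assert np.max(np.abs(x.sum(axis=0))) < 1e-8  # zero-mean columns
        gram = x.T @ x
        assert np.allclose(gram, np.diag(lam), atol=1e-8)  # orthogonal, norms = eigs
        assert np.all(np.diff(lam) <= 1e-12)  # descending

    def test_ring_signals_are_sampled_sinusoids(self):
        from netsig.features import power_spectrum

        for k, other in ((2, 10), (10, 2)):
            s = graph_signals(make_k_regular(128, k))
            p = power_spectrum(s.signals[:, 0]).power
            assert p.max() > 0.999  # all spectral mass in one bin
        amp2 = np.abs(graph_signals(make_k_regular(128, 2)).signals[:, 0]).max()
        amp10 = np.abs(graph_signals(make_k_regular(128, 10)).signals[:, 0]).max()
        assert amp2 > amp10  # amplitude inversely related to degree

    def test_sbm_leading_signals_recover_blocks(self):
        sizes = [67, 67, 66]
        z = np.repeat(np.arange(3), sizes)
        probs = np.full((3, 3), 0.05)
        np.fill_diagonal(probs, 0.3)
        hits = 0
        for seed in range(5):
            g = make_weighted_sbm(BlockSpec(z, probs), seed=seed)
            labels = segment_plateaus(graph_signals(g), 3)
            hits += int(np.array_equal(labels, z))
        assert hits >= 4

    def test_not_psd_rejected(self):
        from netsig.transform import GramMatrix

        bad = GramMatrix(np.array([[1.0, 0.0], [0.0, -1.0]]))
        with pytest.raises(NotPSDError):
            graph_to_signals(bad)

    def test_sign_convention_deterministic(self):
        g = random_connected_weighted(10, seed=2)
        s = graph_signals(g)
        for c in range(s.n_signals):
            col = s.signals[:, c]
            assert col[np.argmax(np.abs(col))] > 0


class TestInverseTransform:
    def test_squared_difference_example(self):
        s = GraphSignals(
            signals=np.array([[0.0], [1.0], [3.0]]), eigenvalues=np.array([10.0])
        )
        expect = [[0, 1, 9], [1, 0, 4], [9, 4, 0]]
        assert np.allclose(signals_to_distance(s).values, expect)

    def test_identical_rows_give_zero(self):
        s = GraphSignals(signals=np.ones((4, 2)), eigenvalues=np.array([4.0, 4.0]))
        assert np.all(signals_to_distance(s).values == 0)

    def test_unit_triangle_recovered(self, unit_triangle):
        r = resistance_distance(unit_triangle)
        g = distance_to_graph(r)
        assert np.allclose(g.weights, unit_triangle.weights, atol=1e-8)

    def test_two_node_inverse_resistance(self):
        r = DistanceMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]))
        assert abs(distance_to_graph(r).weights[0, 1] - 0.25) < 1e-10

    def test_invalid_resistance_matrix_rejected(self):
        bad = DistanceMatrix(np.array([[0, 1, 5], [1, 0, 1], [5, 1, 0]], dtype=float))
        with pytest.raises(InvalidResistanceError):
            distance_to_graph(bad)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(5, 40), seed=st.integers(0, 10_000))
    def test_roundtrip_recovers_graph(self, n, seed):
        g = make_erdos_renyi(n, 0.4, weighted=True, seed=seed, require_connected=True)
        r = resistance_distance(g)
        r_hat = signals_to_distance(graph_to_signals(double_center(r)))
        assert np.max(np.abs(r_hat.values - r.values)) < 1e-8
        g_hat = distance_to_graph(r_hat)
        assert np.max(np.abs(g_hat.weights - g.weights)) < 1e-6


class TestStress:
    def test_zero_for_identical(self, unit_triangle):
        r = resistance_distance(unit_triangle)
        assert stress(r, r) == 0.0
        assert stress_raw(r, r) == 0.0

    def test_full_rank_roundtrip_is_machine_noise(self):
        g = random_connected_weighted(30, seed=9)
        r = resistance_distance(g)
        r_hat = signals_to_distance(graph_to_signals(double_center(r)))
        assert stress(r, r_hat) < 1e-8

    def test_truncation_gives_positive_stress(self):
        g = make_k_regular(4, 2)
        r = resistance_distance(g)
        s = graph_to_signals(double_center(r))
        s1 = GraphSignals(signals=s.signals[:, :1], eigenvalues=s.eigenvalues[:1])
        assert stress(r, signals_to_distance(s1)) > 1e-3

    def test_all_zero_reference_rejected(self):
        z = DistanceMatrix(np.zeros((3, 3)))
        with pytest.raises(GraphValidationError):
            stress(z, z)


class TestValidateDistance:
    def test_resistance_distances_pass_all_axioms(self):
        for seed in range(10):
            g = random_connected_weighted(15, seed=seed)
            assert validate_distance(resistance_distance(g)).ok

    def test_symmetry_violation_reported(self):
        d = np.array([[0.0, 1.1], [1.0, 0.0]])
        report = validate_distance(d)
        assert report.asymmetric_pairs == [(0, 1)]

    def test_triangle_violation_reported(self):
        d = np.array([[0, 1, 5], [1, 0, 1], [5, 1, 0]], dtype=float)
        report = validate_distance(d)
        assert (0, 1, 2) in report.triangle_violations
        assert not report.ok


def test_segment_plateaus_on_clean_steps():
    x = np.concatenate([np.zeros(10), np.ones(7), np.full(5, -2.0)])
    s = GraphSignals(signals=x[:, None], eigenvalues=np.array([1.0]))
    labels = segment_plateaus(s, 3, n_signals=1, pool=1)
    assert np.array_equal(labels, np.repeat([0, 1, 2], [10, 7, 5]))
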