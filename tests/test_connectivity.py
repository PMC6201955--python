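"""Coherence matrices, thresholded graphs, density and global efficiency."""

import networkx as nx
import numpy as np
import pytest

from cogmap.connectivity import (
    CoherenceMatrix,
    FunctionalGraph,
    coherence_matrix,
    connectivity_density,
    global_efficiency,
    graph_metrics,
    percent,
    threshold_adjacency,
)
from cogmap.trace_processing import FluorescenceTrace

from conftest import random_graph


def _traces(arrays):
    return [
        FluorescenceTrace(f"n{k}", np.asarray(a, float)) for k, a in enumerate(arrays)
    ]


def _graph(A):
    return FunctionalGraph([str(i) for i in range(A.shape[0])], A, 0.45)


def _graph_with_edges(K, m, seed=0):
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    A = np.zeros((K, K), int)
    for k in rng.choice(len(pairs), size=m, replace=False):
        i, j = pairs[k]
        A[i, j] = A[j, i] = 1
    return _graph(A)


class TestCoherenceMatrix:
    def test_self_correlation_is_one_and_negation_minus_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        C = coherence_matrix(_traces([x, x, -x]))
        assert C.rho[0, 0] == 1.0
        assert C.rho[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C.rho[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_double_loop_formula(self):
        # brute-force oracle: evaluate the centered cross-product formula
        # pair by pair
        rng = np.random.default_rng(1)
        V = rng.standard_normal((3, 5000))
        C = coherence_matrix(_traces(V))
        for i in range(3):
            for j in range(3):
                vi, vj = V[i] - V[i].mean(), V[j] - V[j].mean()
                rho = np.sum(vi * vj) / np.sqrt(np.sum(vi**2) * np.sum(vj**2))
                assert abs(C.rho[i, j] - rho) < 1e-12
        # and agrees with the standard library implementation
        assert np.allclose(C.rho, np.corrcoef(V), atol=1e-12)

    def test_constant_trace_flagged_and_zeroed(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning):
            C = coherence_matrix(_traces([rng.standard_normal(100), np.ones(100)]))
        assert C.constant[1]
        assert C.rho[0, 1] == 0.0
        assert C.rho[1, 1] == 1.0

    def test_window_selects_samples(self):
        x = np.concatenate([np.zeros(250), np.arange(250.0)])
        y = np.concatenate([np.zeros(250), np.arange(250.0)[::-1]])
        C = coherence_matrix(_traces([x, y]), window=(1.0, 2.0))
        assert C.rho[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert C.n_samples == 250


class TestThresholdAdjacency:
    def test_zero_matrix_gives_empty_graph(self):
        C = CoherenceMatrix(["a", "b", "c"], np.eye(3), 100, np.zeros(3, bool))
        assert threshold_adjacency(C, 0.45).m == 0

    def test_constructed_pairs_above_threshold(self):
        rho = np.eye(4)
        for i, j in [(0, 1), (1, 2), (0, 3)]:
            rho[i, j] = rho[j, i] = 0.6
        C = CoherenceMatrix(list("abcd"), rho, 100, np.zeros(4, bool))
        assert threshold_adjacency(C, 0.45).m == 3

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 200))
        C = coherence_matrix(_traces(X))
        counts = [threshold_adjacency(C, th).m for th in np.linspace(-0.9, 0.9, 19)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_significance_gate_prunes_weak_edges(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.5
        C = CoherenceMatrix(list("abc"), rho, 10, np.zeros(3, bool))
        loose = threshold_adjacency(C, 0.45, require_significance=False)
        strict = threshold_adjacency(C, 0.45, require_significance=True)
        assert loose.m == 1 and strict.m == 0  # r=0.5, n=10: p ~ 0.14

    def test_invalid_threshold_rejected(self):
        C = CoherenceMatrix(["a", "b"], np.eye(2), 100, np.zeros(2, bool))
        with pytest.raises(ValueError):
            threshold_adjacency(C, 1.5)


class TestDensity:
    def test_worked_examples_80_cells(self):
        # 80 imaged cells: 134 edges -> 4.2%, 81 edges -> 2.5%
        assert percent(connectivity_density(_graph_with_edges(80, 134))) == 4.2
        assert percent(connectivity_density(_graph_with_edges(80, 81))) == 2.5

    def test_complete_graph_density_one(self):
        A = 1 - np.eye(5, dtype=int)
        assert connectivity_density(_graph(A)) == 1.0

    def test_formula_for_constructed_graphs(self):
        for K, m in [(10, 0), (10, 17), (12, 30)]:
            G = _graph_with_edges(K, m, seed=K)
            assert connectivity_density(G) == pytest.approx(2 * m / (K * (K - 1)))


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        assert global_efficiency(_graph(1 - np.eye(6, dtype=int))) == 1.0

    def test_edgeless_graph_is_zero(self):
        assert global_efficiency(_graph(np.zeros((5, 5), int))) == 0.0

    def test_path_graph_hand_enumerated(self):
        # P4 distances {1,1,1,2,2,3}: E = 2*(3 + 2/2 + 1/3)/12 = 0.7222...
        A = np.zeros((4, 4), int)
        for i in range(3):
            A[i, i + 1] = A[i + 1, i] = 1
        assert global_efficiency(_graph(A)) == pytest.approx(13.0 / 18.0, abs=1e-12)

    def test_matches_floyd_warshall_oracle(self, fw_efficiency):
        rng = np.random.default_rng(4)
        for _ in range(50):
            K = int(rng.integers(2, 13))
            A = random_graph(K, rng.uniform(0.05, 0.9), rng)
            G = _graph(A)
            assert abs(global_efficiency(G) - fw_efficiency(A)) < 1e-12

    def test_matches_networkx(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            A = random_graph(int(rng.integers(3, 15)), rng.uniform(0.1, 0.8), rng)
            G = _graph(A)
            assert global_efficiency(G) == pytest.approx(
                nx.global_efficiency(nx.from_numpy_array(A)), abs=1e-12
            )

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(6)
        A = random_graph(10, 0.2, rng)
        G = _graph(A)
        base = global_efficiency(G)
        empty = np.argwhere((A == 0) & ~np.eye(10, dtype=bool))
        i, j = empty[rng.integers(len(empty))]
        A2 = A.copy()
        A2[i, j] = A2[j, i] = 1
        assert global_efficiency(_graph(A2)) >= base

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        A = random_graph(9, 0.3, rng)
        perm = rng.permutation(9)
        P = A[np.ix_(perm, perm)]
        assert global_efficiency(_graph(P)) == pytest.approx(
            global_efficiency(_graph(A)), abs=1e-12
        )
        assert connectivity_density(_graph(P)) == connectivity_density(_graph(A))


class TestPopulationSanity:
    def test_shared_drive_raises_density(self):
        # overlapping evoked populations cohere; disjoint ones do not
        rng = np.random.default_rng(8)
        n = 1500
        drive = np.sin(np.linspace(0, 30, n)) + rng.standard_normal(n) * 0.1

        def population(n_driven):
            arrays = []
            for k in range(10):
                noise_ = rng.standard_normal(n)
                arrays.append(drive + 0.2 * noise_ if k < n_driven else noise_)
            return _traces(arrays)

        C_overlap = coherence_matrix(population(8))
        C_disjoint = coherence_matrix(population(2))
        d_overlap = connectivity_density(threshold_adjacency(C_overlap, 0.45))
        d_disjoint = connectivity_density(threshold_adjacency(C_disjoint, 0.45))
        assert d_overlap > d_disjoint

    def test_metrics_dict_is_consistent(self):
        G = _graph_with_edges(12, 20, seed=9)
        metrics = graph_metrics(G)
        assert metrics["m"] == 20 and metrics["K"] == 12
        assert metrics["density"] == pytest.approx(40 / 132)
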