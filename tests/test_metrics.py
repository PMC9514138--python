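"""Graph metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from scovnet.metrics import (
    CommunityPartition,
    compute_network_metrics,
    detect_communities,
    global_efficiency,
    local_efficiency,
    network_metric,
    participation_coefficient,
)

from _oracles import (
    best_partition_exhaustive,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_participation,
    newman_modularity,
    random_graph,
)


def complete(n):
    A = np.ones((n, n), int)
    np.fill_diagonal(A, 0)
    return A


def from_edges(n, edges):
    A = np.zeros((n, n), int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        assert global_efficiency(complete(4)) == pytest.approx(1.0)

    def test_path_p3(self):
        A = from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(A) == pytest.approx(5 / 6)

    def test_two_disjoint_edges(self):
        A = from_edges(4, [(0, 1), (2, 3)])
        assert global_efficiency(A) == pytest.approx(1 / 3)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(np.zeros((5, 5), int)) == 0.0

    def test_monotone_under_edge_addition(self, rng):
        for _ in range(30):
            A = random_graph(rng)
            zeros = np.argwhere(np.triu(A == 0, 1))
            if not len(zeros):
                continue
            i, j = zeros[rng.integers(len(zeros))]
            B = A.copy()
            B[i, j] = B[j, i] = 1
            assert global_efficiency(B) >= global_efficiency(A) - 1e-12


class TestLocalEfficiency:
    def test_triangle_all_ones(self):
        per, mean = local_efficiency(complete(3))
        assert np.allclose(per, 1.0) and mean == pytest.approx(1.0)

    def test_star_all_zero(self):
        A = from_edges(4, [(0, 1), (0, 2), (0, 3)])
        per, mean = local_efficiency(A)
        # center's neighborhood has no edges; leaves have degree 1
        assert np.allclose(per, 0.0) and mean == 0.0

    def test_k4_minus_edge_matches_oracle(self):
        A = complete(4)
        A[0, 1] = A[1, 0] = 0
        per, mean = local_efficiency(A)
        oper, omean = brute_local_efficiency(A)
        assert np.allclose(per, oper, atol=1e-12)
        assert mean == pytest.approx(omean, abs=1e-12)


class TestCommunities:
    def test_two_cliques_separated_with_q_half(self):
        A = np.zeros((8, 8), int)
        A[:4, :4] = complete(4)
        A[4:, 4:] = complete(4)
        part = detect_communities(A, seed=0)
        assert part.n_modules == 2
        assert (part.membership[:4] == part.membership[0]).all()
        assert (part.membership[4:] == part.membership[4]).all()
        assert part.quality == pytest.approx(0.5)
        # matches the exhaustive optimum
        _, q_opt = best_partition_exhaustive(A)
        assert part.quality == pytest.approx(q_opt, abs=1e-12)

    def test_complete_k6_single_module(self):
        part = detect_communities(complete(6), resolution=1.0, seed=1)
        assert part.n_modules == 1
        _, q_opt = best_partition_exhaustive(complete(6))
        assert part.quality == pytest.approx(q_opt, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        A = random_graph(rng)
        p1 = detect_communities(A, seed=9)
        p2 = detect_communities(A, seed=9)
        assert (p1.membership == p2.membership).all()

    def test_edgeless_graph_singletons_with_warning(self):
        with pytest.warns(UserWarning, match="edgeless"):
            part = detect_communities(np.zeros((4, 4), int))
        assert part.n_modules == 4 and part.quality == 0.0

    def test_isolated_node_is_singleton(self):
        A = from_edges(4, [(0, 1), (1, 2), (0, 2)])
        part = detect_communities(A, seed=0)
        assert (part.membership == part.membership[3]).sum() == 1


class TestParticipation:
    def test_all_edges_within_own_module_zero(self):
        A = complete(3)
        part = CommunityPartition(np.zeros(3, int), 1.0, 0.0)
        pc, mean = participation_coefficient(A, part)
        assert np.allclose(pc, 0.0) and mean == 0.0

    def test_half_half_two_modules(self):
        # degree-4 hub: 2 edges into each of 2 modules
        A = from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        membership = np.array([0, 0, 0, 1, 1])
        pc, _ = participation_coefficient(
            A, CommunityPartition(membership, 1.0, 0.0)
        )
        assert pc[0] == pytest.approx(0.5)

    def test_three_modules_two_thirds(self):
        A = from_edges(4, [(0, 1), (0, 2), (0, 3)])
        membership = np.array([0, 0, 1, 2])
        pc, _ = participation_coefficient(
            A, CommunityPartition(membership, 1.0, 0.0)
        )
        assert pc[0] == pytest.approx(2 / 3)

    def test_partition_size_mismatch_errors(self):
        with pytest.raises(ValueError, match="partition"):
            participation_coefficient(
                complete(4), CommunityPartition(np.zeros(3, int), 1.0, 0.0)
            )


class TestOracleEquivalence:
    def test_efficiencies_and_pc_match_brute_force(self, rng):
        for _ in range(60):
            A = random_graph(rng)
            assert global_efficiency(A) == pytest.approx(
                brute_global_efficiency(A), abs=1e-12
            )
            per, mean = local_efficiency(A)
            oper, omean = brute_local_efficiency(A)
            assert np.allclose(per, oper, atol=1e-12)
            opt_membership, q_opt = best_partition_exhaustive(A)
            # contiguous relabel for the package's partition type
            _, inv = np.unique(opt_membership, return_inverse=True)
            part = CommunityPartition(inv, 1.0, q_opt)
            pc, _ = participation_coefficient(A, part)
            assert np.allclose(pc, brute_participation(A, inv), atol=1e-12)
            # Louvain never beats the exhaustive optimum
            found = detect_communities(A, seed=3)
            assert found.quality <= q_opt + 1e-12


class TestBundle:
    def test_edgeless_all_zero(self):
        with pytest.warns(UserWarning):
            m = compute_network_metrics(np.zeros((5, 5), int))
        assert m.mean_local_efficiency == 0.0
        assert m.global_efficiency == 0.0
        assert m.mean_participation == 0.0

    def test_complete_graph_end_to_end(self):
        m = compute_network_metrics(complete(8))
        assert m.mean_local_efficiency == pytest.approx(1.0)
        assert m.global_efficiency == pytest.approx(1.0)
        assert m.partition.n_modules == 1
        assert m.mean_participation == pytest.approx(0.0)

    def test_participation_drops_as_between_block_edges_removed(self):
        # nested graphs: two K5 blocks plus k bridges, k = 5..0
        base = np.zeros((10, 10), int)
        base[:5, :5] = complete(5)
        base[5:, 5:] = complete(5)
        bridges = [(i, 5 + i) for i in range(5)]
        means = []
        for k in (5, 3, 1, 0):
            A = base.copy()
            for i, j in bridges[:k]:
                A[i, j] = A[j, i] = 1
            means.append(network_metric(A, "participation", seed=0))
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))
        assert means[0] > means[-1]

    def test_deterministic_bundle(self, rng):
        A = random_graph(rng)
        m1 = compute_network_metrics(A, seed=5)
        m2 = compute_network_metrics(A, seed=5)
        assert m1.mean_participation == m2.mean_participation
        assert (m1.partition.membership == m2.partition.membership).all()
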