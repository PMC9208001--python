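"""Rich-club curves, rewiring nulls, communities, participation, efficiency."""

from itertools import combinations

import numpy as np
import pytest

import oracles
from conftest import as_network, random_symmetric
from hierconn.graphmetrics import (
    CommunityPartition,
    degree_and_strength,
    detect_communities,
    global_efficiency,
    participation_coefficient,
    rewire_nulls,
    rich_club_normalized,
    rich_club_raw,
)


def weights_from_edges(n, edges):
    w = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return w


class TestDegreeStrength:
    def test_triangle_hand_count(self):
        w = weights_from_edges(3, [(0, 1, 0.2), (0, 2, 0.3), (1, 2, 0.4)])
        k, s = degree_and_strength(as_network(w))
        np.testing.assert_array_equal(k, [2, 2, 2])
        np.testing.assert_allclose(s, [0.5, 0.6, 0.7])

    def test_empty_network_all_zero(self):
        k, s = degree_and_strength(as_network(np.zeros((4, 4))))
        assert not k.any() and not s.any()

    def test_matches_edge_list_tally(self, rng):
        net = as_network(random_symmetric(20, rng), sparsity=0.3)
        k, s = degree_and_strength(net)
        k2, s2 = oracles.degree_strength_tally(net.weights)
        np.testing.assert_array_equal(k, k2)
        np.testing.assert_allclose(s, s2)


class TestRichClubRaw:
    def test_homogeneous_complete_graph_is_flat_one(self):
        w = 0.4 * (1 - np.eye(6))
        curve = rich_club_raw(as_network(w))
        defined = np.isfinite(curve.phi)
        assert defined.any()
        np.testing.assert_allclose(curve.phi[defined], 1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        net = as_network(random_symmetric(5, rng), sparsity=0.7)
        curve = rich_club_raw(net)
        expected = oracles.rich_club_curve(net.weights)
        for idx, k in enumerate(curve.k):
            if k in expected:
                assert curve.phi[idx] == pytest.approx(expected[k])
            else:
                assert np.isnan(curve.phi[idx])

    def test_star_graph_undefined_above_leaf_degree(self):
        w = weights_from_edges(5, [(0, i, 0.5) for i in range(1, 5)])
        curve = rich_club_raw(as_network(w))
        assert np.isnan(curve.phi[curve.k == 1]).all()  # club = {hub} only

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            net = as_network(random_symmetric(12, rng), sparsity=0.4)
            phi = rich_club_raw(net).phi
            ok = np.isfinite(phi)
            assert np.all(phi[ok] > 0) and np.all(phi[ok] <= 1 + 1e-12)


class TestRewireNulls:
    def test_degree_sequence_and_weight_multiset_conserved(self, rng):
        net = as_network(random_symmetric(15, rng), sparsity=0.3)
        ens = rewire_nulls(net, n_nulls=5, seed=7)
        k0 = np.count_nonzero(net.weights, axis=1)
        w0 = np.sort(net.weights[np.triu_indices(15, 1)])
        for null in ens.nulls:
            np.testing.assert_array_equal(np.count_nonzero(null, axis=1), k0)
            np.testing.assert_allclose(np.sort(null[np.triu_indices(15, 1)]), w0)
            np.testing.assert_allclose(null, null.T)

    def test_path_graph_nulls_stay_in_enumerated_null_space(self):
        """Every rewiring of the 4-path must be one of the degree-matched simple graphs."""
        w = weights_from_edges(4, [(0, 1, 0.1), (1, 2, 0.2), (2, 3, 0.3)])
        target_deg = tuple(np.count_nonzero(w, axis=1))
        valid = set()
        for edges in combinations(combinations(range(4), 2), 3):
            deg = [0, 0, 0, 0]
            for a, b in edges:
                deg[a] += 1
                deg[b] += 1
            if tuple(deg) == target_deg:
                valid.add(frozenset(edges))
        ens = rewire_nulls(as_network(w), n_nulls=30, seed=3)
        for null in ens.nulls:
            got = frozenset(zip(*np.nonzero(np.triu(null, 1))))
            assert frozenset((int(a), int(b)) for a, b in got) in valid

    def test_rigid_graph_warns_and_returns_original(self):
        w = weights_from_edges(3, [(0, 1, 0.5)])
        with pytest.warns(UserWarning):
            ens = rewire_nulls(as_network(w), n_nulls=2, seed=0)
        np.testing.assert_array_equal(ens.nulls[0], w)


class TestRichClubNormalized:
    def test_unswappable_network_normalizes_to_one(self):
        # a triangle cannot be rewired, so every null equals the original
        w = weights_from_edges(3, [(0, 1, 0.2), (0, 2, 0.3), (1, 2, 0.4)])
        curve = rich_club_normalized(as_network(w), n_nulls=3, seed=0)
        ok = np.isfinite(curve.phi_norm)
        np.testing.assert_allclose(curve.phi_norm[ok], 1.0)

    def test_reproducible_under_seed(self, rng):
        net = as_network(random_symmetric(12, rng), sparsity=0.4)
        c1 = rich_club_normalized(net, n_nulls=10, seed=5)
        c2 = rich_club_normalized(net, n_nulls=10, seed=5)
        np.testing.assert_array_equal(c1.phi_norm, c2.phi_norm)


class TestCommunities:
    def test_two_disconnected_cliques_split_exactly(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i, j in combinations(block, 2):
                w[i, j] = w[j, i] = 0.8
        part = detect_communities(as_network(w), n_restarts=5, seed=1)
        assert part.n_communities == 2
        assert len(set(part.membership[:4])) == 1
        assert len(set(part.membership[4:])) == 1
        assert part.membership[0] != part.membership[4]

    def test_matches_exhaustive_modularity_search(self, rng):
        # two noisy 4-node blocks; exhaustive search over all partitions of 8 nodes
        w = np.zeros((8, 8))
        for i, j in combinations(range(8), 2):
            same = (i < 4) == (j < 4)
            w[i, j] = w[j, i] = 0.9 if same else 0.1 * rng.random()
        np.fill_diagonal(w, 0)
        part = detect_communities(as_network(w), n_restarts=20, seed=2)
        best_m, best_q = oracles.best_partition_exhaustive(w)
        assert part.q == pytest.approx(best_q, abs=1e-10)
        # same grouping up to relabeling
        for i, j in combinations(range(8), 2):
            assert (part.membership[i] == part.membership[j]) == (best_m[i] == best_m[j])

    def test_deterministic_under_seed(self, rng):
        net = as_network(random_symmetric(20, rng), sparsity=0.3)
        p1 = detect_communities(net, n_restarts=10, seed=9)
        p2 = detect_communities(net, n_restarts=10, seed=9)
        np.testing.assert_array_equal(p1.membership, p2.membership)

    def test_empty_network_gives_singletons(self):
        part = detect_communities(as_network(np.zeros((5, 5))))
        assert part.q == 0.0
        assert part.n_communities == 5


class TestParticipation:
    def test_all_edges_internal_gives_zero(self):
        w = weights_from_edges(4, [(0, 1, 0.5), (0, 2, 0.5), (1, 2, 0.5)])
        part = CommunityPartition(np.array([0, 0, 0, 1]), 0.0, 1.0)
        p = participation_coefficient(as_network(w), part)
        assert p[0] == pytest.approx(0.0)
        assert p[3] == 0.0  # isolated

    def test_one_edge_per_community_closed_form(self):
        m = 4  # hub with one edge into each of 4 communities
        w = weights_from_edges(5, [(0, i, 0.5) for i in range(1, 5)])
        part = CommunityPartition(np.array([0, 0, 1, 2, 3]), 0.0, 1.0)
        p = participation_coefficient(as_network(w), part)
        assert p[0] == pytest.approx(1 - 1 / m)

    def test_matches_direct_summation(self, rng):
        net = as_network(random_symmetric(10, rng), sparsity=0.4)
        membership = rng.integers(0, 3, size=10)
        part = CommunityPartition(membership, 0.0, 1.0)
        np.testing.assert_allclose(
            participation_coefficient(net, part),
            oracles.participation(net.weights, membership),
            atol=1e-12,
        )

    def test_invariant_to_community_relabeling(self, rng):
        net = as_network(random_symmetric(10, rng), sparsity=0.4)
        membership = rng.integers(0, 3, size=10)
        relabeled = np.array([2, 0, 1])[membership]
        p1 = participation_coefficient(net, CommunityPartition(membership, 0.0, 1.0))
        p2 = participation_coefficient(net, CommunityPartition(relabeled, 0.0, 1.0))
        np.testing.assert_allclose(p1, p2)


class TestGlobalEfficiency:
    def test_two_nodes_equals_weight(self):
        assert global_efficiency(weights_from_edges(2, [(0, 1, 0.7)])) == pytest.approx(0.7)

    def test_disconnected_pair_is_zero(self):
        assert global_efficiency(np.zeros((2, 2))) == 0.0

    def test_single_node_warns_zero(self):
        with pytest.warns(UserWarning):
            assert global_efficiency(np.zeros((1, 1))) == 0.0

    def test_matches_floyd_warshall(self, rng):
        w = random_symmetric(6, rng)
        w[w < 0.4] = 0.0  # make some pairs indirect
        assert global_efficiency(w) == pytest.approx(oracles.floyd_warshall_efficiency(w))

    def test_monotone_under_weight_increase(self, rng):
        w = random_symmetric(7, rng)
        w[w < 0.5] = 0.0
        base = global_efficiency(w)
        i, j = np.unravel_index(np.argmax(np.triu(w, 1)), w.shape)
        w2 = w.copy()
        w2[i, j] = w2[j, i] = w[i, j] * 2
        assert global_efficiency(w2) >= base
        w3 = w.copy()  # add an edge
        zero = np.argwhere(np.triu(w3 == 0, 1))[0]
        w3[zero[0], zero[1]] = w3[zero[1], zero[0]] = 0.3
        assert global_efficiency(w3) >= base
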