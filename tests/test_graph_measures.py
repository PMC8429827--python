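"""Weighted graph measures against brute-force oracles, closed forms and
binary-graph textbook values."""

import networkx as nx
import numpy as np
import pytest

from scnet import (
    MEASURE_NAMES,
    NullModelSpec,
    clustering_and_transitivity,
    local_efficiency,
    measure_set,
    modularity,
    path_measures,
    random_reference,
    shortest_path_lengths,
    small_worldness,
    strength_and_assortativity,
)
from scnet.errors import RewiringError, UndefinedMeasureError

from conftest import random_connectivity
from oracles import (
    assortativity_longhand,
    floyd_warshall,
    max_modularity_exhaustive,
    newman_q,
    onnela_clustering,
    path_summaries,
)


def complete(n, w=1.0):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return m


class TestShortestPaths:
    def test_unit_complete_graph(self):
        d = shortest_path_lengths(complete(3))
        assert np.array_equal(d, complete(3))

    def test_chain_additivity(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        d = shortest_path_lengths(w)
        assert d[0, 2] == 2.0

    def test_unreachable_is_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        d = shortest_path_lengths(w)
        assert np.isinf(d[0, 2])

    def test_matches_floyd_warshall_oracle(self, rng):
        w = random_connectivity(rng, 10)
        assert np.allclose(shortest_path_lengths(w), floyd_warshall(w),
                           atol=1e-10)


class TestPathMeasures:
    def test_k5_closed_forms(self):
        pm = path_measures(complete(5))
        for key in ("characteristic_path_length", "eccentricity", "radius",
                    "diameter", "global_efficiency"):
            assert pm[key] == pytest.approx(1.0)

    def test_two_node_half_weight(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        pm = path_measures(w)
        assert pm["characteristic_path_length"] == pytest.approx(2.0)
        assert pm["global_efficiency"] == pytest.approx(0.5)

    def test_matches_oracle_recomputation(self, rng):
        w = random_connectivity(rng, 8)
        pm = path_measures(w)
        expected = path_summaries(floyd_warshall(w))
        for key, val in expected.items():
            assert pm[key] == pytest.approx(val, abs=1e-10)

    def test_singleton_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            path_measures(np.zeros((1, 1)))

    def test_radius_ecc_diameter_ordering(self, rng):
        for _ in range(25):
            w = random_connectivity(rng, rng.integers(3, 10))
            if not (w.sum(axis=1) > 0).any():
                continue
            pm = path_measures(w)
            assert pm["radius"] <= pm["eccentricity"] <= pm["diameter"]

    def test_global_efficiency_monotone_in_weights(self, rng):
        """Raising any single weight cannot reduce global efficiency."""
        for _ in range(10):
            w = random_connectivity(rng, 7)
            pm0 = path_measures(w)["global_efficiency"]
            i, j = rng.integers(0, 7, size=2)
            if i == j:
                continue
            w2 = w.copy()
            w2[i, j] = w2[j, i] = min(1.0, w2[i, j] + rng.random())
            pm1 = path_measures(w2)["global_efficiency"]
            assert pm1 >= pm0 - 1e-12


class TestClustering:
    def test_complete_uniform(self):
        c, t = clustering_and_transitivity(complete(5, 0.7))
        assert c == pytest.approx(1.0)
        assert t == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.8
        c, t = clustering_and_transitivity(w)
        assert c == 0.0 and t == 0.0

    def test_matches_triangle_enumeration_oracle(self, rng):
        w = random_connectivity(rng, 8)
        c, t = clustering_and_transitivity(w)
        c_exp, t_exp = onnela_clustering(w)
        assert c == pytest.approx(c_exp, abs=1e-10)
        assert t == pytest.approx(t_exp, abs=1e-10)


class TestStrengthAssortativity:
    def test_complete_unit_strength(self):
        s, _ = strength_and_assortativity(complete(6))
        assert s == pytest.approx(5.0)

    def test_regular_graph_assortativity_undefined(self):
        # a cycle: every endpoint degree is 2, zero variance
        w = np.zeros((5, 5))
        for i in range(5):
            w[i, (i + 1) % 5] = w[(i + 1) % 5, i] = 0.5
        s, a = strength_and_assortativity(w)
        assert s == pytest.approx(1.0)
        assert np.isnan(a)

    def test_all_zero_matrix(self):
        s, a = strength_and_assortativity(np.zeros((4, 4)))
        assert s == 0.0 and np.isnan(a)

    def test_matches_edge_list_pearson_oracle(self, rng):
        for _ in range(10):
            w = random_connectivity(rng, 10, density=0.5)
            _, a = strength_and_assortativity(w)
            expected = assortativity_longhand(w)
            if np.isnan(expected):
                assert np.isnan(a)
            else:
                assert a == pytest.approx(expected, abs=1e-10)


class TestModularity:
    def test_two_disconnected_cliques(self):
        w = np.zeros((8, 8))
        w[:4, :4] = complete(4)[:, :]
        w[4:, 4:] = complete(4)[:, :]
        assert modularity(w, seed=1) == pytest.approx(0.5)

    def test_complete_uniform_graph(self):
        q = modularity(complete(6), seed=1)
        assert q >= -1e-10
        assert q == pytest.approx(0.0, abs=1e-10)

    def test_two_block_matches_exhaustive_search(self, rng):
        """Louvain Q within 0.02 of the exhaustive-partition maximum on a
        12-node two-block graph (within-block 0.9, between 0.1)."""
        n = 12
        blocks = np.repeat([0, 1], 6)
        w = np.where(blocks[:, None] == blocks[None, :], 0.9, 0.1)
        np.fill_diagonal(w, 0.0)
        q = modularity(w, seed=3)
        q_star = max_modularity_exhaustive(w, max_blocks=3)
        assert q <= q_star + 1e-12
        assert q >= q_star - 0.02

    def test_partition_quality_definition_agrees_with_networkx(self, rng):
        w = random_connectivity(rng, 9)
        g = nx.from_numpy_array(w)
        parts = nx.community.louvain_communities(g, weight="weight", seed=5)
        q_nx = nx.community.modularity(g, parts, weight="weight")
        assignment = np.empty(9, dtype=int)
        for ci, nodes in enumerate(parts):
            for node in nodes:
                assignment[node] = ci
        assert newman_q(w, assignment) == pytest.approx(q_nx, abs=1e-10)

    def test_empty_graph_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            modularity(np.zeros((4, 4)), seed=0)

    def test_deterministic_given_seed(self, rng):
        w = random_connectivity(rng, 10)
        assert modularity(w, seed=7) == modularity(w, seed=7)


class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        w = random_connectivity(rng, 12, density=0.4)
        ref = random_reference(w, NullModelSpec(1, 10, seed=3))
        assert np.array_equal((ref > 0).sum(axis=1), (w > 0).sum(axis=1))

    def test_weight_multiset_preserved(self, rng):
        w = random_connectivity(rng, 12, density=0.4)
        ref = random_reference(w, NullModelSpec(1, 10, seed=3))
        iu = np.triu_indices(12, 1)
        assert np.allclose(
            np.sort(w[iu][w[iu] > 0]), np.sort(ref[iu][ref[iu] > 0])
        )

    def test_complete_graph_topology_unchanged(self, rng):
        w = complete(6) * np.round(np.linspace(0.2, 1.0, 36).reshape(6, 6), 3)
        w = np.triu(w, 1) + np.triu(w, 1).T
        ref = random_reference(w, NullModelSpec(1, 10, seed=4))
        assert np.array_equal(ref > 0, w > 0)
        iu = np.triu_indices(6, 1)
        assert np.allclose(np.sort(w[iu]), np.sort(ref[iu]))

    def test_rewiring_actually_rewires(self, rng):
        w = random_connectivity(rng, 14, density=0.3)
        ref = random_reference(w, NullModelSpec(1, 10, seed=5))
        assert not np.array_equal(ref > 0, w > 0)

    def test_too_few_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(RewiringError):
            random_reference(w, NullModelSpec(1, 10, seed=0))


class TestSmallWorldness:
    def test_self_null_limit_on_complete_graph(self):
        """A complete uniform graph equals every rewired reference, so
        sigma is exactly 1."""
        sigma = small_worldness(complete(8, 0.6), NullModelSpec(10, 5, seed=1))
        assert sigma == pytest.approx(1.0)

    def _ring_lattice(self, n=30, k=4, rewire_frac=0.1, seed=0):
        g = nx.watts_strogatz_graph(n, k, rewire_frac, seed=seed)
        return nx.to_numpy_array(g)

    def test_small_world_fixture_beats_random_fixture(self):
        """A slightly-rewired ring lattice is more small-world than a
        density-matched fully random graph."""
        ws = self._ring_lattice()
        m = int(ws.sum() / 2)
        g_rand = nx.gnm_random_graph(30, m, seed=1)
        wr = nx.to_numpy_array(g_rand)
        spec = NullModelSpec(20, 10, seed=2)
        assert small_worldness(ws, spec) > small_worldness(wr, spec)

    def test_scale_invariance(self):
        """Doubling all weights changes neither C (max-rescaled) nor the
        L ratio, hence not sigma."""
        w = self._ring_lattice() * 0.4
        spec = NullModelSpec(10, 5, seed=3)
        assert small_worldness(w, spec) == pytest.approx(
            small_worldness(2 * w, spec), rel=1e-12
        )


class TestMeasureSet:
    def test_k5_closed_forms(self):
        ms = measure_set(complete(5), NullModelSpec(5, 5), seed=1)
        assert ms.average_strength == pytest.approx(4.0)
        assert ms.characteristic_path_length == pytest.approx(1.0)
        assert ms.eccentricity == pytest.approx(1.0)
        assert ms.radius == pytest.approx(1.0)
        assert ms.diameter == pytest.approx(1.0)
        assert ms.global_efficiency == pytest.approx(1.0)
        assert ms.mean_clustering_coefficient == pytest.approx(1.0)
        assert ms.transitivity == pytest.approx(1.0)

    def test_contains_exactly_twelve_measures(self, rng):
        w = random_connectivity(rng, 8)
        ms = measure_set(w, NullModelSpec(3, 3), seed=2)
        assert tuple(ms.as_dict()) == MEASURE_NAMES
        assert len(MEASURE_NAMES) == 12

    def test_deterministic_given_seed(self, rng):
        w = random_connectivity(rng, 8)
        a = measure_set(w, NullModelSpec(3, 3), seed=9)
        b = measure_set(w, NullModelSpec(3, 3), seed=9)
        assert a == b


def test_binary_graphs_match_textbook_values():
    """On unit-weight graphs every measure must equal its binary textbook
    value; swept over all connected graphs with <= 6 nodes from the
    networkx graph atlas."""
    checked = 0
    for g in nx.graph_atlas_g()[2:209]:
        if g.number_of_nodes() < 2 or not nx.is_connected(g):
            continue
        w = nx.to_numpy_array(g)
        pm = path_measures(w)
        assert pm["characteristic_path_length"] == pytest.approx(
            nx.average_shortest_path_length(g), abs=1e-10
        )
        ecc = nx.eccentricity(g)
        assert pm["eccentricity"] == pytest.approx(
            np.mean(list(ecc.values())), abs=1e-10
        )
        assert pm["radius"] == nx.radius(g)
        assert pm["diameter"] == nx.diameter(g)
        assert pm["global_efficiency"] == pytest.approx(
            nx.global_efficiency(g), abs=1e-10
        )
        c, t = clustering_and_transitivity(w)
        assert c == pytest.approx(nx.average_clustering(g), abs=1e-10)
        assert t == pytest.approx(nx.transitivity(g), abs=1e-10)
        assert local_efficiency(w) == pytest.approx(
            nx.local_efficiency(g), abs=1e-10
        )
        s, _ = strength_and_assortativity(w)
        assert s == pytest.approx(
            np.mean([d for _, d in g.degree()]), abs=1e-10
        )
        checked += 1
    assert checked > 100  # the sweep actually covered the atlas
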