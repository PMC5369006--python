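"""Topological features, null ensembles and significance tests."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from interonet import (
    NullEnsemble,
    compute_centralities,
    compute_diameter,
    compute_modularity,
    compute_transitivity,
    detect_modules,
    fit_degree_loglog,
    gen_reference_interactomes,
    generate_null_ensemble,
    null_model_tests,
    rank_hubs,
    topology_report,
    SynthConfig,
)
from interonet.topology import _normal_fit_p


def two_triangles_with_bridge():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


class TestDiameter:
    def test_path_graph(self):
        assert compute_diameter(nx.path_graph(5)) == 4

    def test_complete_graph(self):
        assert compute_diameter(nx.complete_graph(4)) == 1

    def test_disconnected_uses_largest_component(self):
        g = nx.Graph()
        g.add_edges_from(nx.path_graph(5).edges)
        g.add_edges_from([("x", "y")])
        assert compute_diameter(g) == 4

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_diameter(nx.Graph())


def oracle_transitivity(g):
    """Triangle/triple counting by explicit enumeration."""
    nodes = list(g.nodes)
    triangles = sum(
        1 for a, b, c in itertools.combinations(nodes, 3)
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c))
    triples = sum(
        1 for v in nodes
        for a, b in itertools.combinations(list(g.neighbors(v)), 2))
    return 3.0 * triangles / triples


class TestTransitivity:
    def test_complete_graph(self):
        assert compute_transitivity(nx.complete_graph(4)) == 1.0

    def test_star_has_no_triangles(self):
        assert compute_transitivity(nx.star_graph(4)) == 0.0

    def test_pendant_triangle(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)])
        assert compute_transitivity(g) == pytest.approx(0.6)

    def test_no_triples_errors(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="undefined"):
            compute_transitivity(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        if sum(d for _, d in g.degree()) == 0:
            pytest.skip("empty random draw")
        assert compute_transitivity(g) == pytest.approx(oracle_transitivity(g))


class TestCentralities:
    def test_star_center(self):
        deg, bet = compute_centralities(nx.star_graph(4))
        assert deg[0] == 4
        assert bet[0] == pytest.approx(6.0)  # all C(4,2) pairs route via hub

    def test_path_midpoint(self):
        _, bet = compute_centralities(nx.path_graph(3))
        assert bet[1] == pytest.approx(1.0)

    def test_complete_graph_zero_betweenness(self):
        _, bet = compute_centralities(nx.complete_graph(4))
        assert all(b == 0.0 for b in bet.values())


def set_partitions(items):
    """All partitions of a list (recursive, standard construction)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def oracle_modularity(g, partition):
    """Q from the adjacency-matrix formulation:
    (1/2m) * sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    nodes = list(g.nodes)
    m = g.number_of_edges()
    k = dict(g.degree())
    q = 0.0
    for i in nodes:
        for j in nodes:
            if partition[i] != partition[j]:
                continue
            a_ij = 1.0 if g.has_edge(i, j) else 0.0
            q += a_ij - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


class TestModularity:
    def test_two_triangles_bridge_partition(self):
        g = two_triangles_with_bridge()
        partition = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert compute_modularity(g, partition) == pytest.approx(5 / 14)

    def test_single_module_is_zero(self):
        g = two_triangles_with_bridge()
        assert compute_modularity(g, {n: 0 for n in g}) == pytest.approx(0.0)

    def test_incomplete_partition_errors(self):
        g = two_triangles_with_bridge()
        with pytest.raises(ValueError, match="incomplete"):
            compute_modularity(g, {0: 0})

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_adjacency_oracle_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(10, 18, seed=seed)
        for _ in range(5):
            partition = {n: int(rng.integers(3)) for n in g}
            assert compute_modularity(g, partition) == pytest.approx(
                oracle_modularity(g, partition))


class TestDetectModules:
    def test_two_triangles_split(self):
        g = two_triangles_with_bridge()
        partition = detect_modules(g)
        assert len(set(partition.values())) == 2
        assert partition[0] == partition[1] == partition[2]
        assert partition[3] == partition[4] == partition[5]
        # and this is the brute-force maximum-modularity partition
        best_q = max(
            compute_modularity(
                g, {n: i for i, block in enumerate(p) for n in block})
            for p in set_partitions(list(g.nodes)))
        assert compute_modularity(g, partition) == pytest.approx(best_q)

    def test_single_clique_one_module(self):
        partition = detect_modules(nx.complete_graph(5))
        assert len(set(partition.values())) == 1

    def test_deterministic(self, small_pipeline):
        g = small_pipeline["predicted"].to_graph()
        assert detect_modules(g) == detect_modules(g)


class TestNullEnsembles:
    def test_rewired_preserves_degree_sequence(self, small_pipeline):
        g = small_pipeline["predicted"].to_graph()
        ens = generate_null_ensemble(g, "rewired", n=20, seed=1)
        original = sorted(d for _, d in g.degree())
        for sample in ens.graphs:
            assert sorted(d for _, d in sample.degree()) == original
            assert nx.number_of_selfloops(sample) == 0

    def test_rewired_actually_rewires(self, small_pipeline):
        g = small_pipeline["predicted"].to_graph()
        ens = generate_null_ensemble(g, "rewired", n=5, seed=1)
        assert any(set(map(frozenset, s.edges)) != set(map(frozenset, g.edges))
                   for s in ens.graphs)

    def test_same_size_preserves_counts(self, small_pipeline):
        g = small_pipeline["predicted"].to_graph()
        ens = generate_null_ensemble(g, "same_size_random", n=20, seed=2)
        for sample in ens.graphs:
            assert sample.number_of_nodes() == g.number_of_nodes()
            assert sample.number_of_edges() == g.number_of_edges()

    def test_star_is_rewiring_fixed_point(self):
        star = nx.star_graph(4)
        with pytest.warns(UserWarning, match="no degree-preserving swap"):
            ens = generate_null_ensemble(star, "rewired", n=5, seed=3)
        for sample in ens.graphs:
            assert set(map(frozenset, sample.edges)) == set(
                map(frozenset, star.edges))

    def test_seeded_reproducibility(self, small_pipeline):
        g = small_pipeline["predicted"].to_graph()
        e1 = generate_null_ensemble(g, "rewired", n=5, seed=9)
        e2 = generate_null_ensemble(g, "rewired", n=5, seed=9)
        for a, b in zip(e1.graphs, e2.graphs):
            assert set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_null_ensemble(nx.path_graph(3), "shuffled", n=2, seed=0)


class TestNullModelTests:
    def test_diameter_p_is_relative_frequency(self):
        # ensemble of 10 graphs: 7 with diameter 4, 3 with diameter 3
        graphs = [nx.path_graph(5) for _ in range(7)] + \
                 [nx.path_graph(4) for _ in range(3)]
        set1 = NullEnsemble(kind="rewired", graphs=graphs, seed=0, n=10)
        set2 = NullEnsemble(kind="same_size_random",
                            graphs=[nx.path_graph(5)], seed=0, n=1)
        g = nx.path_graph(5)
        g.add_edge(1, 3)  # create a triangle so transitivity is defined
        report = topology_report(g)
        stats = null_model_tests(report, set1, set2)
        expected = float(np.mean(
            [compute_diameter(s) == report.diameter for s in graphs]))
        assert stats["diameter"].p_value == pytest.approx(expected)
        assert stats["diameter"].p_upper_tail >= stats["diameter"].p_value

    def test_observed_at_random_mean_gives_half(self):
        rng = np.random.default_rng(4)
        samples = rng.normal(0.4, 0.05, size=500)
        p, normal = _normal_fit_p(float(samples.mean()), samples, alpha=0.05)
        assert p == pytest.approx(0.5)
        assert normal

    def test_identical_distributions_give_ks_p_one(self, small_pipeline):
        g = small_pipeline["predicted"].to_graph()
        report = topology_report(g)
        set1 = NullEnsemble(kind="rewired", graphs=[g.copy()], seed=0, n=1)
        set2 = NullEnsemble(kind="same_size_random", graphs=[g.copy()],
                            seed=0, n=1)
        stats = null_model_tests(report, set1, set2)
        assert stats["degree"].p_value == pytest.approx(1.0)
        assert stats["betweenness"].p_value == pytest.approx(1.0)
        assert stats["diameter"].p_value == pytest.approx(1.0)

    def test_wrong_ensemble_kinds_error(self, small_pipeline):
        g = small_pipeline["predicted"].to_graph()
        report = topology_report(g)
        ens = NullEnsemble(kind="rewired", graphs=[g.copy()], seed=0, n=1)
        with pytest.raises(ValueError, match="ensemble"):
            null_model_tests(report, ens, ens)


class TestRankHubs:
    def test_top_in_both_is_first(self):
        degrees = {"hub": 22, "a": 13, "b": 11, "c": 5}
        betweenness = {"hub": 90.0, "a": 40.0, "b": 60.0, "c": 1.0}
        table = rank_hubs(degrees, betweenness)
        assert table.iloc[0]["node"] == "hub"
        assert table.iloc[0]["total_rank"] == 2

    def test_rank_sum(self):
        degrees = {"x": 13, "y": 22, "z": 11, "w": 9}
        betweenness = {"x": 10.0, "y": 90.0, "z": 50.0, "w": 40.0}
        table = rank_hubs(degrees, betweenness).set_index("node")
        assert table.loc["x", "degree_rank"] == 2
        assert table.loc["x", "betweenness_rank"] == 4
        assert table.loc["x", "total_rank"] == 6

    def test_all_ties_share_total(self):
        degrees = {n: 3 for n in "abcd"}
        betweenness = {n: 1.0 for n in "abcd"}
        table = rank_hubs(degrees, betweenness)
        assert set(table["total_rank"]) == {2}

    def test_mismatched_node_sets_error(self):
        with pytest.raises(ValueError, match="same node set"):
            rank_hubs({"a": 1}, {"b": 1.0})


class TestDegreeLogLog:
    def test_exact_power_law(self):
        # counts proportional to k^-2: 16, 4, 1 at k = 1, 2, 4
        degrees = [1] * 16 + [2] * 4 + [4]
        slope, intercept = fit_degree_loglog(degrees)
        assert slope == pytest.approx(-2.0)
        assert intercept == pytest.approx(math.log10(16))

    def test_regular_graph_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_degree_loglog([3, 3, 3, 3])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_preferential_attachment_slope_below_minus_one(self, seed):
        config = SynthConfig(
            seed=seed, n_proteins_ref_a=250, n_autophagy_a=250,
            n_interactions_a=500, n_proteins_ref_b=20, n_autophagy_b=20,
            n_interactions_b=30, n_conserved_interologs=10,
            preferential_attachment=True)
        ref_a, _ = gen_reference_interactomes(config)
        g = nx.Graph(ref_a.edge_pairs)
        slope, _ = fit_degree_loglog([d for _, d in g.degree()])
        assert slope < -1.0
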