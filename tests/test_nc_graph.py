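"""NC decomposition, graph construction, merging, and serialization."""

import networkx as nx
import pytest

from nclandscape import (
    FibonacciGPMap,
    NCGraph,
    build_nc_graph,
    decompose_into_ncs,
    generate_fixture,
    geometric_mean_evolvability,
    merge_ncs_by_phenotype,
    read_nc_graph,
    summarize_nc_graph,
    write_nc_graph,
)
from nclandscape.gp_maps import enumerate_genotypes, mutational_neighbors
from nclandscape.nc_graph import NCGraphTableError


class TestDecomposition:
    def test_fibonacci_L3_partition(self, fib3_map, fib3_labeling):
        assert fib3_labeling.n_ncs == 7
        assert sorted(fib3_labeling.sizes().values()) == [1, 1, 1, 1, 3, 3, 9]
        # one NC per phenotype
        assert len(set(fib3_labeling.phenotype_of_nc.values())) == 7

    def test_deleterious_unlabeled(self, fib3_map, fib3_labeling):
        assert "000" not in fib3_labeling.nc_id_of
        assert "012" in fib3_labeling.nc_id_of

    def test_partition_covers_nondeleterious(self, fib3_map, fib3_labeling):
        nondel = [
            g for g in enumerate_genotypes(fib3_map) if not fib3_map.is_deleterious(g)
        ]
        assert set(fib3_labeling.nc_id_of) == set(nondel)
        assert sum(fib3_labeling.sizes().values()) == len(nondel)

    def test_single_phenotype_map_one_nc(self):
        m, _ = generate_fixture("single_phenotype_K2_L3")
        lab = decompose_into_ncs(m)
        assert lab.n_ncs == 1
        assert lab.sizes()[0] == 8

    def test_all_distinct_map_singletons(self):
        m, _ = generate_fixture("all_distinct_K2_L2")
        lab = decompose_into_ncs(m)
        assert lab.n_ncs == 4
        assert all(s == 1 for s in lab.sizes().values())

    def test_ids_deterministic(self, fib3_map):
        a = decompose_into_ncs(fib3_map)
        b = decompose_into_ncs(fib3_map)
        assert a.nc_id_of == b.nc_id_of

    def test_maximality(self, fib3_map, fib3_labeling):
        # every same-phenotype Hamming edge stays within one NC
        for g in enumerate_genotypes(fib3_map):
            if fib3_map.is_deleterious(g):
                continue
            for h in mutational_neighbors(g, fib3_map):
                if fib3_map.phenotype_of(h) == fib3_map.phenotype_of(g):
                    assert fib3_labeling.nc_id_of[g] == fib3_labeling.nc_id_of[h]


class TestGraphConstruction:
    def test_fibonacci_L3_graph(self, fib3_graph):
        assert fib3_graph.n_ncs == 7
        assert fib3_graph.n_edges == 15
        eps = fib3_graph.evolvabilities()
        empty_nc = next(
            nc for nc in fib3_graph.nc_ids if fib3_graph.phenotype(nc) == ""
        )
        assert eps[empty_nc] == 6
        assert sorted(eps.values()) == [4, 4, 4, 4, 4, 4, 6]

    def test_totals(self, fib3_graph):
        assert fib3_graph.total_genotypes == 27
        assert fib3_graph.n_nondeleterious == 19
        assert fib3_graph.n_phenotypes == 7

    def test_single_nc_map_no_edges(self):
        m, _ = generate_fixture("single_phenotype_K2_L3")
        g = build_nc_graph(m, decompose_into_ncs(m))
        assert g.n_edges == 0
        assert g.evolvability(0) == 0

    def test_shared_neighbor_phenotype_degree_exceeds_evolvability(self):
        # phenotype B splits into two NCs both adjacent to the single A NC:
        # the A node has degree 2 but evolvability 1
        m, _ = generate_fixture("shared_neighbor_phenotype_K2_L4")
        g = build_nc_graph(m, decompose_into_ncs(m))
        a = next(nc for nc in g.nc_ids if g.phenotype(nc) == "A")
        assert g.graph.degree[a] == 2
        assert g.evolvability(a) == 1

    def test_no_self_or_same_phenotype_edges(self, fib3_graph):
        for a, b in fib3_graph.graph.edges:
            assert a != b
            assert fib3_graph.phenotype(a) != fib3_graph.phenotype(b)

    @pytest.mark.parametrize(
        "name",
        ["fibonacci_L3", "le_fibonacci_L4", "shared_neighbor_phenotype_K2_L4"],
    )
    def test_evolvability_bounds(self, name):
        m, _ = generate_fixture(name)
        g = build_nc_graph(m, decompose_into_ncs(m))
        for nc in g.nc_ids:
            assert g.evolvability(nc) <= g.graph.degree[nc]
            assert g.evolvability(nc) <= g.n_phenotypes - 1

    def test_deleterious_inclusion_flag_only_increases(self):
        m = FibonacciGPMap(length=3)
        lab = decompose_into_ncs(m)
        base = build_nc_graph(m, lab)
        sens = build_nc_graph(m, lab, include_deleterious_in_evolvability=True)
        diffs = [sens.evolvability(nc) - base.evolvability(nc) for nc in base.nc_ids]
        assert all(d in (0, 1) for d in diffs)
        assert any(d == 1 for d in diffs)  # some NC borders the deleterious class


class TestMergeByPhenotype:
    def test_idempotent_on_one_nc_per_phenotype(self, fib3_graph):
        merged = merge_ncs_by_phenotype(fib3_graph)
        assert merged.n_ncs == fib3_graph.n_ncs
        assert merged.n_edges == fib3_graph.n_edges
        assert sorted(merged.sizes().values()) == sorted(fib3_graph.sizes().values())
        again = merge_ncs_by_phenotype(merged)
        assert nx.is_isomorphic(
            merged.graph, again.graph, node_match=lambda a, b: a == b
        )

    def test_sizes_add(self):
        m, _ = generate_fixture("shared_neighbor_phenotype_K2_L4")
        g = build_nc_graph(m, decompose_into_ncs(m))
        merged = merge_ncs_by_phenotype(g)
        assert merged.n_ncs == 2
        b = next(nc for nc in merged.nc_ids if merged.phenotype(nc) == "B")
        assert merged.size(b) == 2
        assert merged.n_edges == 1


class TestGeometricMeanEvolvability:
    def test_constant_sequence(self):
        g = nx.Graph()
        for i in range(3):
            g.add_node(i, phenotype=f"p{i}", size=1)
        g.add_edges_from([(0, 1), (1, 2), (0, 2)])  # triangle: all eps = 2
        graph = NCGraph(graph=g, total_genotypes=3)
        assert geometric_mean_evolvability(graph) == pytest.approx(2.0)

    def test_mixed_values(self):
        # path a-b-c: eps multiset {1, 2, 1} -> (1*2*1)^(1/3)
        g = nx.Graph()
        for i, p in enumerate("abc"):
            g.add_node(i, phenotype=p, size=1)
        g.add_edges_from([(0, 1), (1, 2)])
        graph = NCGraph(graph=g, total_genotypes=3)
        assert graph.evolvabilities() == {0: 1, 1: 2, 2: 1}
        assert geometric_mean_evolvability(graph) == pytest.approx(2 ** (1 / 3))

    def test_zero_replacement(self):
        g = nx.Graph()
        g.add_node(0, phenotype="a", size=1)  # isolated: eps 0
        g.add_node(1, phenotype="b", size=1)
        g.add_node(2, phenotype="c", size=1)
        g.add_edge(1, 2)  # both eps 1
        graph = NCGraph(graph=g, total_genotypes=3)
        # eps multiset {0, 1, 1} -> (0.01 * 1 * 1)^(1/3)
        assert geometric_mean_evolvability(graph) == pytest.approx(0.01 ** (1 / 3))
        two = NCGraph(
            graph=g.subgraph([0, 1]).copy(), total_genotypes=2
        )  # eps {0, 0} -> isolated pair
        assert geometric_mean_evolvability(two) == pytest.approx(0.01)


class TestSummary:
    def test_fibonacci_counts(self, fib3_graph):
        s = summarize_nc_graph(fib3_graph)
        assert s["n_ncs"] == 7
        assert s["n_edges"] == 15
        assert s["n_phenotypes"] == 7

    def test_all_singleton_no_edges_mean_eps_zero(self):
        m, _ = generate_fixture("single_phenotype_K2_L3")
        g = build_nc_graph(m, decompose_into_ncs(m))
        assert summarize_nc_graph(g)["mean_evolvability"] == 0.0

    def test_perfect_monotone_association(self, fib3_graph):
        s = summarize_nc_graph(fib3_graph)
        # in the L=3 map the largest NC also has the largest evolvability
        assert s["size_evolvability_rank_correlation"] > 0


class TestSerialization:
    def test_round_trip(self, fib3_graph, tmp_path):
        nodes, edges = tmp_path / "n.tsv", tmp_path / "e.tsv"
        write_nc_graph(fib3_graph, nodes, edges)
        loaded = read_nc_graph(nodes, edges, K=3, L=3)
        assert loaded.n_ncs == fib3_graph.n_ncs
        assert set(loaded.graph.edges) == set(fib3_graph.graph.edges)
        assert loaded.evolvabilities() == fib3_graph.evolvabilities()
        assert loaded.sizes() == fib3_graph.sizes()
        assert loaded.total_genotypes == 27

    def test_dangling_edge(self, tmp_path):
        (tmp_path / "n.tsv").write_text("nc_id\tphenotype\tsize\tevolvability\n0\tA\t1\t0\n")
        (tmp_path / "e.tsv").write_text("nc_id_1\tnc_id_2\n0\t7\n")
        with pytest.raises(NCGraphTableError, match="unknown NC id 7"):
            read_nc_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")

    def test_evolvability_mismatch(self, tmp_path):
        (tmp_path / "n.tsv").write_text(
            "nc_id\tphenotype\tsize\tevolvability\n0\tA\t1\t3\n1\tB\t1\t1\n"
        )
        (tmp_path / "e.tsv").write_text("nc_id_1\tnc_id_2\n0\t1\n")
        with pytest.raises(NCGraphTableError, match="inconsistent"):
            read_nc_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")
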