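"""SCAN clustering: similarity, cores/clusters/roles, modularity, ranking."""

import math

import numpy as np
import pytest

import netmod as nm
from netmod.scan import HUB, OUTLIER, ScanParams
from oracles import check_scan_clustering, newman_q, random_string_graph


class TestStructuralSimilarity:
    def test_identical_closed_neighborhoods(self, triangle):
        assert nm.structural_similarity(triangle, "a", "b") == pytest.approx(1.0)

    def test_path_pair(self, path_abc):
        assert nm.structural_similarity(path_abc, "a", "b") \
            == pytest.approx(2 / math.sqrt(6))

    def test_bridge_pair(self, two_triangles_bridge):
        assert nm.structural_similarity(two_triangles_bridge, "c", "d") \
            == pytest.approx(0.5)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        g = random_string_graph(rng, n_max=15)
        for u, v in g.edges:
            s_uv = nm.structural_similarity(g, u, v)
            assert s_uv == pytest.approx(nm.structural_similarity(g, v, u))
            assert 0.0 <= s_uv <= 1.0 + 1e-12

    def test_sigma_one_iff_same_closed_neighborhood(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g = random_string_graph(rng, n_max=12)
            nodes = sorted(g.nodes)
            for u in nodes:
                for v in nodes:
                    same = nm.closed_neighborhood(g, u) \
                        == nm.closed_neighborhood(g, v)
                    sigma = nm.structural_similarity(g, u, v)
                    assert (abs(sigma - 1.0) < 1e-12) == same

    def test_unknown_node(self, triangle):
        with pytest.raises(KeyError):
            nm.structural_similarity(triangle, "a", "zz")


class TestScanCluster:
    def test_two_triangles_split_at_bridge(self, two_triangles_bridge):
        c = nm.scan_cluster(two_triangles_bridge, ScanParams(0.7, 2))
        assert sorted(map(sorted, c.modules)) \
            == [["a", "b", "c"], ["d", "e", "f"]]
        assert all(r == "member" for r in c.role.values())
        c.validate()

    def test_hub_bridges_two_modules(self, two_triangles_bridge):
        g = two_triangles_bridge
        nm.add_edge(g, "h", "a")
        nm.add_edge(g, "h", "e")
        c = nm.scan_cluster(g, ScanParams(0.7, 2))
        assert c.role["h"] == HUB

    def test_pendant_is_outlier(self, two_triangles_bridge):
        # pendant on the bridge endpoint c: sigma(o, c) = 2/sqrt(10) < 0.7,
        # so o stays outside the module and touches only one
        g = two_triangles_bridge
        nm.add_edge(g, "o", "c")
        c = nm.scan_cluster(g, ScanParams(0.7, 2))
        assert c.role["o"] == OUTLIER

    def test_pendant_on_low_degree_node_joins_module(self,
                                                     two_triangles_bridge):
        # sigma(o, a) = 2/sqrt(2*4) ~ 0.707 >= 0.7: the pendant is inside
        # a's eps-neighborhood and is absorbed as a border member
        g = two_triangles_bridge
        nm.add_edge(g, "o", "a")
        c = nm.scan_cluster(g, ScanParams(0.7, 2))
        assert c.role["o"] == "member"
        assert c.label["o"] == c.label["a"]

    def test_empty_graph(self):
        c = nm.scan_cluster(nm.new_graph())
        assert c.modules == [] and c.label == {} and c.role == {}

    def test_deterministic_across_runs(self, two_triangles_bridge):
        a = nm.scan_cluster(two_triangles_bridge)
        b = nm.scan_cluster(two_triangles_bridge)
        assert a.label == b.label and a.role == b.role

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_definition_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_string_graph(rng, n_max=30)
        eps = float(rng.uniform(0.4, 0.9))
        mu = int(rng.integers(1, 5))
        c = nm.scan_cluster(g, ScanParams(eps, mu))
        c.validate()
        assert check_scan_clustering(g, c, eps, mu) == []

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ScanParams(epsilon=0.0)
        with pytest.raises(ValueError):
            ScanParams(mu=0)


class TestModuleModularity:
    def test_two_triangles_worked_value(self, two_triangles_bridge):
        q = nm.module_modularity(two_triangles_bridge, [{"a", "b", "c"}], 0)
        assert q == pytest.approx(3 / 7 - 0.25, abs=1e-12)

    def test_whole_graph_module_is_zero(self, two_triangles_bridge):
        g = two_triangles_bridge
        assert nm.module_modularity(g, [set(g.nodes)], 0) \
            == pytest.approx(0.0, abs=1e-12)

    def test_isolated_module_is_zero(self, triangle):
        g = triangle
        g.add_node("lonely")
        assert nm.module_modularity(g, [{"lonely"}], 0) == 0.0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            nm.module_modularity(nm.new_graph(), [set()], 0)

    @pytest.mark.parametrize("seed", range(15))
    def test_partition_sum_equals_global_newman_q(self, seed):
        from oracles import random_partition
        rng = np.random.default_rng(100 + seed)
        g = random_string_graph(rng, n_max=25)
        if g.number_of_edges() == 0:
            return
        parts = random_partition(rng, g.nodes)
        total = sum(nm.module_modularity(g, parts, i)
                    for i in range(len(parts)))
        assert total == pytest.approx(newman_q(g, parts), abs=1e-12)


class TestRankModules:
    @pytest.fixture
    def clustering(self):
        modules = [{"a1", "a2", "a3"}, {"b1", "b2"},
                   {"c1", "c2", "c3", "c4"}]
        label = {v: i + 1 for i, mod in enumerate(modules) for v in mod}
        role = {v: "member" for v in label}
        return nm.Clustering(label=label, role=role, modules=modules)

    @pytest.fixture
    def graph_of(self, clustering):
        g = nm.new_graph()
        for mod in clustering.modules:
            members = sorted(mod)
            for u, v in zip(members, members[1:]):
                nm.add_edge(g, u, v)
        return g

    def test_sort_by_seed_count(self, graph_of, clustering):
        seeds = nm.SeedSet(seeds=("a1", "b1", "b2", "c1"),
                           found=("a1", "b1", "b2", "c1"))
        ranked = nm.rank_modules(graph_of, clustering, seeds, "seed_count")
        assert [s.n_seeds for s in ranked] == [2, 1, 1]
        # seed-count tie between modules 1 and 3 breaks to the larger module
        assert [s.module_id for s in ranked] == [2, 3, 1]

    def test_top_k_truncates_but_never_pads(self, graph_of, clustering):
        seeds = nm.SeedSet(seeds=(), found=())
        assert len(nm.rank_modules(graph_of, clustering, seeds, "size", 6)) == 3
        assert len(nm.rank_modules(graph_of, clustering, seeds, "size", 2)) == 2

    def test_size_criterion(self, graph_of, clustering):
        seeds = nm.SeedSet(seeds=(), found=())
        ranked = nm.rank_modules(graph_of, clustering, seeds, "size")
        assert [s.n_nodes for s in ranked] == [4, 3, 2]

    def test_invalid_args(self, graph_of, clustering):
        seeds = nm.SeedSet(seeds=(), found=())
        with pytest.raises(ValueError):
            nm.rank_modules(graph_of, clustering, seeds, "bogus")
        with pytest.raises(ValueError):
            nm.rank_modules(graph_of, clustering, seeds, "size", 0)


def test_module_tables_round_readably(tmp_path, two_triangles_bridge):
    c = nm.scan_cluster(two_triangles_bridge)
    seeds = nm.SeedSet(seeds=("a",), found=("a",))
    mod_path, sum_path = tmp_path / "m.tsv", tmp_path / "s.tsv"
    from netmod.scan import write_module_table, write_summary_table
    write_module_table(c, seeds, mod_path)
    ranked = nm.rank_modules(two_triangles_bridge, c, seeds)
    write_summary_table(ranked, sum_path)
    lines = mod_path.read_text().splitlines()
    assert lines[0] == "module_id\tnode\tis_seed\trole"
    assert len(lines) == 1 + 6
    assert sum_path.read_text().count("\n") == 3  # header + 2 modules
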