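"""Synthetic generators: reproducibility, expected counts, validity."""

import numpy as np
import pytest

import netmod as nm
from netmod import fixtures as F
from netmod import graph as G


class TestPlantedPartitionGraph:
    def test_extremes_give_disjoint_cliques(self):
        g, labels = F.planted_partition_graph(
            F.PlantedSpec((4, 5), p_in=1.0, p_out=0.0, rng_seed=1))
        assert g.number_of_edges() == 6 + 10
        for u, v in g.edges:
            assert labels[u] == labels[v]

    def test_deterministic_for_fixed_seed(self):
        spec = F.PlantedSpec((10, 10), 0.5, 0.05, rng_seed=42)
        g1, l1 = F.planted_partition_graph(spec)
        g2, l2 = F.planted_partition_graph(spec)
        assert G.sorted_edges(g1) == G.sorted_edges(g2) and l1 == l2

    def test_single_block_edge_count_within_3sd(self):
        # C(10,2)·0.5 = 22.5 expected edges; binomial sd = sqrt(45·0.25)
        counts = [
            F.planted_partition_graph(
                F.PlantedSpec((10,), 0.5, 0.0, rng_seed=s))[0].number_of_edges()
            for s in range(200)
        ]
        mean, sd = 22.5, np.sqrt(45 * 0.25)
        assert abs(np.mean(counts) - mean) < 3 * sd / np.sqrt(200)

    def test_graphs_are_valid(self):
        g, _ = F.planted_partition_graph(
            F.PlantedSpec((8, 8, 8), 0.7, 0.1, rng_seed=3))
        nm.validate(g)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            F.PlantedSpec((0,), 0.5, 0.1)
        with pytest.raises(ValueError):
            F.PlantedSpec((5,), 1.5, 0.1)


class TestMultisourceKb:
    @pytest.fixture
    def base_graph(self):
        g, _ = F.planted_partition_graph(
            F.PlantedSpec((12,), 0.6, 0.0, rng_seed=9))
        return g

    def test_full_coverage_every_source_reports_everything(self, base_graph):
        records = F.make_multisource_kb(base_graph, n_sources=3,
                                        coverage=1.0, rng_seed=0)
        m = nm.IdMap.identity(base_graph.nodes)
        kb = nm.merge_sources(records, m)
        g_k3 = nm.kvotes_filter(kb, 3)
        assert G.sorted_edges(g_k3) == G.sorted_edges(base_graph)

    def test_single_source_union_is_sampled_subset(self, base_graph):
        records = F.make_multisource_kb(base_graph, n_sources=1,
                                        coverage=0.5, rng_seed=4)
        m = nm.IdMap.identity(base_graph.nodes)
        kb = nm.merge_sources(records, m)
        union = set(G.sorted_edges(nm.kvotes_filter(kb, 1)))
        assert union <= set(G.sorted_edges(base_graph))
        assert union == {(r.a, r.b) for r in records}

    def test_expected_support_within_3sd(self, base_graph):
        n_sources, coverage = 4, 0.7
        supports = []
        for s in range(100):
            records = F.make_multisource_kb(base_graph, n_sources,
                                            coverage, rng_seed=s)
            m = nm.IdMap.identity(base_graph.nodes)
            kb = nm.merge_sources(records, m)
            supports.extend(len(v) for v in kb.support.values())
        mean = n_sources * coverage
        sd = np.sqrt(n_sources * coverage * (1 - coverage))
        assert abs(np.mean(supports) - mean) < 3 * sd / np.sqrt(len(supports))


class TestAlignedAnnotations:
    @pytest.fixture
    def labels(self):
        _, labels = F.planted_partition_graph(
            F.PlantedSpec((15, 15, 15), 1.0, 0.0, rng_seed=2))
        return labels

    def test_zero_noise_sets_equal_blocks(self, labels):
        coll = F.make_aligned_annotations(labels, n_decoy_sets=0,
                                          noise=0.0, rng_seed=0)
        assert len(coll.sets) == 3
        for s in coll.sets:
            block = int(s.set_id.removeprefix("BLOCK"))
            assert s.members == frozenset(v for v, b in labels.items()
                                          if b == block)

    def test_noise_swaps_members(self, labels):
        coll = F.make_aligned_annotations(labels, n_decoy_sets=0,
                                          noise=0.2, rng_seed=1)
        for s in coll.sets:
            block = int(s.set_id.removeprefix("BLOCK"))
            true_block = frozenset(v for v, b in labels.items() if b == block)
            assert len(s.members) == len(true_block)
            assert len(s.members & true_block) == len(true_block) - 3

    def test_decoys_and_determinism(self, labels):
        a = F.make_aligned_annotations(labels, n_decoy_sets=5,
                                       noise=0.1, rng_seed=7)
        b = F.make_aligned_annotations(labels, n_decoy_sets=5,
                                       noise=0.1, rng_seed=7)
        assert [s.members for s in a.sets] == [s.members for s in b.sets]
        assert sum(s.set_id.startswith("DECOY") for s in a.sets) == 5
        assert a.universe == set(labels)


class TestSampleSeeds:
    @pytest.fixture
    def labels(self):
        return {f"n{i:02d}": i // 20 for i in range(40)}

    def test_fraction_one_takes_whole_block(self, labels):
        seeds = F.sample_seeds(labels, (0,), 1.0, rng_seed=0)
        assert set(seeds.seeds) == {v for v, b in labels.items() if b == 0}

    def test_floor_convention(self, labels):
        seeds = F.sample_seeds(labels, (0,), 0.5, rng_seed=0)
        assert len(seeds.seeds) == 10

    def test_disjoint_blocks_disjoint_seeds(self, labels):
        s0 = F.sample_seeds(labels, (0,), 0.5, rng_seed=1)
        s1 = F.sample_seeds(labels, (1,), 0.5, rng_seed=1)
        assert not set(s0.seeds) & set(s1.seeds)

    def test_empty_selection_errors(self, labels):
        with pytest.raises(ValueError):
            F.sample_seeds(labels, (99,), 0.5, rng_seed=0)


class TestScenario:
    def test_write_scenario_files_readable(self, tmp_path):
        sc = F.make_scenario(rng_seed=5)
        paths = F.write_scenario(sc, tmp_path)
        records = nm.read_interactions(paths["interactions"])
        assert {(r.a, r.b, r.source) for r in records} \
            == {(r.a, r.b, r.source) for r in sc.records}
        m = nm.IdMap.from_tsv(paths["idmap"])
        assert all(m.lookup(s) == s for s in sc.seeds.seeds)
        assert m.lookup(f"GENE_{sc.seeds.seeds[0]}") == sc.seeds.seeds[0]
        coll = nm.read_gmt(paths["gmt"])
        assert {s.set_id for s in coll.sets} \
            == {s.set_id for s in sc.annotations.sets}
        assert nm.read_seed_list(paths["seeds"]) == list(sc.seeds.seeds)

    def test_scenario_reproducible(self):
        a, b = F.make_scenario(rng_seed=11), F.make_scenario(rng_seed=11)
        assert G.sorted_edges(a.graph) == G.sorted_edges(b.graph)
        assert a.seeds.seeds == b.seeds.seeds
        assert [(r.a, r.b, r.source) for r in a.records] \
            == [(r.a, r.b, r.source) for r in b.records]
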