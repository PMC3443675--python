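"""Synthetic fixtures with known ground truth.

Every analysis stage is testable without downloading interaction
databases: a planted-partition graph stands in for the true interactome
(dense blocks = functional modules), several simulated source databases
each report a random subset of its edges (curation coverage), gene-set
annotations are aligned with the planted blocks up to a noise fraction,
and seed lists are sampled from chosen blocks the way a disease
signature samples a disease module.

All generators are bit-reproducible for a fixed ``rng_seed`` and thread
a single :class:`numpy.random.Generator`, so one seed reproduces a whole
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import graph as G
from .enrichment import GeneSet, GeneSetCollection, write_gmt
from .knowledge import InteractionRecord, write_interactions
from .network import SeedSet


@dataclass(frozen=True)
class PlantedSpec:
    """Planted-partition graph: blocks joined densely inside, sparsely
    between."""

    block_sizes: tuple[int, ...]
    p_in: float = 0.9
    p_out: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must all be >= 1")
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0, 1]")


def _node_ids(n: int) -> list[str]:
    # Entrez-style numeric strings of equal width: lexicographic order
    # coincides with generation order, keeping outputs deterministic.
    start = 10 ** len(str(n))
    return [str(start + i) for i in range(n)]


def planted_partition_graph(spec: PlantedSpec) -> tuple[G.Graph, dict[str, int]]:
    """Sample a planted-partition graph; returns (graph, node → block id).

    Each within-block pair is joined independently with probability
    ``p_in``, each between-block pair with ``p_out``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sizes = spec.block_sizes
    ids = _node_ids(sum(sizes))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    labels = {ids[i]: b
              for b, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:]))
              for i in range(lo, hi)}
    g = G.new_graph()
    g.add_nodes_from(ids)
    nblocks = len(sizes)
    for b1 in range(nblocks):
        lo1, hi1 = offsets[b1], offsets[b1 + 1]
        for b2 in range(b1, nblocks):
            lo2, hi2 = offsets[b2], offsets[b2 + 1]
            p = spec.p_in if b1 == b2 else spec.p_out
            hits = rng.random((hi1 - lo1, hi2 - lo2)) < p
            rows, cols = np.nonzero(hits)
            for r, c in zip(rows, cols):
                i, j = lo1 + r, lo2 + c
                if i < j:  # upper triangle only; skips self-pairs
                    G.add_edge(g, ids[i], ids[j])
    return g, labels


def make_multisource_kb(g: G.Graph, n_sources: int = 3,
                        coverage: float = 0.8,
                        rng_seed: int = 0) -> list[InteractionRecord]:
    """Simulate source databases, each reporting a random subset of edges.

    Each of the ``n_sources`` databases (named SRC1..SRCn) independently
    samples every edge of ``g`` with probability ``coverage``, so the
    expected support of an edge is ``n_sources * coverage`` votes.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    edges = G.sorted_edges(g)
    records = []
    for s in range(1, n_sources + 1):
        mask = rng.random(len(edges)) < coverage
        src = f"SRC{s}"
        records.extend(InteractionRecord(u, v, src)
                       for (u, v), keep in zip(edges, mask) if keep)
    return records


def make_aligned_annotations(labels: dict[str, int], n_decoy_sets: int = 10,
                             noise: float = 0.1,
                             rng_seed: int = 0) -> GeneSetCollection:
    """Gene sets aligned with the planted blocks, plus random decoys.

    One set per block (``BLOCK<b>``) with a ``noise`` fraction of its
    members swapped for random outside genes, plus ``n_decoy_sets``
    uniformly drawn decoy sets of mean block size.  Universe = all nodes.
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must lie in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    universe = sorted(labels)
    blocks: dict[int, list[str]] = {}
    for v in universe:
        blocks.setdefault(labels[v], []).append(v)

    sets = []
    for b in sorted(blocks):
        members = set(blocks[b])
        n_swap = int(noise * len(members))
        if n_swap:
            outside = sorted(set(universe) - members)
            drop = rng.choice(sorted(members), size=n_swap, replace=False)
            gain = rng.choice(outside, size=n_swap, replace=False)
            members = (members - set(drop)) | set(gain)
        sets.append(GeneSet(set_id=f"BLOCK{b}", name=f"planted block {b}",
                            category="planted", members=frozenset(members)))
    decoy_size = max(1, round(np.mean([len(m) for m in blocks.values()])))
    for d in range(1, n_decoy_sets + 1):
        members = rng.choice(universe, size=min(decoy_size, len(universe)),
                             replace=False)
        sets.append(GeneSet(set_id=f"DECOY{d}", name=f"decoy set {d}",
                            category="decoy", members=frozenset(members)))
    return GeneSetCollection(sets=sets, universe=set(universe))


def sample_seeds(labels: dict[str, int], blocks: tuple[int, ...] | list[int],
                 fraction: float = 0.5, rng_seed: int = 0) -> SeedSet:
    """Sample a seed list: a uniform, floor-rounded fraction of each block."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    chosen: list[str] = []
    for b in blocks:
        members = sorted(v for v, lbl in labels.items() if lbl == b)
        if not members:
            continue
        n_take = max(1, int(fraction * len(members)))
        chosen.extend(rng.choice(members, size=n_take, replace=False))
    if not chosen:
        raise ValueError("seed sample is empty: no members in chosen blocks")
    seeds = tuple(sorted(chosen))
    return SeedSet(seeds=seeds, found=seeds)


@dataclass
class Scenario:
    """A complete synthetic study: interactome, sources, seeds, annotations."""

    graph: G.Graph
    labels: dict[str, int]
    records: list[InteractionRecord]
    seeds: SeedSet
    annotations: GeneSetCollection
    seeded_blocks: tuple[int, ...]


def make_scenario(block_sizes: tuple[int, ...] = (20, 20, 20, 20),
                  p_in: float = 0.9, p_out: float = 0.02,
                  n_sources: int = 3, coverage: float = 0.8,
                  seed_blocks: tuple[int, ...] = (0, 1),
                  seed_fraction: float = 0.5,
                  noise: float = 0.1, n_decoy_sets: int = 10,
                  rng_seed: int = 0) -> Scenario:
    """Generate a full scenario from one seed (sub-seeds are derived)."""
    ss = np.random.SeedSequence(rng_seed)
    s_graph, s_kb, s_ann, s_seed = (int(x) for x in
                                    ss.generate_state(4) % (2 ** 31))
    g, labels = planted_partition_graph(
        PlantedSpec(tuple(block_sizes), p_in, p_out, s_graph))
    records = make_multisource_kb(g, n_sources, coverage, s_kb)
    annotations = make_aligned_annotations(labels, n_decoy_sets, noise, s_ann)
    seeds = sample_seeds(labels, tuple(seed_blocks), seed_fraction, s_seed)
    return Scenario(graph=g, labels=labels, records=records, seeds=seeds,
                    annotations=annotations, seeded_blocks=tuple(seed_blocks))


def write_scenario(sc: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a scenario as pipeline-ready input files.

    ``interactions.tsv``, ``idmap.tsv`` (identity plus GENE_<id> symbol
    aliases), ``seeds.txt`` and ``annotations.gmt``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "idmap": out / "idmap.tsv",
        "seeds": out / "seeds.txt",
        "gmt": out / "annotations.gmt",
    }
    write_interactions(sc.records, paths["interactions"])
    with open(paths["idmap"], "w", encoding="utf-8") as fh:
        fh.write("# alias\tcanonical\n")
        for v in sorted(sc.graph.nodes):
            fh.write(f"{v}\t{v}\nGENE_{v}\t{v}\n")
    with open(paths["seeds"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(sc.seeds.seeds) + "\n")
    write_gmt(sc.annotations, paths["gmt"])
    return paths
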