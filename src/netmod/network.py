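"""Seed-based network construction.

A user supplies a list of seed genes (e.g. a disease signature); the
analysis network is carved out of the consensus knowledge-base graph
around those seeds.  Three construction modes are supported:

``direct_neighbors``
    seeds plus every gene directly interacting with a seed (default for
    seed lists under 1000 genes);
``min_seed_links(t)``
    like ``direct_neighbors`` but a non-seed gene is kept only if it
    interacts with *more than* ``t`` seeds (default ``t = 2``) — a
    stringent option for large lists;
``seeds_only``
    the subgraph induced on the seeds alone (default above 1000 genes).

In the two expanded modes an edge enters the network only if at least one
endpoint is a seed: edges between two added (non-seed) genes are excluded,
so the network stays anchored on the user's list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import graph as G

logger = logging.getLogger(__name__)

#: Seed-list size above which expansion is switched off by default.
DEFAULT_MODE_CUTOFF = 1000
#: Seed lists beyond this size trigger a warning (not an error).
SEED_SOFT_CAP = 3000


@dataclass(frozen=True)
class ExpansionMode:
    kind: str  # direct_neighbors | min_seed_links | seeds_only
    t: int = 2  # min_seed_links threshold: keep non-seed iff seed-degree > t

    _KINDS = ("direct_neighbors", "min_seed_links", "seeds_only")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown expansion mode {self.kind!r}")
        if self.kind == "min_seed_links" and self.t < 1:
            raise ValueError("min_seed_links threshold t must be >= 1")

    def __str__(self) -> str:
        return (f"{self.kind}(t={self.t})"
                if self.kind == "min_seed_links" else self.kind)


DIRECT_NEIGHBORS = ExpansionMode("direct_neighbors")
SEEDS_ONLY = ExpansionMode("seeds_only")


def min_seed_links(t: int = 2) -> ExpansionMode:
    return ExpansionMode("min_seed_links", t)


@dataclass
class SeedSet:
    """Canonical seed IDs and the subset found in the knowledge-base graph."""

    seeds: tuple[str, ...]
    found: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seed list contains duplicates after mapping")
        if not set(self.found) <= set(self.seeds):
            raise ValueError("found seeds must be a subset of all seeds")

    @property
    def missing(self) -> tuple[str, ...]:
        found = set(self.found)
        return tuple(s for s in self.seeds if s not in found)


def make_seed_set(mapped_ids: Iterable[str], kb_graph: G.Graph) -> SeedSet:
    """Split mapped seed IDs into those present/absent in the KB graph."""
    seeds = tuple(dict.fromkeys(mapped_ids))
    if len(seeds) > SEED_SOFT_CAP:
        logger.warning("seed list has %d genes, above the soft cap of %d; "
                       "expect slow expansion", len(seeds), SEED_SOFT_CAP)
    found = tuple(s for s in seeds if s in kb_graph)
    return SeedSet(seeds=seeds, found=found)


@dataclass
class SeededNetwork:
    graph: G.Graph
    is_seed: dict[str, bool]
    mode: ExpansionMode = field(default=DIRECT_NEIGHBORS)

    def seed_nodes(self) -> set[str]:
        return {v for v, s in self.is_seed.items() if s}

    def validate(self) -> None:
        G.validate(self.graph)
        assert set(self.is_seed) == set(self.graph.nodes), \
            "every node must carry a seed flag"
        if self.mode.kind != "seeds_only":
            for u, v in self.graph.edges:
                assert self.is_seed[u] or self.is_seed[v], \
                    f"edge {u}-{v} joins two non-seed nodes"


class NoSeedsFoundError(ValueError):
    def __init__(self):
        super().__init__(
            "none of the seed genes were found in the knowledge-base graph; "
            "check the ID-mapping table and the seed identifier format")


def select_default_mode(n_seeds: int) -> ExpansionMode:
    """Default construction mode by seed-list size.

    Expansion to direct interactors up to 1000 seeds, seeds-only above;
    exactly 1000 resolves to expansion (the tool's default behavior).
    """
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    return SEEDS_ONLY if n_seeds > DEFAULT_MODE_CUTOFF else DIRECT_NEIGHBORS


def build_network(kb_graph: G.Graph, seeds: SeedSet,
                  mode: ExpansionMode = DIRECT_NEIGHBORS) -> SeededNetwork:
    """Build the seeded analysis network under the given mode.

    All mapped seeds appear in the output (seeds absent from the knowledge
    base stay as isolated flagged nodes, so reported seed counts match the
    user's mapped list).  In expanded modes no edge joins two non-seed
    nodes.
    """
    if not seeds.found:
        raise NoSeedsFoundError()
    seed_set = set(seeds.found)

    if mode.kind == "seeds_only":
        net = G.induced_subgraph(kb_graph, seed_set)
    else:
        if mode.kind == "direct_neighbors":
            added = {n for s in seed_set for n in kb_graph[s]} - seed_set
        else:  # min_seed_links: keep iff seed-neighbor count strictly > t
            counts: dict[str, int] = {}
            for s in seed_set:
                for n in kb_graph[s]:
                    if n not in seed_set:
                        counts[n] = counts.get(n, 0) + 1
            added = {n for n, c in counts.items() if c > mode.t}
        keep = seed_set | added
        net = G.new_graph()
        net.add_nodes_from(keep)
        for u, v in kb_graph.edges:
            if u in keep and v in keep and (u in seed_set or v in seed_set):
                G.add_edge(net, u, v)

    # retain every mapped seed, even those missing from the knowledge base
    net.add_nodes_from(seeds.seeds)
    if seeds.missing:
        logger.info("%d seeds absent from the knowledge base kept as "
                    "isolated nodes: %s", len(seeds.missing),
                    list(seeds.missing)[:5])
    all_seeds = set(seeds.seeds)
    is_seed = {v: v in all_seeds for v in net.nodes}
    return SeededNetwork(graph=net, is_seed=is_seed, mode=mode)


def read_seed_list(path: str | Path) -> list[str]:
    """Read a seed file: one identifier per line, '#' comments skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
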