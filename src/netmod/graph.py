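"""Undirected simple-graph primitives shared by every analysis stage.

Nodes are canonical gene identifiers (non-empty strings, typically
Entrez-style numeric strings after ID mapping).  Graphs are plain
:class:`networkx.Graph` instances restricted to the simple, undirected,
unweighted case: no self-loops, no parallel edges, no directionality.
All functions here enforce those restrictions so downstream code
(structural clustering in particular) can rely on them.

Deterministic output everywhere: node and edge orderings in files are
lexicographic by node ID.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: The graph container used throughout the package.
Graph = nx.Graph

_SELF_LOOPS_KEY = "self_loops_dropped"


class UnknownNodeError(KeyError):
    """Raised when an operation names a node absent from the graph."""

    def __init__(self, node: str):
        super().__init__(node)
        self.node = node

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"node {self.node!r} is not in the graph"


def new_graph() -> Graph:
    """Return an empty undirected simple graph."""
    g = nx.Graph()
    g.graph[_SELF_LOOPS_KEY] = 0
    return g


def _check_node_id(v: str) -> str:
    if not isinstance(v, str) or not v or v != v.strip():
        raise ValueError(
            f"node IDs must be non-empty strings without surrounding "
            f"whitespace, got {v!r}"
        )
    return v


def add_edge(g: Graph, u: str, v: str) -> Graph:
    """Add the undirected edge ``{u, v}``, creating nodes as needed.

    Idempotent on repeats.  A self-loop (``u == v``) is silently dropped
    with a logged warning and counted in ``g.graph['self_loops_dropped']``;
    self-interactions carry no information for common-neighbor similarity.
    """
    _check_node_id(u)
    _check_node_id(v)
    if u == v:
        g.graph[_SELF_LOOPS_KEY] = g.graph.get(_SELF_LOOPS_KEY, 0) + 1
        logger.warning("dropped self-loop on node %r", u)
        return g
    g.add_edge(u, v)
    return g


def self_loops_dropped(g: Graph) -> int:
    """Number of self-loop inputs dropped since the graph was created."""
    return int(g.graph.get(_SELF_LOOPS_KEY, 0))


def closed_neighborhood(g: Graph, v: str) -> set[str]:
    """Return ``adj(v) ∪ {v}`` — the closed neighborhood used by SCAN's
    structural similarity."""
    if v not in g:
        raise UnknownNodeError(v)
    nbrs = set(g[v])
    nbrs.add(v)
    return nbrs


def induced_subgraph(g: Graph, keep: Iterable[str]) -> Graph:
    """Independent subgraph on ``keep ∩ nodes(g)``.

    Unknown IDs in ``keep`` are ignored with a logged report (they are not
    an error: seed lists routinely contain genes absent from the knowledge
    base).
    """
    keep = set(keep)
    unknown = keep - set(g.nodes)
    if unknown:
        logger.info("induced_subgraph: ignoring %d unknown node IDs (e.g. %s)",
                    len(unknown), sorted(unknown)[:5])
    sub = new_graph()
    kept = keep & set(g.nodes)
    sub.add_nodes_from(kept)
    for u, v in g.edges:
        if u in kept and v in kept:
            sub.add_edge(u, v)
    return sub


def validate(g: Graph) -> None:
    """Walk the adjacency structure and assert the simple-graph invariants.

    Raises ``AssertionError`` on a violation.  Used by tests after every
    operation sequence; cheap enough to call on fixture-sized graphs.
    """
    for v in g.nodes:
        _check_node_id(v)
        for w in g[v]:
            assert w != v, f"self-loop on {v!r}"
            assert w in g.nodes, f"adjacency of {v!r} references non-member {w!r}"
            assert v in g[w], f"asymmetric adjacency between {v!r} and {w!r}"
    degree_sum = sum(d for _, d in g.degree())
    assert degree_sum == 2 * g.number_of_edges(), "degree sum != 2·|E|"


def sorted_nodes(g: Graph) -> list[str]:
    return sorted(g.nodes)


def sorted_edges(g: Graph) -> list[tuple[str, str]]:
    return sorted(tuple(sorted(e)) for e in g.edges)


# ---------------------------------------------------------------------------
# Edge-list TSV I/O: two ID columns, optional third source column,
# '#' comment lines skipped.
# ---------------------------------------------------------------------------

def iter_edge_rows(path: str | Path) -> Iterator[tuple[str, ...]]:
    """Yield (id_a, id_b[, source]) tuples from a tab-separated edge list."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected at least two tab-separated "
                    f"ID columns, got {line!r}"
                )
            yield tuple(parts[:3])


def read_edgelist(path: str | Path) -> Graph:
    """Read a two-column edge-list TSV into a graph (source column ignored)."""
    g = new_graph()
    for row in iter_edge_rows(path):
        add_edge(g, row[0], row[1])
    return g


def write_edgelist(g: Graph, path: str | Path) -> None:
    """Write edges in lexicographic order as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id_a\tid_b\n")
        for u, v in sorted_edges(g):
            fh.write(f"{u}\t{v}\n")
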