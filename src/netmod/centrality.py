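"""Node-level network statistics exported alongside the clustering.

Four standard measures on the undirected analysis network: PageRank
(uniform teleport, damping 0.85), degree centrality (degree / (n−1)),
HITS (on an undirected graph hub and authority scores coincide with the
principal eigenvector of the adjacency matrix, reported L2-normalized),
and shortest-path betweenness (Brandes, unnormalized pair-based counts
with fractional credit across equal-length paths).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from . import graph as G

DEFAULT_DAMPING = 0.85
DEFAULT_TOL = 1e-10


@dataclass(frozen=True)
class NodeStats:
    node: str
    degree_centrality: float
    pagerank: float
    hits_score: float
    betweenness: float


def pagerank(g: G.Graph, damping: float = DEFAULT_DAMPING,
             tol: float = DEFAULT_TOL) -> dict[str, float]:
    """Undirected PageRank with uniform teleport; scores sum to 1.

    Mass on dangling (isolated) nodes is redistributed uniformly, the
    standard convention, so isolated nodes end up with teleport-level
    scores only.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("PageRank is undefined on an empty graph")
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    return nx.pagerank(g, alpha=damping, tol=tol, max_iter=1000)


def degree_centrality(g: G.Graph) -> dict[str, float]:
    """degree(v) / (n − 1); requires at least two nodes."""
    if g.number_of_nodes() < 2:
        raise ValueError("degree centrality needs at least two nodes")
    return nx.degree_centrality(g)


def hits(g: G.Graph, tol: float = DEFAULT_TOL,
         max_iter: int = 10_000) -> dict[str, float]:
    """Principal adjacency eigenvector, L2-normalized, entries >= 0.

    Shifted power iteration (on A + I, which shares A's eigenvectors but
    cannot oscillate on bipartite graphs) from the uniform vector; on a
    disconnected graph this start deterministically spreads mass over the
    components tied for the dominant eigenvalue, identically on every run.
    """
    if g.number_of_edges() == 0:
        raise ValueError("HITS is undefined on a graph with no edges")
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = a @ x + x
        y /= np.linalg.norm(y)
        if np.abs(y - x).sum() < tol:
            x = y
            break
        x = y
    return {v: float(s) for v, s in zip(nodes, x)}


def betweenness(g: G.Graph, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness over unordered node pairs.

    Unnormalized by default; ``normalized=True`` divides by
    (n−1)(n−2)/2.
    """
    return nx.betweenness_centrality(g, normalized=normalized)


def node_stats(g: G.Graph, damping: float = DEFAULT_DAMPING,
               normalized_betweenness: bool = False) -> list[NodeStats]:
    """All four measures for every node, in lexicographic node order.

    Degenerate graphs degrade gracefully: degree centrality is 0 on a
    single node, HITS scores are 0 when there are no edges.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("no nodes to compute statistics for")
    pr = pagerank(g, damping=damping)
    dc = (degree_centrality(g) if g.number_of_nodes() >= 2
          else {v: 0.0 for v in g.nodes})
    hs = (hits(g) if g.number_of_edges() > 0 else {v: 0.0 for v in g.nodes})
    bt = betweenness(g, normalized=normalized_betweenness)
    return [NodeStats(v, dc[v], pr[v], hs[v], bt[v]) for v in sorted(g.nodes)]


def write_stats_table(stats: Sequence[NodeStats], path) -> None:
    """Tab-delimited export: node, degree centrality, PageRank, HITS,
    betweenness."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tdegree_centrality\tpagerank\thits\tbetweenness\n")
        for s in stats:
            fh.write(f"{s.node}\t{s.degree_centrality:.10g}"
                     f"\t{s.pagerank:.10g}\t{s.hits_score:.10g}"
                     f"\t{s.betweenness:.10g}\n")
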