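"""Independent oracles: brute-force / closed-form reference computations.

Everything here is deliberately written against the *definitions* —
exhaustive enumeration, dense linear algebra, exact rational arithmetic —
and shares no code path with src/netmod, so agreement is evidence, not
tautology.  Used by the pytest suite and by scripts/acceptance.py.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# SCAN definition checker
# ---------------------------------------------------------------------------

def scan_reference(g, epsilon: float, mu: int):
    """Recompute cores, core components and attachable borders from scratch.

    Returns (cores, core_components, eps_n) where core_components is a
    list of frozensets of cores (connected under mutual ε-neighborhood
    chaining) and eps_n maps every node to its ε-neighborhood (closed:
    the node itself always qualifies).
    """
    closed = {v: set(g[v]) | {v} for v in g.nodes}
    eps_n = {}
    for v in g.nodes:
        eps_n[v] = {
            w for w in closed[v]
            if len(closed[v] & closed[w])
            / math.sqrt(len(closed[v]) * len(closed[w])) >= epsilon
        }
    cores = {v for v in g.nodes if len(eps_n[v]) >= mu}
    # connected components of the core-to-core direct-reachability graph
    core_graph = nx.Graph()
    core_graph.add_nodes_from(cores)
    for u in cores:
        for w in eps_n[u]:
            if w in cores:
                core_graph.add_edge(u, w)
    components = [frozenset(c) for c in nx.connected_components(core_graph)]
    return cores, components, eps_n


def check_scan_clustering(g, clustering, epsilon: float, mu: int) -> list[str]:
    """Return a list of definitional violations (empty = fully consistent).

    Checks, by exhaustive recomputation: every module's cores form
    exactly one core component (and each component appears exactly once);
    every non-core member sits in the ε-neighborhood of a core of its own
    module; every node reachable from any core is a member; every
    non-member is a hub iff its graph neighbors span >= 2 modules.
    """
    cores, components, eps_n = scan_reference(g, epsilon, mu)
    label, modules = clustering.label, clustering.modules
    errors: list[str] = []

    comp_of_module = []
    for i, members in enumerate(modules, start=1):
        mod_cores = members & cores
        if not mod_cores:
            errors.append(f"module {i} contains no core")
            continue
        owning = {comp for comp in components if comp & mod_cores}
        if len(owning) != 1 or mod_cores != set(next(iter(owning))):
            errors.append(f"module {i} cores {sorted(mod_cores)} do not "
                          f"match one core component")
            continue
        comp_of_module.append(next(iter(owning)))
        for v in members - cores:
            if not any(v in eps_n[c] for c in mod_cores):
                errors.append(f"border {v} in module {i} is not in the "
                              f"eps-neighborhood of any of its cores")
    if len(set(comp_of_module)) != len(components) or \
            len(comp_of_module) != len(modules):
        errors.append(f"{len(modules)} modules reported but "
                      f"{len(components)} core components exist")

    reachable = set().union(*(eps_n[c] for c in cores)) if cores else set()
    for v in g.nodes:
        if v in reachable and v not in label:
            errors.append(f"{v} is reachable from a core but unclustered")
        if v not in reachable and v in label:
            errors.append(f"{v} is clustered but unreachable from any core")
    for v in g.nodes:
        if v in label:
            continue
        touched = {label[w] for w in g[v] if w in label}
        expected = "hub" if len(touched) >= 2 else "outlier"
        if clustering.role.get(v) != expected:
            errors.append(f"{v}: role {clustering.role.get(v)} but touches "
                          f"{len(touched)} modules")
    return errors


# ---------------------------------------------------------------------------
# Newman modularity (global), via networkx
# ---------------------------------------------------------------------------

def newman_q(g, partition) -> float:
    """Global Newman modularity of a complete partition (networkx)."""
    return nx.algorithms.community.modularity(g, partition)


# ---------------------------------------------------------------------------
# Exact hypergeometric tail (rational arithmetic)
# ---------------------------------------------------------------------------

def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), as an exact Fraction."""
    denom = math.comb(N, n)
    total = sum(math.comb(K, x) * math.comb(N - K, n - x)
                for x in range(k, min(K, n) + 1))
    return Fraction(total, denom)


def hypergeom_all_tails(K: int, n: int, N: int) -> list[Fraction]:
    """Tails P(X >= k) for k = 0..min(K, n), via one backward pass."""
    denom = math.comb(N, n)
    kmax = min(K, n)
    tails = [Fraction(0)] * (kmax + 2)
    for k in range(kmax, -1, -1):
        pmf = Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
        tails[k] = tails[k + 1] + pmf
    return tails[:kmax + 1]


# ---------------------------------------------------------------------------
# Betweenness by exhaustive shortest-path enumeration
# ---------------------------------------------------------------------------

def _all_shortest_paths(g, s, t):
    """Enumerate all shortest s-t paths by BFS layering + DFS (no networkx)."""
    dist = {s: 0}
    frontier = [s]
    while frontier and t not in dist:
        nxt = []
        for v in frontier:
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    if t not in dist:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in g[v]:
            if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def betweenness_enum(g) -> dict:
    """Unnormalized pair betweenness with fractional credit, by listing
    every shortest path of every unordered pair.  Exponential; n <= 10."""
    bt = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        credit = 1.0 / len(paths)
        for p in paths:
            for v in p[1:-1]:
                bt[v] += credit
    return bt


# ---------------------------------------------------------------------------
# PageRank by dense linear solve
# ---------------------------------------------------------------------------

def pagerank_dense(g, damping: float = 0.85) -> dict:
    """Solve the PageRank fixed point directly (dangling mass to uniform)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    deg = a.sum(axis=1)
    p = np.zeros((n, n))
    live = deg > 0
    p[live] = a[live] / deg[live, None]
    dangling = (~live).astype(float)
    m = damping * p.T + (damping / n) * np.outer(np.ones(n), dangling)
    x = np.linalg.solve(np.eye(n) - m, np.full(n, (1.0 - damping) / n))
    return dict(zip(nodes, x))


# ---------------------------------------------------------------------------
# Random test graphs
# ---------------------------------------------------------------------------

def random_string_graph(rng: np.random.Generator, n_max: int = 40):
    """G(n, p) with string node IDs; n and density vary per draw."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.6))
    ids = [f"{i:03d}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(ids[i], ids[j])
    return g


def random_partition(rng: np.random.Generator, nodes) -> list[set]:
    """A random complete partition of the node set into 1..5 parts."""
    nodes = sorted(nodes)
    n_parts = int(rng.integers(1, min(5, len(nodes)) + 1))
    assignment = rng.integers(0, n_parts, size=len(nodes))
    # every part index must be non-empty for a well-formed partition
    for part in range(n_parts):
        if not (assignment == part).any():
            assignment[int(rng.integers(0, len(nodes)))] = part
    parts = [set() for _ in range(n_parts)]
    for v, p in zip(nodes, assignment):
        parts[int(p)].add(v)
    return [p for p in parts if p]
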