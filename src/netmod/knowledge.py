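"""Consensus integration of multi-source interaction records.

Public protein–protein interaction databases overlap only partially and
each carries curation noise.  The integration strategy here is *k-votes*:
merge all sources into one graph over canonical gene IDs, remember for
every edge the set of distinct databases that reported it, and keep an
interaction only if at least ``k`` sources vote for it.  ``k = 1`` is the
plain union; ``k = 2`` keeps interactions confirmed by at least two
independent databases and is the conventional "robust" setting.

Identifier heterogeneity (symbols, accessions, numeric gene IDs) is
resolved up front by an :class:`IdMap` onto one canonical namespace;
records that cannot be mapped are dropped and counted, never silently
lost.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import graph as G

logger = logging.getLogger(__name__)

# Named presets for the two database modes exposed to users: the plain
# union of all sources, and the two-vote consensus subset.
KVOTES_PRESETS = {"union": 1, "k2": 2}


@dataclass(frozen=True)
class InteractionRecord:
    """One raw interaction row: two identifiers plus the source database."""

    a: str
    b: str
    source: str

    def __post_init__(self):
        if not self.source:
            raise ValueError("interaction record with empty source name")
        if not self.a or not self.b:
            raise ValueError("interaction record with empty identifier")


class IdMapCollisionError(ValueError):
    """One alias maps to two different canonical IDs in the mapping table."""


class IdMap:
    """Alias → canonical gene ID mapping.

    Symbol-style aliases (anything non-numeric) are matched
    case-insensitively, numeric aliases exactly — mixed conventions are
    the norm in real gene lists.  Canonical IDs always map to themselves.
    Collisions (one alias pointing at two canonicals) are rejected at load
    time: silent ambiguity would corrupt seed mapping downstream.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._map: dict[str, str] = {}
        self._collisions: list[tuple[str, str, str]] = []
        for alias, canonical in pairs:
            self.add(alias, canonical)
        self._raise_on_collisions()

    @staticmethod
    def _key(alias: str) -> str:
        alias = alias.strip()
        return alias if alias.isdigit() else alias.casefold()

    def add(self, alias: str, canonical: str) -> None:
        alias = alias.strip()
        canonical = canonical.strip()
        if not alias or not canonical:
            raise ValueError("empty alias or canonical ID in mapping table")
        for key, target in ((self._key(alias), canonical),
                            (self._key(canonical), canonical)):
            existing = self._map.get(key)
            if existing is not None and existing != target:
                self._collisions.append((key, existing, target))
            else:
                self._map[key] = target

    def _raise_on_collisions(self) -> None:
        if self._collisions:
            rows = "; ".join(f"{a!r} -> {x!r} and {y!r}"
                             for a, x, y in self._collisions[:10])
            raise IdMapCollisionError(
                f"{len(self._collisions)} ambiguous alias rows in ID map: {rows}")

    def lookup(self, alias: str) -> str | None:
        return self._map.get(self._key(alias))

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "IdMap":
        """Map every given ID to itself (fixtures, pre-canonical inputs)."""
        return cls((i, i) for i in ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        """Load an ``alias<TAB>canonical`` table; '#' comments skipped."""
        m = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = [p.strip() for p in line.split("\t")]
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(
                        f"{path}:{lineno}: expected alias<TAB>canonical, "
                        f"got {line!r}")
                m.add(parts[0], parts[1])
        m._raise_on_collisions()
        return m


def map_ids(raw: Sequence[str], m: IdMap) -> tuple[list[str], list[str]]:
    """Map raw identifiers onto canonical IDs.

    Order-preserving; duplicates after mapping collapse to their first
    occurrence.  Unmapped identifiers are returned (original spelling) as
    a report, not raised as an error.
    """
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for ident in raw:
        canonical = m.lookup(ident)
        if canonical is None:
            unmapped.append(ident)
        elif canonical not in seen:
            seen.add(canonical)
            mapped.append(canonical)
    return mapped, unmapped


@dataclass
class KnowledgeBase:
    """Merged interaction graph with per-edge source support.

    ``support`` maps each unordered edge (as a sorted tuple) to the set of
    distinct source databases reporting it.  ``dropped`` counts records
    discarded during the merge, by reason.
    """

    graph: G.Graph
    support: dict[tuple[str, str], set[str]]
    sources: list[str]
    dropped: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        G.validate(self.graph)
        edge_set = {tuple(sorted(e)) for e in self.graph.edges}
        assert set(self.support) == edge_set, "support keys != edge set"
        src = set(self.sources)
        for pair, supp in self.support.items():
            assert supp, f"edge {pair} with empty support"
            assert supp <= src, f"edge {pair} supported by unknown source"

    def support_histogram(self) -> Counter:
        """Number of edges at each support size (for `kb summary`)."""
        return Counter(len(s) for s in self.support.values())


def merge_sources(records: Iterable[InteractionRecord], m: IdMap) -> KnowledgeBase:
    """Merge tagged interaction records into one consensus knowledge base.

    Endpoints are mapped to canonical IDs; records with any unmapped
    endpoint are dropped and counted (``dropped['unmapped']``), as are
    records whose endpoints collapse onto the same canonical ID
    (``dropped['self_loop']``).  Support counts *distinct source names*,
    not record multiplicity, so a database mentioning a pair twice still
    casts a single vote.  The merge is order-independent.
    """
    g = G.new_graph()
    support: dict[tuple[str, str], set[str]] = {}
    sources: set[str] = set()
    dropped: Counter = Counter()
    for rec in records:
        sources.add(rec.source)
        ca, cb = m.lookup(rec.a), m.lookup(rec.b)
        if ca is None or cb is None:
            dropped["unmapped"] += 1
            continue
        if ca == cb:
            dropped["self_loop"] += 1
            continue
        pair = (ca, cb) if ca < cb else (cb, ca)
        G.add_edge(g, *pair)
        support.setdefault(pair, set()).add(rec.source)
    kb = KnowledgeBase(graph=g, support=support, sources=sorted(sources),
                       dropped=dropped)
    if dropped:
        logger.info("merge_sources dropped records: %s", dict(dropped))
    return kb


def kvotes_filter(kb: KnowledgeBase, k: int) -> G.Graph:
    """Keep edges supported by at least ``k`` distinct sources.

    Isolated nodes are removed from the result.  ``k`` must lie in
    ``1..len(kb.sources)``.
    """
    if not 1 <= k <= max(len(kb.sources), 1):
        raise ValueError(
            f"k={k} out of range 1..{len(kb.sources)} for this knowledge base")
    g = G.new_graph()
    for (u, v), supp in kb.support.items():
        if len(supp) >= k:
            G.add_edge(g, u, v)
    return g


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read an ``id_a<TAB>id_b<TAB>source`` TSV into interaction records."""
    records = []
    for row in G.iter_edge_rows(path):
        if len(row) < 3:
            raise ValueError(
                f"{path}: interaction rows need a third source column: {row}")
        records.append(InteractionRecord(*row))
    return records


def write_interactions(records: Iterable[InteractionRecord],
                       path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id_a\tid_b\tsource\n")
        for rec in records:
            fh.write(f"{rec.a}\t{rec.b}\t{rec.source}\n")
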