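"""Per-module gene-set enrichment by one-sided Fisher's exact test.

Each functional module is tested against every gene set in a collection
(e.g. KEGG pathways in GMT format).  The 2×2 table for module M and set
S over a background universe U is (|M∩S|, |M\\S|, |S\\M|, |U\\(M∪S)|);
the enrichment p-value is the exact hypergeometric upper tail
P(X ≥ k), no normal approximation.  The background universe defaults to
all genes appearing in the collection — universe choice moves every
p-value, so it is explicit and overridable.

Raw p-values are reported (an optional Benjamini–Hochberg column can be
added); very small values render as "<0.0001" in human-readable output
while machine-readable output keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

P_DISPLAY_FLOOR = 1e-4


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate set_ids in gene-set collection")
        if not self.universe:
            self.universe = {g for s in self.sets for g in s.members}
        for s in self.sets:
            if not s.members <= self.universe:
                raise ValueError(
                    f"gene set {s.set_id!r} has members outside the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    overlap_genes: tuple[str, ...]
    k: int
    module_size_in_universe: int
    set_size: int
    universe_size: int
    p_value: float

    def p_display(self) -> str:
        return ("<0.0001" if self.p_value < P_DISPLAY_FLOOR
                else f"{self.p_value:.5f}")


def fisher_greater(k, K: int, n: int, N: int):
    """One-sided (enrichment) Fisher p-value P(X ≥ k), X ~ Hypergeom(N, K, n).

    ``k`` successes drawn, ``K`` marked in the population, ``n`` drawn,
    ``N`` population size.  Margins must be consistent.  ``k`` may be an
    array of overlap counts for the same margins, in which case an array
    of p-values is returned.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: K={K}, n={n}, N={N}")
    ks = np.asarray(k)
    if ((ks < 0) | (ks > min(K, n))).any():
        raise ValueError(f"overlap k={k} outside 0..min(K={K}, n={n})")
    # hypergeom.sf(k-1) = P(X >= k), exact summation under the hood
    p = np.minimum(1.0, hypergeom.sf(ks - 1, N, K, n))
    return p if isinstance(k, np.ndarray) else float(p)


def enrich_module(module_nodes: Iterable[str], coll: GeneSetCollection,
                  seeds: Iterable[str] = ()) -> list[EnrichmentResult]:
    """Test one module against every set in the collection.

    Module genes outside the universe are excluded before testing.  Only
    sets with non-empty overlap are reported, sorted by ascending
    p-value, ties by descending overlap then set_id.  Seed genes in the
    overlap are flagged with a trailing ``*`` in the overlap report.
    """
    if not coll.universe:
        raise ValueError("enrichment requires a non-empty background universe")
    seed_set = set(seeds)
    module_in_universe = set(module_nodes) & coll.universe
    n = len(module_in_universe)
    N = len(coll.universe)
    results = []
    for s in coll.sets:
        overlap = module_in_universe & s.members
        if not overlap:
            continue
        k = len(overlap)
        p = fisher_greater(k, len(s.members), n, N)
        flagged = tuple(g + "*" if g in seed_set else g
                        for g in sorted(overlap))
        results.append(EnrichmentResult(
            set_id=s.set_id, name=s.name, overlap_genes=flagged, k=k,
            module_size_in_universe=n, set_size=len(s.members),
            universe_size=N, p_value=p))
    return sorted(results, key=lambda r: (r.p_value, -r.k, r.set_id))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted q-values, preserving input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p_values[i] * m / rank_from_top)
        q[i] = running
    return q


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

    A description of the form ``name|category`` carries the category
    through; otherwise the category is empty.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need id, description and at "
                    f"least one gene")
            set_id, desc = parts[0].strip(), parts[1].strip()
            name, _, category = desc.partition("|")
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            sets.append(GeneSet(set_id=set_id, name=name or set_id,
                                category=category, members=genes))
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in coll.sets:
            desc = f"{s.name}|{s.category}" if s.category else s.name
            fh.write("\t".join([s.set_id, desc, *sorted(s.members)]) + "\n")


def write_enrichment_table(rows: Sequence[tuple[int, EnrichmentResult]],
                           path, fdr: bool = False) -> None:
    """``(module_id, result)`` rows to TSV; optional BH q-value column."""
    qs: list[float] = []
    if fdr and rows:
        qs = benjamini_hochberg([r.p_value for _, r in rows])
    with open(path, "w", encoding="utf-8") as fh:
        header = ("module_id\tset_id\tname\tk\tset_size\tmodule_size"
                  "\tuniverse_size\tp_value\toverlap_genes")
        fh.write(header + ("\tq_value\n" if fdr else "\n"))
        for i, (mid, r) in enumerate(rows):
            line = (f"{mid}\t{r.set_id}\t{r.name}\t{r.k}\t{r.set_size}"
                    f"\t{r.module_size_in_universe}\t{r.universe_size}"
                    f"\t{r.p_value:.6g}\t{','.join(r.overlap_genes)}")
            fh.write(line + (f"\t{qs[i]:.6g}\n" if fdr else "\n"))
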