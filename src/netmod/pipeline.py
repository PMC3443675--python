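"""End-to-end workflow: seed list → network → ranked modules → enrichment.

One call runs the whole analysis: map seed identifiers, merge the tagged
interaction sources, apply the k-votes consensus filter, build the
seeded network, cluster it with SCAN, rank the modules, test the top
modules for gene-set enrichment, and compute node centralities.  All
outputs are deterministic text files (module table, module summary,
enrichment table, node statistics, a GDF graph file for visualization
tools, and a run log recording every parameter and every dropped
record).

Stage failures surface with the stage name; partially written outputs
are removed so a failed run never leaves a plausible-looking directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

from . import centrality as C
from . import enrichment as E
from . import graph as G
from . import knowledge as K
from . import network as N
from . import scan as S

logger = logging.getLogger(__name__)

OUTPUT_FILES = ("modules.tsv", "module_summary.tsv", "enrichment.tsv",
                "node_stats.tsv", "network.gdf", "run.log")


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    interactions_path: str
    idmap_path: str
    seeds_path: str
    gmt_path: str
    output_dir: str
    kvotes: int = 2
    mode: str = "auto"  # auto | direct | min-links | seeds-only
    min_links_t: int = 2
    epsilon: float = 0.7
    mu: int = 2
    rank_by: str = "seed_count"
    top_k: int = S.DEFAULT_TOP_K
    universe_choice: str = "collection"  # collection | network | file:PATH
    fdr: bool = False

    @classmethod
    def from_file(cls, path: str | Path,
                  overrides: dict | None = None) -> "PipelineConfig":
        """Flat ``key = value`` config file; CLI overrides win."""
        values: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        if overrides:
            values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(values) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced: dict = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if f.type in ("int", int):
                coerced[f.name] = int(raw)
            elif f.type in ("float", float):
                coerced[f.name] = float(raw)
            elif f.type in ("bool", bool):
                coerced[f.name] = (str(raw).lower() in ("1", "true", "yes")
                                   if isinstance(raw, str) else bool(raw))
            else:
                coerced[f.name] = raw
        return cls(**coerced)

    def expansion_mode(self, n_seeds: int) -> N.ExpansionMode:
        if self.mode == "auto":
            return N.select_default_mode(n_seeds)
        return {
            "direct": N.DIRECT_NEIGHBORS,
            "seeds-only": N.SEEDS_ONLY,
            "min-links": N.min_seed_links(self.min_links_t),
        }[self.mode]


@dataclass
class RunReport:
    """Counts mirroring the seed/added-gene accounting of the summary table."""

    n_input_seeds: int = 0
    n_mapped_seeds: int = 0
    unmapped_seeds: list[str] = field(default_factory=list)
    n_seeds_in_kb: int = 0
    mode: str = ""
    n_nodes: int = 0
    n_edges: int = 0
    added_genes: int = 0
    added_edges: int = 0
    n_modules: int = 0
    n_hubs: int = 0
    n_outliers: int = 0
    dropped_records: dict = field(default_factory=dict)
    top_modules: list[S.ModuleSummary] = field(default_factory=list)

    def log_lines(self) -> list[str]:
        return [
            f"input seeds: {self.n_input_seeds}",
            f"mapped seeds: {self.n_mapped_seeds}",
            f"unmapped seeds: {len(self.unmapped_seeds)}"
            + (f" ({', '.join(self.unmapped_seeds[:10])})"
               if self.unmapped_seeds else ""),
            f"seeds found in knowledge base: {self.n_seeds_in_kb}",
            f"expansion mode: {self.mode}",
            f"network nodes: {self.n_nodes}",
            f"network edges: {self.n_edges}",
            f"added genes: {self.added_genes}",
            f"added edges: {self.added_edges}",
            f"modules found: {self.n_modules}",
            f"hubs: {self.n_hubs}",
            f"outliers: {self.n_outliers}",
            f"dropped interaction records: {self.dropped_records}",
        ]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full workflow and write all output files.

    Byte-identical outputs for identical config and inputs: every
    traversal is ordered, nothing is randomized.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(cfg, out)
    except Exception:
        for name in OUTPUT_FILES:  # no plausible partial outputs
            (out / name).unlink(missing_ok=True)
        raise


def _run(cfg: PipelineConfig, out: Path) -> RunReport:
    report = RunReport()
    log_lines = [f"config: {cfg}"]

    idmap = _stage("load_idmap")(K.IdMap.from_tsv)(cfg.idmap_path)
    records = _stage("load_interactions")(K.read_interactions)(
        cfg.interactions_path)
    raw_seeds = _stage("load_seeds")(N.read_seed_list)(cfg.seeds_path)
    coll = _stage("load_gene_sets")(E.read_gmt)(cfg.gmt_path)

    mapped, unmapped = _stage("map_ids")(K.map_ids)(raw_seeds, idmap)
    report.n_input_seeds = len(raw_seeds)
    report.n_mapped_seeds = len(mapped)
    report.unmapped_seeds = unmapped

    kb = _stage("merge_sources")(K.merge_sources)(records, idmap)
    report.dropped_records = dict(kb.dropped)
    kb_graph = _stage("kvotes_filter")(K.kvotes_filter)(kb, cfg.kvotes)

    seeds = N.make_seed_set(mapped, kb_graph)
    report.n_seeds_in_kb = len(seeds.found)
    mode = cfg.expansion_mode(len(seeds.seeds))
    report.mode = str(mode)
    net = _stage("build_network")(N.build_network)(kb_graph, seeds, mode)

    clustering = _stage("scan_cluster")(S.scan_cluster)(
        net.graph, S.ScanParams(cfg.epsilon, cfg.mu))
    summaries = _stage("rank_modules")(S.rank_modules)(
        net.graph, clustering, seeds, cfg.rank_by, cfg.top_k)

    universe = _resolve_universe(cfg, coll, net)
    coll_used = (coll if universe is None
                 else E.GeneSetCollection(sets=coll.sets, universe=universe))
    enrich_rows: list[tuple[int, E.EnrichmentResult]] = []
    for summ in summaries:
        members = clustering.modules[summ.module_id - 1]
        results = _stage("enrich_module")(E.enrich_module)(
            members, coll_used, seeds.seeds)
        enrich_rows.extend((summ.module_id, r) for r in results)

    stats = _stage("centrality")(C.node_stats)(net.graph)

    seed_nodes = net.seed_nodes()
    report.n_nodes = net.graph.number_of_nodes()
    report.n_edges = net.graph.number_of_edges()
    report.added_genes = report.n_nodes - len(seed_nodes)
    report.added_edges = report.n_edges
    report.n_modules = len(clustering.modules)
    report.n_hubs = sum(1 for r in clustering.role.values() if r == S.HUB)
    report.n_outliers = sum(1 for r in clustering.role.values()
                            if r == S.OUTLIER)
    report.top_modules = summaries

    S.write_module_table(clustering, seeds, out / "modules.tsv")
    S.write_summary_table(summaries, out / "module_summary.tsv")
    E.write_enrichment_table(enrich_rows, out / "enrichment.tsv", fdr=cfg.fdr)
    C.write_stats_table(stats, out / "node_stats.tsv")
    write_gdf(net, clustering, stats, out / "network.gdf")
    log_lines.extend(report.log_lines())
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    logger.info("pipeline finished: %d nodes, %d edges, %d modules",
                report.n_nodes, report.n_edges, report.n_modules)
    return report


def _resolve_universe(cfg: PipelineConfig, coll: E.GeneSetCollection,
                      net: N.SeededNetwork) -> set[str] | None:
    if cfg.universe_choice == "collection":
        return None
    if cfg.universe_choice == "network":
        return set(net.graph.nodes) | coll.universe
    if cfg.universe_choice.startswith("file:"):
        path = cfg.universe_choice[len("file:"):]
        return set(N.read_seed_list(path)) | {g for s in coll.sets
                                              for g in s.members}
    raise ValueError(f"unknown universe choice {cfg.universe_choice!r}")


# ---------------------------------------------------------------------------
# GDF export/import (GUESS graph-definition format)
# ---------------------------------------------------------------------------

GDF_NODEDEF = ("nodedef>name VARCHAR,label VARCHAR,is_seed BOOLEAN,"
               "module VARCHAR,role VARCHAR,pagerank DOUBLE,"
               "betweenness DOUBLE")
GDF_EDGEDEF = "edgedef>node1 VARCHAR,node2 VARCHAR"


def write_gdf(net: N.SeededNetwork, c: S.Clustering,
              stats: Sequence[C.NodeStats], path: str | Path) -> None:
    """Write the network with node attributes in GDF.

    Nodes and edges in lexicographic order; an unassigned module renders
    as the empty string.  Round-trippable by :func:`read_gdf`.
    """
    by_node = {s.node: s for s in stats}
    missing = set(net.graph.nodes) - set(by_node)
    if missing:
        raise ValueError(f"stats missing for nodes: {sorted(missing)[:5]}")
    lines = [GDF_NODEDEF]
    for v in G.sorted_nodes(net.graph):
        mid = str(c.label[v]) if v in c.label else ""
        s = by_node[v]
        lines.append(f"{v},{v},{str(net.is_seed[v]).lower()},{mid},"
                     f"{c.role[v]},{s.pagerank:.10g},{s.betweenness:.10g}")
    lines.append(GDF_EDGEDEF)
    lines.extend(f"{u},{v}" for u, v in G.sorted_edges(net.graph))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gdf(path: str | Path) -> tuple[G.Graph, dict[str, dict]]:
    """Read a GDF file written by :func:`write_gdf`.

    Returns the graph and per-node attributes
    (is_seed, module, role, pagerank, betweenness).
    """
    g = G.new_graph()
    attrs: dict[str, dict] = {}
    section = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("nodedef>"):
                section = "nodes"
                continue
            if line.startswith("edgedef>"):
                section = "edges"
                continue
            parts = line.split(",")
            if section == "nodes":
                name, _, is_seed, module, role, pr, btw = parts
                g.add_node(name)
                attrs[name] = {"is_seed": is_seed == "true",
                               "module": module, "role": role,
                               "pagerank": float(pr),
                               "betweenness": float(btw)}
            elif section == "edges":
                G.add_edge(g, parts[0], parts[1])
            else:
                raise ValueError(f"{path}: data before nodedef> header")
    return g, attrs
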