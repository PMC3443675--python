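# Methods

## Model and procedure

The package treats an interactome as an undirected simple graph over
canonical gene identifiers. Directionality, interaction weights,
self-interactions and duplicate records carry no information for the
analyses performed here and are discarded at ingestion (self-loops and
unmappable records are counted and logged, never silently dropped).

The analysis proceeds in five stages.

**1. Consensus knowledge base.** Interaction records from multiple
source databases are mapped onto one canonical ID namespace and merged.
Support is counted in *distinct source names*, not record mentions, so a
database that lists a pair twice still casts one vote. The k-votes
filter keeps an edge iff its support is ≥ k; edge sets therefore nest
monotonically in k, with k = 1 the union and k = n_sources the
intersection. ID-map rows are matched case-insensitively for
symbol-style aliases and exactly for purely numeric aliases, reflecting
how gene symbols and numeric IDs are used in practice; an alias pointing
at two canonical IDs aborts the load, because silent ambiguity would
corrupt seed mapping downstream.

**2. Seed expansion.** Given seed set S and the consensus graph, the
network is: *direct neighbors* — S plus all genes adjacent to S;
*min-seed-links(t)* — S plus non-seeds adjacent to strictly more than t
seeds (t = 2 by default); or *seeds only* — the induced subgraph on S.
In the expanded modes an edge is included only if at least one endpoint
is a seed, which keeps the network anchored on the user's list and
yields the containment chain seeds_only ⊆ min_seed_links(t) ⊆
direct_neighbors. The default mode switches from direct neighbors to
seeds-only above 1000 seeds (exactly 1000 still expands — expansion is
the tool's default behavior and the boundary had to land somewhere).
Mapped seeds absent from the knowledge base are retained as isolated,
seed-flagged nodes so reported seed counts match the user's list; lists
beyond 3000 seeds trigger a warning but are processed.

**3. SCAN clustering.** Structural similarity of adjacent nodes is
σ(u,v) = |Γ(u)∩Γ(v)|/√(|Γ(u)||Γ(v)|) with Γ the **closed** neighborhood
(the node included), so σ(v,v) = 1 and σ = 1 exactly when two nodes have
identical closed neighborhoods. A node is a core when at least μ of its
closed-neighborhood members (itself included) have σ ≥ ε; modules are
the structure-reachability closures of cores. Defaults ε = 0.7, μ = 2
are the canonical SCAN setting and are exposed as parameters. Nodes in
no module are hubs when their graph neighbors span ≥ 2 modules,
otherwise outliers.

Determinism: nodes are visited in lexicographic ID order and each
border node (a non-core reachable from cores of more than one module)
stays with the module that reaches it first in that order. Border
assignment is the only order-dependent part of SCAN; fixing the order
makes module IDs and all output files stable across runs, and the test
suite checks the *definitional* predicates (core status, reachability,
role rules) rather than specific border assignments.

Complexity: σ is computed once per edge via a set intersection, so
clustering costs O(Σ_(u,v)∈E min(deg u, deg v)) — near-linear in edge
count at bounded degree. The benchmark in the acceptance script
clusters a ~1.1·10⁵-edge planted graph (25 blocks × 100 nodes,
p_in = 0.9, p_out = 0.001) in well under a minute on one CPU and
compares it against a ~1.3·10⁴-edge graph of equal block size (3 × 100),
so the two differ in edge count but not expected degree and the runtime
ratio isolates edge-count scaling.

**4. Module quality and ranking.** Each module i is scored by the
per-community decomposition of Newman's modularity, Q_i = e_ii − a_i²
(e_ii = fraction of edges inside i, a_i = fraction of edge endpoints
attached to i); the terms sum to the global Newman Q over any complete
partition, which the tests verify against an independent implementation
to 1e-12. Modules are ranked by seed count (default), size, or Q_i; ties
break toward the larger module, then toward the module containing the
lexicographically smallest gene ID. The default report shows the top 6.
No statistical significance test is attached to modules; the ranking
criteria serve that role.

**5. Enrichment.** Each reported module is tested against every set in
a GMT collection with the one-sided Fisher exact test — the exact
hypergeometric upper tail P(X ≥ k), no normal approximation (delegated
to scipy's exact survival function and verified against rational-
arithmetic tail sums to 1e-12 for all N ≤ 60). The background universe
defaults to all genes in the collection; this choice moves every
p-value, so it is explicit and can be set to the network's gene set or a
user file. Raw p-values are reported, ordered ascending with ties broken
by larger overlap; a Benjamini–Hochberg q-value column is optional and
off by default. Human-readable output prints p < 1e-4 as "<0.0001";
machine output keeps full precision. All module genes are tested (not
only seeds); seed genes in the overlap are starred in the report.

**Centralities.** PageRank: uniform teleport, damping 0.85, dangling
mass redistributed uniformly (so scores sum to 1; verified against a
dense linear solve). Degree centrality: degree/(n−1). HITS: on an
undirected graph hub and authority scores coincide with the principal
adjacency eigenvector; it is computed by shifted power iteration on
A + I from the uniform vector (the shift removes the period-2
oscillation plain power iteration exhibits on bipartite graphs, without
changing eigenvectors) and reported L2-normalized. On a disconnected
graph with tied dominant components the uniform start spreads mass over
the tie deterministically — documented behavior rather than an error.
Betweenness: Brandes' algorithm, unnormalized pair-based counts with
fractional credit across equal-length shortest paths; a normalized
variant divides by (n−1)(n−2)/2.

## Synthetic data

The fixtures module generates complete studies with known ground truth.
The interactome is a planted-partition graph: blocks of genes joined
within with probability p_in and between with p_out (defaults 4 blocks ×
20 genes, p_in = 0.9, p_out = 0.02 — dense modules, sparse background).
Source databases are simulated by independent per-source edge sampling
at a coverage rate (default 3 sources × 0.8), so per-edge support is
Binomial(n_sources, coverage) and k-votes behavior is analytically
predictable. Seed lists sample a fraction (default 0.5, floored) of
chosen blocks, emulating a disease signature drawn from affected
modules. Annotations provide one gene set per block with a noise
fraction of members swapped out (default 0.1) plus uniformly random
decoy sets (default 10, of mean block size). A single seed reproduces an
entire scenario bit for bit.

What the generator does **not** emulate: heavy-tailed PPI degree
distributions, literature-curation bias (correlated source errors),
study-specific ID-mapping failures, or overlapping pathway annotations.
Equal independent edge probabilities were chosen over degree-corrected
models so expected edge counts and supports have closed forms the tests
can assert. Passing recovery tests therefore demonstrates correctness
of the machinery on well-separated modules, not performance on real
interactomes, where module boundaries are far blurrier.

## Numerical and design notes

- All output files order nodes and edges lexicographically; pipeline
  re-runs are byte-identical (asserted in tests).
- σ and Q_i are plain floating point; the 1e-12 test tolerances reflect
  accumulation over ≤ a few thousand terms.
- `fisher_greater` accepts a vector of overlap counts for one margin
  triple, the natural batch shape for sweeps.
- Degenerate inputs: empty graphs cluster to an empty result; modularity
  and PageRank on an empty graph, degree centrality on < 2 nodes, HITS
  without edges, and enrichment with an empty universe raise errors
  naming the problem; module-less nodes export an empty module field
  (never the string "None").
- The per-module modularity can be negative (a module sparser inside
  than random); the whole-graph "module" scores exactly 0.
- Problem sizes in tests and the acceptance script (200 definition-check
  graphs at n ≤ 40, 20 recovery replicates, 40 end-to-end replicates,
  the 10⁵-edge benchmark) were chosen to exercise each property at
  desk scale; all are parameters, not limits of the method.

## Known limitations

- Single canonical namespace; no cross-species mapping.
- No multi-hop expansion and no confidence-weighted edges.
- SCAN's ε is not self-tuned; poorly separated networks may need manual
  adjustment.
- Enrichment treats gene sets as flat; hierarchical relations between
  pathways are ignored.
- The REACTOME-style flattening of pathway data into binary
  interactions is out of scope: the loader accepts pre-flattened pair
  lists only.
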