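"""Expand a seed gene list into an analysis network.

Builds a tiny knowledge base, then compares the three construction
modes: direct neighbors (default under 1000 seeds), min-seed-links
(keep an added gene only if it touches more than t seeds), and
seeds-only (induced subgraph; default above 1000 seeds).
"""

import netmod as nm

kb = nm.new_graph()
for u, v in [("s1", "x"), ("s2", "x"), ("s3", "x"),   # x touches 3 seeds
             ("s1", "y"),                              # y touches 1 seed
             ("x", "y"),                               # non-seed/non-seed
             ("s1", "s2")]:
    nm.add_edge(kb, u, v)

seeds = nm.make_seed_set(["s1", "s2", "s3"], kb)
print(f"default mode for {len(seeds.seeds)} seeds:",
      nm.select_default_mode(len(seeds.seeds)).kind)

for mode in (nm.DIRECT_NEIGHBORS, nm.min_seed_links(2), nm.SEEDS_ONLY):
    net = nm.build_network(kb, seeds, mode)
    edges = sorted(tuple(sorted(e)) for e in net.graph.edges)
    print(f"{str(mode):22s} nodes={sorted(net.graph.nodes)} edges={edges}")

print("x survives min_seed_links(t=2) because it touches 3 > 2 seeds;")
print("y does not (1 seed), and the x-y edge is always excluded because")
print("edges must have at least one seed endpoint in expanded modes.")
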