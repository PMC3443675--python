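"""The whole workflow on a synthetic study with known ground truth.

Generates a planted-module scenario (4 functional modules of 20 genes,
3 simulated source databases, seeds sampled from 2 modules, annotations
aligned with the planted blocks), writes it to disk, runs the pipeline,
and prints the run report plus the top enrichment hit per module.
"""

import tempfile
from pathlib import Path

from netmod import fixtures as F
from netmod.pipeline import PipelineConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="netmod_demo_"))
scenario = F.make_scenario(rng_seed=7)
paths = F.write_scenario(scenario, workdir / "inputs")

config = PipelineConfig(
    interactions_path=str(paths["interactions"]),
    idmap_path=str(paths["idmap"]),
    seeds_path=str(paths["seeds"]),
    gmt_path=str(paths["gmt"]),
    output_dir=str(workdir / "results"),
    kvotes=2)
report = run_pipeline(config)

for line in report.log_lines():
    print(line)

print("\ntop enrichment hit per module (from enrichment.tsv):")
seen = set()
for line in (workdir / "results" / "enrichment.tsv").read_text().splitlines()[1:]:
    module_id, set_id, name, k, *_ = line.split("\t")
    if module_id not in seen:
        seen.add(module_id)
        print(f"  module {module_id}: {set_id} ({name}), overlap {k}")

print(f"\nall outputs in {workdir / 'results'}")
print("Seeds were drawn from planted blocks"
      f" {scenario.seeded_blocks}; the pipeline recovers one module per")
print("seeded block and each module's top-ranked gene set is the one")
print("aligned with its planted block.")
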