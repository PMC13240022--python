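"""One-call end-to-end run on the default synthetic design, with exports.

Equivalent to `regfate run --outdir ... --seed 17` from the shell: simulates
all inputs (3,000 cells, 100 regulons, drivers, a 300-patient cohort), runs
QC -> activity -> RSS/CSI/modules -> state regulons -> fate networks ->
signature/survival, and writes every artifact (TSV/GraphML/JSON manifest).
"""

from regfate import PipelineConfig
from regfate.pipeline import export_results, run_pipeline

config = PipelineConfig(outdir="scratch/pipeline_demo", seed=17)
results = run_pipeline(config)
written = export_results(results, config.outdir, config)

print(f"wrote {len(written)} files to {config.outdir}")
print(f"regulons kept after scoring: {results.activity.shape[1]}")
print(f"state-specific calls: {int(results.state_calls['selected'].sum())}")
for fate, graph in sorted(results.networks.items()):
    print(f"  {fate}: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
hr = results.signature["cox_univariable"].loc["signature", "HR"]
print(f"signature HR per 1-SD in the synthetic cohort: {hr:.2f} "
      f"(true log-hazard planted at {0.6})")
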