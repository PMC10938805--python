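"""Run the full pipeline at the default study size and read the recovery
report: how well the analysis recovers the planted ground truth.

Equivalent shell command:  stageomics run-all --seed 1 --out-dir run_out
"""

import json

import stageomics as so

manifest = so.run_pipeline(so.PipelineConfig(seed=1), "run_out")

print(f"outputs written: {len(manifest['outputs'])}")
print("ground-truth recovery:")
for key, value in manifest["recovery"].items():
    print(f"  {key:>28}: {value}")
print(json.dumps({"seed": manifest["seed"],
                  "version": manifest["version"]}, indent=2))
# edge/dmr sensitivity ~1.0 and FDR well below 0.1, cluster ARI 1.0 and
# coupling sign recovery 1.0 mean every planted layer of structure was
# recovered by the pipeline at its default thresholds.
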