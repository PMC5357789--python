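"""End-to-end pipeline run: simulate → screen-array → screen-pairs → classify.

Equivalent to `exopair run --seed 3 --out exopair-run` on the shell; all
stage outputs (TSV tables, truth sidecars, summary.json) land in the run
directory and rerunning with the same seed reproduces them exactly.
"""

import json

from exopair import PipelineConfig, run_pipeline

config = PipelineConfig(seed=3, out="scratch/example-run")
summary = run_pipeline(config)

print("candidate union:",
      len(summary["array_screen"]["candidate_union"]), "miRNAs")
print("selected pairs:")
for p in summary["pair_screen"]["selected_pairs"]:
    print(f"  {p['trend']:8s} {p['target']} / {p['reference']}")
print("classifier confusion:",
      json.dumps(summary["classifier"]["confusion"]))
print("KD sensitivity:", round(summary["classifier"]["kd_sensitivity"], 3),
      "specificity:", round(summary["classifier"]["kd_specificity"], 3))
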