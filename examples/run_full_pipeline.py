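"""Run the whole pipeline for one stratum and inspect the manifest.

Equivalent to ``cmcpatterns all --stratum elsa/male --n 400 --quick``;
all stages are seeded, so rerunning with the same config reproduces
every CSV/JSON output byte for byte.
"""

import json
from pathlib import Path

from cmcpatterns import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=11,
    outdir="scratch/example_run",
    strata=(("elsa", "male"),),
    n=400,
    quick=True,
    k_range=(2, 6),
)
manifest = run_pipeline(config)

print("completed:", manifest.completed)
for stage in manifest.stages:
    print(f"  {stage['stage']:<28} {stage['seconds']:.1f}s")
print("outputs:")
for path in manifest.outputs:
    print("  ", path)

metrics = json.loads(Path(config.outdir, "elsa_male", "metrics.json").read_text())
print("classifier mean metrics:", {k: round(v, 3) for k, v in metrics["mean"].items()})
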