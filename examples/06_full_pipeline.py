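"""Run the deterministic multi-stage pipeline and inspect its manifest.

Executes the in-vitro kinetics and transcript-count stages (the fast
ones) with a fixed master seed, writing every artifact plus a manifest of
SHA-256 checksums. Re-running with the same seed reproduces the manifest
bit for bit; the simulation stage can be added via
``stages=(..., "simulation")`` when a few minutes of runtime are fine.
"""

import json
from pathlib import Path

from alternans import pipeline

out = Path("pipeline_out")
config = pipeline.PipelineConfig(
    stages=("titration", "stopped_flow", "counts"),
    master_seed=42,
    out_dir=str(out),
)
manifest = pipeline.run_pipeline(config)

print(f"stages run : {manifest['stages']}")
print(f"stage seeds: {manifest['stage_seeds']}")
print("artifacts  :")
for name, info in sorted(manifest["files"].items()):
    print(f"  {name:28s} [{info['stage']}]  sha256={info['sha256'][:12]}...")

fits = json.loads((out / "titration_fits.json").read_text())
print(
    f"\nKd ratio WT/variant from the titration stage: "
    f"{fits['comparison']['fold_ratio']:.2f} (p = {fits['comparison']['p_value']:.1e})"
)
print("Identical master seeds reproduce identical checksums end to end.")
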