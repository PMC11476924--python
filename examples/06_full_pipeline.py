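"""Run the whole pipeline (synthetic demo cohort) and list its outputs.

Equivalent shell command:  chemoatlas all --out out/ --seed 1
"""

import json
import tempfile
from pathlib import Path

from chemoatlas import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    outputs = run_pipeline(RunConfig(seed=1, n_per_arm=8), tmp)
    for key in sorted(outputs):
        print(f"  {key:15} {Path(outputs[key]).name}")
    correlations = json.loads(Path(outputs["correlations"]).read_text())
    print("\nmouse-model correlations vs human aggregate:")
    for c in correlations:
        print(f"  {c['model_id']:14} r = {c['r']:.2f}  (n = {c['n']})")
# Tables (TSV/JSON) are byte-identical across reruns with the same seed.
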