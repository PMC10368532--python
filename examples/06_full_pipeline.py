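"""Run the whole pipeline on a demo cohort and inspect the manifest.

Equivalent shell command:  mosaic-evo run --out demo_run --seed 42
"""

import json
import tempfile
from pathlib import Path

from mosaicevo import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(seed=42, cohort={"n_mice": 3, "samples_per_mouse": 3})
    manifest = run_pipeline(cfg, tmp)
    print(json.dumps(manifest["stages"], indent=1))
    print("outputs:", sorted(p.name for p in Path(tmp).iterdir()))
# rerunning with the same seed reproduces every output byte for byte
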