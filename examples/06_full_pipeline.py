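"""End-to-end pipeline run with report rendering.

Equivalent to `dispatchtrial run-all --out out/ --seed 2` with a reduced
problem size: simulate -> impute -> analyze -> report, all tables written
as CSV and Parquet plus a results JSON and a run manifest.
"""

import json
import tempfile
from pathlib import Path

from dispatchtrial import GeneratorConfig, run_pipeline

cfg = GeneratorConfig(n_rcs=600, m_imputations=4, mice_iterations=5,
                      mice_engine="pmm", seed=2)
outdir = Path(tempfile.mkdtemp(prefix="dispatchtrial_"))
results, manifest = run_pipeline(cfg, outdir)

print(f"outputs in {outdir}:")
for name in sorted(p.name for p in outdir.iterdir()):
    print(f"  {name}")
print()
print((outdir / "report.txt").read_text())
print(f"config hash {manifest.config_hash}; rerunning with the same config "
      "and seed reproduces these tables byte for byte.")
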