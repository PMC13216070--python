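"""Validate the simulated survey tables and emit model-ready data.

Runs the ingestion rules (missing-value translation, monitored-day and
frequency invariants, duplicate-recall rejection) over the 10%-coverage
campaign and writes one tidy CSV per submodel plus the ingestion report.

Expected on synthetic input: zero flags and zero exclusions — the
generator's output satisfies the schema by construction.
"""

import json
from pathlib import Path

from wildmeat.pipeline import RunConfig, run_pipeline

out = Path("results/sim/cov10")
if not (out / "studies.csv").exists():
    raise SystemExit("run analysis/01_simulate.py first")

cfg = RunConfig(out_dir=str(out), seed=0, stages=("ingest",))
report = run_pipeline(cfg)["ingest"]
print("ingestion counts:", json.dumps(report["counts"], indent=1))
print("flags:", report["flags"] or "none")
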