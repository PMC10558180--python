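#!/usr/bin/env python
"""Generate the default synthetic cohort and write its case manifest.

Thirteen multimodal phantom cases mirror the study composition — 4
gadolinium-enhancing tumors, 5 non-enhancing tumors visible on PET, and 4
non-enhancing tumors invisible on PET; the last two cases lack a lectin
channel.  Volumes are written as NIfTI under scratch/ (they are bulky,
regenerable inputs, not results); the manifest TSV goes to results/.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

from tumorburden.core import mask_volume_mm3
from tumorburden.pipeline import PipelineConfig, run_pipeline

SEED = 1

cfg = PipelineConfig(out_dir="scratch/cohort", seed=SEED, stages=("simulate",),
                     write_volumes=True)
products = run_pipeline(cfg)
cases = products["cases"]

Path("results").mkdir(exist_ok=True)
manifest = Path("scratch/cohort/case_manifest.tsv")
Path("results/case_manifest.tsv").write_bytes(manifest.read_bytes())

print(f"simulated {len(cases)} cases (seed {SEED}) -> scratch/cohort/, manifest -> results/")
for case in cases:
    print(f"  {case.case_id}  {case.stratum:18s}  truth {mask_volume_mm3(case.truth):6.1f} mm^3"
          f"  lectin={'yes' if case.lectin is not None else 'no'}")
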