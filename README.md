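# tumorburden

Whole-brain tumor-burden detection analysis for multimodal preclinical
imaging.  Conventional MRI (gadolinium-enhanced T1w, T2w) under-detects
invasive, non-enhancing glioma, and amino acid PET sees some of what MRI
misses — but quantifying either claim needs a whole-brain ground truth.
This package implements the full analysis chain for studies that obtain one
from ex vivo fluorescence imaging of optically cleared brain slices
(a tdTomato tumor-cell marker): landmark-based co-registration of all
modalities into one frame, threshold segmentation per modality, voxel-wise
detection scores against the fluorescence truth, exact nonparametric group
comparisons, and a regression of PET uptake on biologic correlates.  A
synthetic multimodal phantom generator provides a fully controlled test
bed, and the published 13-tumor per-tumor score table ships as a fixture so
every summary statistic can be re-derived from printed data.

It is aimed at researchers doing multimodal validation studies
(PET/MRI vs histology or cleared-tissue ground truth) who want the scoring
and statistics to be exact, contract-checked and reproducible.

## What it computes

For detection masks A (a modality) and truth T inside a brain region B, on
a common grid with anisotropic voxel spacing in mm:

- sensitivity = |A ∩ T| / |T|
- specificity = (|B| − |(A ∪ T) ∩ B|) / (|B| − |T|)
- Dice = 2|A ∩ T| / (|A| + |T|)
- maximum surface distance = max over both masks' surface voxels of the
  minimum world-mm distance to the other surface (worst-case symmetric
  Hausdorff); "nd" when the tumor is entirely undetected

Modalities scored: T1, T2, T1+T2 ("MRI"), PET, MRI+PET, and a 2-mm
metrically expanded MRI.  Groups (all / Gd+ / Gd− / Gd− by PET visibility)
are summarized as median (min, max) and compared with *exact* Wilcoxon
tests — signed-rank with zeros discarded and midranks for paired modality
contrasts, rank-sum for Gd+ vs Gd− — enumerated by dynamic programming, so
tied data at n = 13 need no normal approximation.  PET uptake, normalized
to contralateral normal brain, is log-standardized and regressed on
tdTomato, ASCT2, lectin, tumor volume and enhancement status, with
added-variable plots whose slopes equal the multivariate coefficients
(Frisch–Waugh–Lovell).

See `docs/methods.md` for conventions, numerical choices, and what the
phantom does and does not emulate.

## Worked example

The numbered scripts under `analysis/` run the study end to end; each
writes TSV reports under `results/`.  Re-deriving the published summary
from the packaged per-tumor table:

```sh
$ python analysis/03_fixture_reanalysis.py
overall median sensitivity: PET 0.67  MRI 0.61  MRI+PET 0.86
combined gain: 41% over MRI, 28% over PET
overall median specificity: PET 0.93  MRI 0.97
Gd+ vs Gd- combined-MRI sensitivity: 0.74 vs 0.52
```

Combining PET with MRI raises median detection sensitivity from 0.61 (MRI
alone) to 0.86 — a 41% gain, exact signed-rank p = 0.004 (and 28% over PET
alone, p = 0.0002) — at a small specificity cost (p = 0.004 vs MRI, 0.002
vs PET).  The script also flags the five cells where the published
overall-median row disagrees with its own 13 rows (the recomputed value is
kept).

The same analysis on a freshly simulated 13-case phantom cohort:

```sh
$ python analysis/02_score_cohort.py
overall median sensitivity by modality:
T1              0.00
T2              0.72
T1+T2           0.72
PET             0.66
MRI+PET         0.84
...
MRI+PET T1+T2  0.840517  0.722919      0.004
MRI+PET   PET  0.840517  0.661341     0.0002
```

The synthetic cohort reproduces the qualitative pattern — the union beats
either modality, with the same exact p-values arising from all-positive
paired differences.  `analysis/04_pet_correlates.py` fits the uptake
regression on the same cohort (tumor-level lectin-free model: tdTomato
β = 0.92, the largest standardized coefficient, R² = 0.97) and exports
partial-regression plots.

Library use mirrors the scripts:

```python
from tumorburden.phantom import generate_cohort
from tumorburden.pipeline import score_phantom_cohort
from tumorburden.group_stats import summarize_cohort

cohort = generate_cohort(master_seed=1)          # 4 Gd+, 5 Gd- PET+, 4 Gd- PET-
scores, info = score_phantom_cohort(cohort)      # per-tumor DetectionResults
summary, comparisons = summarize_cohort(scores, info)
```

A `tumorburden` console script wraps the pipeline
(`tumorburden fixture|simulate|score|summarize|correlate|all`, with
`--config config.yaml --seed N --out DIR`).

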