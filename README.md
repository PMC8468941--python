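# voltraj

Normative brain-volume growth trajectories and study-level deviation
contrasts.

`voltraj` fits a hybrid growth model — a saturating early-growth term plus a
cubic polynomial,

```
f(age) = b4 * (1 - exp(-age / b5)) + b0 + b1*age + b2*age^2 + b3*age^3
```

— to individual-level reference data for five volumetric measures (GMV, WMV,
TIV, GMV/TIV, WMV/TIV), builds pointwise 95% confidence and prediction bands
(first-order delta method or parametric Monte Carlo), and classifies
study-level group means from a summary table into ordered deviation
categories (`below_PI`, `below_CI`, `within_CI_below`, `within_CI_above`,
`above_CI`, `above_PI`) with a standardized z-score companion.

Because the original reference MRI datasets are not redistributable, the
package ships a seeded synthetic-data module that generates full-term
reference cohorts (880 subjects across four source-dataset labels by
default) and preterm study-summary tables with configurable age-dependent
deficits, so the entire pipeline runs and is tested offline. A transcription
of the published 14-row preterm study-summary table is included as package
data.

## Modules

| module | what it does |
| --- | --- |
| `voltraj.study_table` | parse/validate study-summary CSVs, unit harmonization (months→years, mm³/dm³→cm³, kg→g, ratio↔volume), eligibility filtering, same-cohort deduplication, cohort accounting |
| `voltraj.normative_model` | hybrid-model fitting (bounded multi-start least squares), delta-method and Monte-Carlo confidence/prediction bands |
| `voltraj.deviation_contrast` | band interpolation, six-category ordinal classifier, z-scores, contrast tables |
| `voltraj.synthetic_data` | seeded generators for full-term cohorts and preterm study tables |
| `voltraj.cli` | `voltraj` command-line interface |

## CLI

```bash
# 1. generate synthetic inputs (deterministic per seed)
voltraj simulate --seed 7 --out runs/sim

# 2. fit all five measures and write bands
voltraj fit --scans runs/sim/ft_scans.csv --out runs/fits --level 0.95

# 3. classify study means against the bands (optionally with plots)
voltraj contrast --studies runs/sim/pt_studies.csv --fits runs/fits \
    --out runs/contrast --plot --scans runs/sim/ft_scans.csv

# 4. bundle cohort accounting and category counts
voltraj report --studies runs/sim/pt_studies.csv \
    --contrast runs/contrast/contrast.csv --out runs/report.json
```

Every command writes a provenance sidecar (input hashes, settings, seed,
version) and refuses to overwrite existing outputs without `--force`.
`simulate` accepts a YAML config mirroring `GeneratorConfig` (plus an
optional `pt_designs` list); `fit` supports `--method monte_carlo --seed N`
for Monte-Carlo bands.

## Library example

```python
import numpy as np
from voltraj import normative_model as nm, synthetic_data as sd
from voltraj.deviation_contrast import contrast_table
from voltraj.study_table import filter_eligible, load_packaged_study_table

config, designs = sd.default_paper_mimic_config(seed=1)
scans = sd.generate_ft_cohort(config)

grid = nm.default_age_grid()
fits = {}
for measure in nm.MEASURES:
    fit = nm.fit_hybrid(scans, measure)
    fits[measure] = (fit, nm.confidence_band(fit, grid, 0.95))

records = filter_eligible(load_packaged_study_table())
calls = contrast_table(records, fits)   # 14 rows x 5 measures
```
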