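# mifqc — validation statistics for multiplex immunofluorescence panels

Multiplex immunofluorescence (mIF) labels several protein biomarkers on one
tissue section, and whole-slide image analysis reduces each slide to a
per-cell table: centroid coordinates plus the mean intensity of every
marker channel. Before such a panel can be trusted in a study, two
questions must be answered quantitatively:

* **Accuracy (concordance)** — does a marker behave the same in the
  multiplex assay as in a 1-plex assay of an adjacent serial section?
* **Precision** — how reproducible are the derived endpoints (% positive
  cells, cell–cell distances) across replicate sections within one
  staining run and across runs?

`mifqc` implements the statistics of that validation workflow for people
who run mIF panels (imaging scientists, quantitative pathology groups) and
for people who analyze the exports. It starts from per-cell tables — not
images — and provides:

* **Gating** of marker positivity, either with one fixed *global*
  threshold per marker or with per-run *local* thresholds computed by
  Otsu's method (maximizing the between-class variance
  `w0·w1·(μ0−μ1)²` of the pooled within-run intensities), plus
  priority-ordered phenotype calling from boolean marker combinations
  (e.g. T_reg = CD3ε⁺CD4⁺FoxP3⁺ before T_helper = CD3ε⁺CD4⁺FoxP3⁻).
* **Concordance** reports: symmetric Bland–Altman relative differences
  `100·(a − b)/((a + b)/2)` between 4-plex and 1-plex % positive cells and
  mean intensities, with a ±20 % annotation band.
* **Precision** reports: intra-run and inter-run coefficients of variation
  `CV = 100·sd/mean` of % positive cells, with the customary 25 % working
  cutoff.
* **Multiplex labeling efficiency (MLE)** — per marker, the percentage of
  its positive cells that fall into valid multi-marker phenotypes
  containing it, e.g. `MLE(CD8α) = 100·#T_cyt / #CD8α⁺`. Tracked across
  runs (ideally on a control specimen), MLE flags runs whose labeling
  drifted, with a ±10 percentage-point default band.
* **Directional nearest-neighbor distances** between phenotypes
  (A→B ≠ B→A when abundances differ), their cross-section CV, and a
  Mann–Whitney comparison of the two directions.
* A **synthetic tissue generator** that emulates the study designs —
  Poisson cell positions, exclusive ground-truth phenotype classes with
  serial-section composition jitter, lognormal signal/background intensity
  populations, and per-run multiplicative channel gains — so every
  statistic can be validated against known ground truth.

## Worked example

Simulate the precision design (5 staining runs × 3 replicate serial
sections of a high-T-cell-density tumor model, run gains drawn log-uniform
from [0.5, 2]), re-threshold each run with Otsu, and summarise:

```python
from mifqc.pipeline import PipelineConfig, run_validation_pipeline
from mifqc.synthetic_tissue import single_specimen_config

cfg = PipelineConfig(out_dir="demo", design="precision",
                     sim=single_specimen_config("CT26"), seed=7, mode="local")
res = run_validation_pipeline(cfg)
print(res["precision"].summary[["entity", "intra_run_cv_mean", "inter_run_cv"]])
```

```
  entity  intra_run_cv_mean  inter_run_cv
    CD3e               4.49          4.64
     CD4               3.28          3.77
    CD8a               7.12          7.40
   FoxP3               8.87          8.91
   T_reg              10.81         12.33
T_helper               6.63          6.68
   T_cyt               9.01          8.83
```

Under local gating every entity's inter-run CV sits well below the 25 %
cutoff and is barely distinguishable from its intra-run CV: per-run
re-thresholding has absorbed the simulated staining-batch drifts. Gating
the identical tables with one fixed global threshold per marker instead
(`mode="global"`) leaves intra-run CVs low (median ≈ 8 %) but inflates the
inter-run CV of the T-cell phenotypes to a median ≈ 45 % — the batch
effect leaks straight into the abundance estimates. The same run also
reports MLE per marker (stable within ~1–7 % CV across all 15 sections
under local gating):

```
specimen marker  median_mle  cv_mle
    CT26   CD3e       88.55    1.52
    CT26    CD4       69.12    4.23
    CT26   CD8a       80.35    4.08
    CT26  FoxP3       56.38    6.69
```

The same pipeline is scriptable from a shell:

```bash
mifqc simulate precision --out study/ --seed 7
mifqc gate --study study/ --mode local --out gated/
mifqc precision --study study/ --mode local --out precision.csv
mifqc all precision --out run1/ --seed 7 --mode local
```

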