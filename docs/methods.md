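# Methods

This note documents the statistical model behind `mifqc`: what each
computation assumes, what the synthetic tissue generator does and does not
emulate, the numerical conventions, and the design decisions taken where
more than one convention was defensible.

## Gating model

A cell is positive for a marker when its mean intensity is **strictly
greater** than the threshold; a cell exactly at the threshold is negative.
The strict inequality is a deterministic convention consistent with
stringent thresholding practice (thresholds are chosen to suppress
spurious positives, so the boundary goes to the negative class).

**Global thresholding** applies one fixed value per marker to every
section of every run. **Local thresholding** recomputes one value per
(run, marker) by Otsu's method on the pooled mean intensities of all cells
of all sections in that run — pooling at run scope, not per section,
because the staining batch is the unit whose gain drifts.

### Otsu implementation

`otsu_threshold` histograms the sample into 256 equal-width bins over
`[min, max]` and returns the interior bin edge maximizing the
between-class variance `w0·w1·(μ0−μ1)²`, with class means computed exactly
from the values (not from bin centers) and ties broken toward the lowest
edge. Operating on raw (not log-transformed) intensities with min–max
binning yields an exact scale equivariance: multiplying a sample by `c > 0`
multiplies the threshold by `c` and leaves the induced labels unchanged.
This equivariance is the mechanism behind the package's central
invariance: for a study whose runs differ only by per-run multiplicative
channel gains, local Otsu gating produces bit-for-bit identical positivity
labels to the gain-free study, so every label-derived statistic
(% positive, phenotype counts, MLE, distances) is unaffected by batch
gain drift. Degenerate channels (fewer than two distinct values in a run)
raise an error or fall back to a configured floor threshold with a logged
warning; downstream statistics for that (run, marker) are reported missing.

### Phenotype calling

Phenotypes are boolean marker combinations evaluated in priority order,
most specific first; a cell takes the first matching label, so labels are
mutually exclusive and, with the default definitions

| priority | label | definition |
|---|---|---|
| 1 | T_reg | CD3e⁺ CD4⁺ FoxP3⁺ |
| 2 | T_helper | CD3e⁺ CD4⁺ FoxP3⁻ |
| 3 | T_cyt | CD3e⁺ CD8a⁺ |
| — | other | anything else |

partition the cell set. Raw positive-marker combinations are also counted
per section so that unusual co-positivities (typically touching-cell
segmentation artefacts) surface in reports even when no definition
anticipates them.

## Concordance

The multiplex section of a specimen is paired, marker by marker, with the
1-plex section labeled for that marker alone. The report compares
% positive cells and the mean intensity of positive cells via the
symmetric Bland–Altman relative difference
`100·(a − b) / ((a + b)/2)` (multiplex minus 1-plex). The symmetric
denominator was chosen because neither assay is a gold standard; dividing
by the 1-plex value instead is available behind a switch. `a = b = 0`
returns 0 by convention. Entries with |rel. diff.| > 20 % are annotated,
and markers with fewer than 50 positive cells in either assay are flagged
low-abundance: at such counts serial-section sampling noise alone produces
large relative differences, so excursions there are expected rather than
diagnostic.

## Precision

`cv` is `100·sd/mean` with the sample (n−1) standard deviation — replicate
counts are small — and is undefined (missing, with a warning) for n < 2 or
zero mean. Intra-run CV is computed over the replicate sections of one
run; the pooled intra-run value is the mean of the per-run CVs. Inter-run
CV is the CV over **all** sections of all runs pooled, so it captures both
within- and between-run dispersion; it therefore equals `cv()` of the full
per-section vector by construction. The 25 % CV cutoff and the ±20 %
concordance band are report annotations, not hard failures, and both are
configurable.

## Multiplex labeling efficiency

For marker *m*, `MLE(m) = 100 · (Σ counts of qualifying phenotypes) /
(# m-positive cells)`, where the qualifying phenotypes are the valid
multi-marker combinations containing *m*:

| marker | qualifying phenotypes |
|---|---|
| CD3e | T_cyt, T_helper, T_reg |
| CD4 | T_helper, T_reg |
| CD8a | T_cyt |
| FoxP3 | T_reg |

Counting uses the exclusive priority labels, with T_helper read as
CD3e⁺CD4⁺FoxP3⁻ so that T_reg cells are not double-counted in the CD3e and
CD4 numerators; this keeps `0 ≤ MLE ≤ 100`, and a numerator exceeding its
denominator (possible only with overlapping user-supplied phenotype sets
in the alternative `combinations` counting mode) is rejected by a
validation check. A zero denominator leaves the MLE missing, not zero.

One consequence of exclusive label counting is a weak coupling between
markers: MLE(CD8a) is independent of the CD4 and FoxP3 thresholds only
while those gates stay within the gap between the signal and background
populations. A grossly lowered CD4 threshold makes T_cyt cells spuriously
CD4-positive and relabels them T_helper, changing MLE(CD8a). The
`combinations` mode restores strict per-marker independence at the price
of the ≤ 100 bound.

MLE is computed per section; the report aggregates per-run means and the
per-marker CV across sections, and flags sections deviating from the
specimen median by more than ±10 percentage points (configurable), the
recommended band for flagging a drifted run. A `control_specimen` filter
supports the recommended practice of tracking MLE on a positive-control
sample only; MLE is not meaningful for panels whose markers label disjoint
cell types.

## Spatial distances

Distances are centroid-to-centroid Euclidean, in microns; membrane-to-
membrane distances are not recoverable from per-cell tables. The A→B
distance of a reference cell is the minimum distance to any B cell
(k-d tree accelerated; verified against brute force in tests). A cell
belonging to both phenotype sets is excluded from its own target search —
zero self-distances are segmentation artefacts, not biology. The two
directions are reported separately because they differ systematically
when abundances differ: the direction pointing at the rarer phenotype has
the longer distances.

Cross-section reproducibility is the CV of the per-section mean distance
over all sections of a specimen, pooled across runs (per-run CVs are a
supplementary table). The direction comparison pools per-cell distances
per specimen and applies a two-sided Mann–Whitney rank test — an
assumption, chosen for its robustness on skewed distance distributions.
No edge correction is applied for cells near the field border; with
reference and target cells sharing the same field, the bias largely
cancels in direction comparisons but distances near borders are mildly
overestimated. This is a known limitation.

## Synthetic tissue generator

The generator produces per-cell tables with the statistical structure the
analyses assume, under two study designs:

* **Precision design**: `n_runs × n_replicates` (default 5 × 3) multiplex
  sections per specimen, serial positions shuffled so run *r* receives
  sections `r, r+5, r+10` — no run gets adjacent sections, decoupling run
  effects from sectioning depth. One gain vector per run.
* **Concordance design**: five serial sections, the third multiplex, the
  others 1-plex (one per marker by default), all sharing one staining
  batch. A 1-plex section's other channels contain background draws only.

Model components and defaults:

* **Spatial law** — homogeneous Poisson: cell count ~ Poisson(density ×
  area), positions uniform over the field (default 2 × 2 mm at
  2000 cells/mm²). Real tumors are spatially structured; homogeneous is
  the minimal model sufficient for distance-reproducibility analyses, and
  an optional Thomas-like parent–offspring cluster mode is provided for
  illustrating stronger asymmetries. Consequently, passing distance-CV
  checks here shows estimator stability under sampling noise, not
  robustness to real spatial heterogeneity.
* **Composition** — each cell takes one mutually exclusive ground-truth
  class (T_cyt, T_helper, T_reg, four single-marker classes, "other").
  The high-density model uses T_cyt 4 %, T_helper 3 %, T_reg 1.5 % plus
  1–2 % singletons (≈ 9.5 % CD3e⁺ overall); the medium model halves the
  T-cell classes and the low model is ten-fold sparser. Per-section
  fractions are jittered by LogNormal(0, σ) with a 7 % CV, emulating
  serial-section composition drift at a magnitude that keeps abundant-
  marker concordance within the ±20 % envelope, as observed for adjacent
  sections in practice. Co-positivity beyond the class definitions does
  not occur, so touching-cell artefacts are *not* modelled.
* **Intensities** — strictly positive lognormal populations per marker:
  background median 20 AU (σ = 0.12) and signal median 100 AU (σ = 0.2),
  chosen jointly so that (a) the populations are separable and a within-
  run Otsu threshold lands in the gap between them, recovering
  ground-truth fractions within binomial error, and (b) a fixed threshold
  midway between the two medians (the global-gating analogue of an
  operator's single stringent cutoff) straddles the scaled signal
  population once run gains drop below ~1, reproducing the strong
  run-to-run sensitivity of globally gated abundances.
* **Batch effects** — one multiplicative gain per (run, marker), drawn
  log-uniform from [0.5, 2.0]; gains scale intensities only, after all
  other draws, so ground-truth labels and positions are gain-invariant by
  construction. The magnitude is calibrated to reproduce the qualitative
  finding that global-threshold inter-run CV far exceeds the 25 % cutoff;
  no quantitative batch magnitudes are available to match.
* **Determinism** — one master seed; every section derives its stream
  from a stable `SeedSequence((seed, specimen_index, serial_index))` and
  the gain stream is tagged separately, so identical configs produce
  byte-identical tables and two studies differing only in gains share all
  other draws.

What the generator does **not** emulate: images, autofluorescence
gradients, cell shapes, nuclear overlap/doublets, membrane spillover, and
spatially structured infiltration. Tests passing on synthetic data
therefore validate the statistics and their invariances, not robustness
to those artefacts.

## Benchmark problem sizes

The simulation benchmarks in `mifqc.benchmarks` use one high-density
specimen over 4 mm² (~8000 cells/section, ~120 000 cells per 15-section
study). Because a 5-run study's median CV is itself a noisy statistic —
five gain draws dominate it — each benchmark simulates five replicate
studies under identical conditions (sub-seeded from the master seed) and
reports the median of the per-study statistic; the distance benchmark uses
T_cyt at 80/mm² and T_reg at 30/mm², and the concordance benchmark uses
four CD3e 1-plex sections around the multiplex section (8 % CD3e⁺ cells,
~8800 cells/section) to obtain four serial-section comparisons for one
abundant marker under a single shared staining batch.

## Numerical conventions and degenerate inputs

* Thresholding: strict `>`; value exactly at an interior histogram edge
  belongs to the upper Otsu class (half-open binning), immaterial for
  continuous data.
* Otsu ties: lowest maximizing edge; `argmax` returns the first maximum.
* Empty sections yield `n_total = 0` summaries with missing percentages;
  zero positive cells yield 0 % with missing positive-intensity means.
* CV of fewer than two values, or of a zero-mean vector: missing, with a
  warning. Relative difference of (0, 0): zero by convention.
* Jittered class fractions summing above 1 are renormalized with a
  warning.
* Unknown markers in a loaded table are an error by default (`strict`
  mode): a silent channel mismatch is the most dangerous QC failure.
  Rows with missing coordinates or intensities are rejected with their
  row numbers reported — per-cell means are never legitimately missing in
  segmentation exports, so imputation would mask export corruption.
* Coordinates are continuous microns with arbitrary origin; all distance
  statistics are origin- and rotation-invariant.
* Marker names are case-sensitive exact strings; a small alias map
  canonicalizes dialect variants (e.g. "CD3ε" → "CD3e", "FOXP3" →
  "FoxP3").
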