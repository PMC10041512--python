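# lomo — longitudinal multi-omics stability analysis

`lomo` analyzes repeated-measures (longitudinal) omics data — plasma
proteomics panels, complete blood counts, cell-type frequencies, and
single-cell RNA/ATAC expression collected from the same donors over many
timepoints. It answers the questions such studies pose: how much of each
feature's variance comes from differences *between* donors versus drift
*within* a donor over time versus differences between cell types; which
features are reliably stable (biomarker baselines, bridging controls) or
reliably variable; whether any sample looks like an abnormal event; and
which genes move systematically with time in a single participant.

It is written for computational biologists running longitudinal cohort
studies, and is usable both as a Python library and as a command-line tool
(`lomo <subcommand>`).

## The five analyses

**Variance decomposition (`lomo vda`).** Each feature *y* is fit with a
random-intercept linear mixed model,
`y ~ X beta + (1|F_1) + ... + (1|F_n)`, where the factors of interest
(donor, week, cell type, ...) are crossed random effects. REML variance
components give `sigma_total^2 = sigma_1^2 + ... + sigma_R^2`, and the
fraction `sigma_i^2 / sigma_total^2` — the intra-class correlation (ICC) —
is the share of variance attributable to factor *i*. Missing values are
dropped feature-wise, so incomplete panels are handled without imputation.

**CV profiling (`lomo cvp`).** For bulk data, each feature's coefficient of
variation, `CV = 100 * SD / mean`, is computed per donor across that donor's
timepoints. A feature is *consistently stable* if CV < cvThreshold
(default 5%) in at least donorThreshold donors (default: all), and
*consistently variable* if CV > cvThreshold likewise. The CV histogram is
exported so the threshold can be placed at the mode of the distribution.

**Stability patterns across cell types (`lomo spect`).** Single-cell data
are pseudo-bulked (mean normalized expression per donor x timepoint x cell
type), low-expressed genes (mean over timepoints < 0.1 everywhere) and rare
cell types (average frequency < 0.5%) are filtered, and CVs across
timepoints are computed per (donor, cell type) combination. Counting
stable/variable calls over the combination grid classifies each gene as
super variable (SUV) / super stable (SUS) — at least groupThreshold
combinations, default half the grid — or as VATIC / STATIC: variable or
stable across time in at least one cell type *consistently across donors*.
The top STATIC genes per cell type form a compact marker panel; panels can
be tested against external gene lists with a one-sided hypergeometric test.

**Outlier detection (`lomo oda`).** Each analyte is standardized within
donor: `z = (value - mean) / SD` across the donor's timepoints (the
evaluated point included, so `|z| <= (n-1)/sqrt(n)`). At each timepoint the
number of analytes with `|z| > z0` (default z0 = 2.5) is compared with the
chance expectation `r = 2(1 - Phi(z0))` = 1.24% by an upper-tail binomial
test; Benjamini-Hochberg-adjusted p < 0.05 flags the timepoint as abnormal.

**Time-course analysis (`lomo tca`).** Per donor and cell type, each gene's
expression is modelled with a two-part hurdle model: logistic regression of
the detection indicator on time (plus covariates, including the
standardized cellular detection rate) and Gaussian regression of expression
on time over expressing cells. A likelihood-ratio test drops the time term
from both parts (chi-square, 2 df); genes with BH-adjusted p < 0.05 and
|slope| > 0.1 per time unit are called significantly up- or down-regulated.

Cross-modality support (`lomo xmod`) correlates per-gene pseudo-bulk
profiles between two modalities (e.g., RNA expression vs. ATAC gene scores)
across matched (donor, timepoint, cell type) entries and derives the null
bound R0 — the 95th percentile of correlations between mismatched gene
pairs over 1000 random shuffles — below which an observed correlation is no
better than random. Circos-style polar heatmaps display CVs per gene, cell
type and donor for one or two modalities.

## Worked example

Simulate a 6-donor x 10-week bulk study, spike an abnormal timepoint into
donor D2 at week 4, and run outlier detection:

```python
from lomo import simulate as sim
from lomo.oda import detect_outlier_samples, zscores

ds, _ = sim.simulate_bulk_longitudinal(sim.bulk6x10(seed=300))
ds, _ = sim.inject_outlier_timepoint(ds, donor="D2", timepoint=4.0,
                                     fraction=0.1, shift=6.0, seed=0)
report = detect_outlier_samples(zscores(ds))
print(report[report.flagged][["donor", "timepoint", "n_outlier",
                              "n_evaluated", "p", "p_adj"]])
```

```
   donor  timepoint  n_outlier  n_evaluated             p         p_adj
13    D2        4.0         61         1042  1.312496e-22  7.874978e-21
```

61 of 1042 analytes exceed |z| > 2.5 at the spiked sample against a chance
expectation of 1.24% (about 13), and it is the only flagged
(donor, timepoint) pair of the 60 tested. The same objects drive the CLI:
`lomo simulate --preset bulk6x10 --out sim/` then
`lomo oda --annotation sim/bulk_annotation.tsv --matrix sim/bulk_matrix.tsv
--out oda/`.

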