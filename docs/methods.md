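# Methods

This note documents the statistical models implemented in `lomo`, the
parameters that matter, the numerical choices, what the synthetic-data
generators do and do not emulate, and known limitations.

## Data model

Bulk data are a feature x sample matrix bound 1:1 to a sample annotation
table with a unique sample id, a donor id and a numeric timepoint per row.
Timepoint labels such as `W2` or `D7` are parsed to their numeric suffix;
plain numbers pass through. Replicated samples (same donor and timepoint)
are collapsed to their per-feature median, ignoring missing values; the
operation is idempotent. Features whose NA fraction is *strictly* above
`na_cutoff` (default 0.4) are removed — a feature exactly at the cutoff is
kept, reading "above" literally.

Single-cell data are a cell x gene matrix of normalized expression (dense
or CSR) with per-cell donor, timepoint and cell type. Pseudo-bulking takes
the arithmetic mean of normalized expression over *all* cells of each
(donor, timepoint, cell type) group, zeros from non-expressing cells
included; this matches the downstream mean-expression filter, which keeps a
gene if its mean-over-timepoints pseudo-bulk value reaches `min_avg`
(default 0.1) in at least one (donor, cell type) pair. Groups with no cells
are *masked*, never imputed as zero — downstream CVs must distinguish
absence from zero expression. Cell types whose per-sample frequency,
averaged over (donor, timepoint) samples, is below `min_freq` (default
0.5%) are dropped.

## Variance decomposition

Per feature, the model is a crossed random-intercept linear mixed model

    y = X beta + sum_i u_i + eps,   u_i ~ N(0, sigma_i^2 I_{q_i}),

with one variance component per factor of interest (donor, timepoint, cell
type, ...) and optional fixed covariates X (absorbed before decomposition,
so fractions refer to the variance not explained by fixed effects; the
default is intercept only). The fraction sigma_i^2 / sigma_total^2 with
sigma_total^2 the sum of all components including the residual is the
intra-class correlation attributed to factor i.

Estimation is restricted maximum likelihood on the dense marginal
covariance V = sum_i sigma_i^2 Z_i Z_i' + sigma_R^2 I, with analytic
gradients (tr(P G_i) - y'P G_i P y) and L-BFGS-B under nonnegativity
bounds; the response is pre-scaled by its variance for conditioning
(fractions are unaffected), the optimizer runs to ftol 1e-10 / at most 200
iterations, and the residual floor is 1e-10 in scaled units. This is exact
and fast at the sample sizes the model is meant for (one observation per
sample or pseudo-bulk group; tens to a few thousand rows). On balanced
one-way designs the estimates agree with the closed-form ANOVA
method-of-moments values to better than 1e-6 relative error, and on crossed
designs with statsmodels' MixedLM variance components to its own
convergence tolerance; both comparisons are in the test suite.

Singular fits report a 0 component (informative, not an error). Factors
with a single observed level contribute sigma^2 = 0 with a flag. Features
with fewer than `min_observations` (default 5) non-missing values, constant
features, and non-converged fits are flagged with fractions set to missing.
Observations with missing y are dropped per feature, so incomplete panels
decompose without imputation; with values deleted at random the result
equals a run on the pre-deleted data exactly.

## CV profiling (bulk)

CV = 100 * SD / mean per (feature, donor) across that donor's timepoints,
SD on the n-1 denominator. The CV is undefined when fewer than 2 values
remain or when |mean| <= 1e-8 x the matrix's maximum absolute value —
log-scale proteomics values can straddle zero, where CV is meaningless;
undefined CVs are excluded from counts and medians rather than coerced.
A feature is consistently stable iff CV < cvThreshold in at least
donorThreshold donors, consistently variable iff CV > cvThreshold likewise
(strict inequalities: a CV exactly at the threshold supports neither call).
Defaults: cvThreshold 5%, donorThreshold = number of donors. At permissive
donor thresholds both conditions can hold simultaneously; such features are
reported unclassified rather than given an arbitrary side, keeping the
stable and variable sets disjoint for any thresholds. The per-feature
median CV histogram is exported so users can place the cutoff at the mode
of the distribution.

## Stability patterns across cell types (single cell)

CVs are computed across timepoints per (gene, donor, cell type) from the
pseudo-bulk tensor; combinations with fewer than 2 timepoints are masked.
Each defined entry is called stable (CV < cvThreshold) or variable
(CV > cvThreshold); 10% is the recommended single-cell cutoff (housekeeping
genes sit just above it in some cell types). Counting calls over the
donor x cell-type grid:

* SUV / SUS: count_variable (count_stable) >= groupThreshold, default
  ceil(n_donor x n_celltype / 2). The threshold is exposed because the
  halfway default and a hand-picked integer can differ (e.g., 38 vs 40 on a
  4 x 19 grid); both readings are reproducible via the flag.
* VATIC / STATIC: not SUV (SUS), and variable (stable) in *all* donors with
  a defined entry for at least one cell type, requiring at least 2 defined
  donors so masked combinations never satisfy the universal condition
  vacuously. SUV and SUS are mutually exclusive; VATIC and STATIC can
  co-occur (a gene can be consistently variable in one cell type and
  consistently stable in another).

The STATIC panel takes, per cell type, up to `per_celltype` (default 25)
supporting genes ranked by ascending *maximum* CV across donors in that
cell type — the most conservative stability statistic; the ranking is a
design choice, with ties broken by mean CV then gene id — and deduplicates
the union. Panel-vs-gene-list overlap uses the upper-tail hypergeometric
probability.

## Outlier detection

Within each donor, z = (value - mean) / SD per analyte across the donor's
timepoints, mean and SD (n-1 denominator) *including* the evaluated point.
This leave-in convention bounds |z| by (n-1)/sqrt(n) (2.85 at n = 10, the
bound a one-spike series attains) and makes each (analyte, donor) z-series
exactly zero-mean, unit-SD. Donors need at least 3 timepoints; analytes
with zero within-donor SD get undefined z and are excluded from counting.

At each (donor, timepoint), the count of analytes with |z| > z0 (default
2.5) among those with defined z is tested against the normal-assumption
chance rate r = 2(1 - Phi(z0)) = 1.24% (one-sided: 0.62%) with an
upper-tail binomial test; BH adjustment runs over all (donor, timepoint)
pairs by default (a per-donor family is available), and adjusted p < 0.05
flags the timepoint.

Two consequences of the leave-in bound are worth knowing. First, the
normal-assumption rate overstates the true leave-in tail (at n = 10 the
actual P(|z| > 2.5) is about 0.08%), so the binomial test is conservative.
Second, a single-sample shift of d within-donor SDs lands near
z = d(1 - 1/n) / sqrt((n-2)/(n-1) + d^2/n), which crosses z0 = 2.5 only
around d = 5.5 at n = 10: moderate shifts (~3 SD) are invisible to the
z0 = 2.5 criterion by construction, and the detectable regime starts near
6 SD (the test suite demonstrates reliable recovery there). Real abnormal
events produce exactly this signature — many analytes pinned near the
attainable maximum.

## Time-course analysis

Data are split by donor and cell type and analyzed independently. Genes
detected in fewer than `mincellsexpressed` (default 0.1) of the subset's
cells are removed. Each remaining gene gets a two-part hurdle fit:

* discrete part — logistic regression of the detection indicator on time
  plus covariates, with a ridge penalty of 1e-6 on standardized
  coefficients so quasi-separated fits stay finite without materially
  changing the likelihood ratio;
* continuous part — ordinary least squares of expression on time plus
  covariates over expressing cells (value > 0), with the Gaussian LRT
  statistic n log(RSS0 / RSS1).

The reported slope is the continuous-part time coefficient per original
time unit (the discrete-part coefficient is also exposed). The test drops
the time term from both parts and sums the statistics, p from chi-square
with 2 df (1 when a part is degenerate — constant detection or constant
expression — which is flagged). The design is standardized internally, so
inference is invariant to affine recoding of time while coefficients
transform as expected. The standardized cellular detection rate (per-cell
fraction of genes detected within the subset) is a default covariate;
`adjfac` adds further per-cell covariates. With at least 3 distinct
timepoints, time is continuous; with exactly 2 the same machinery runs a
two-group contrast and the coefficient is the between-timepoint difference.
BH adjustment is per (cell type, donor) family; the default significance
call is adjusted p < 0.05 and |slope| > 0.1.

The hurdle test assumes cells are independent given the covariates. When
expression carries genuine timepoint-level variation shared by all cells of
a sample (biological drift, batch), the effective replication is the number
of timepoints, not cells, and p-values against the cell-level null are
anticonservative — the classic pseudoreplication caveat for single-cell
differential testing. Type-I calibration in the test suite therefore uses
generator settings with no group-level variation; on data with sample-level
noise the test answers "does expression co-vary with time in this donor",
not "would this recur in new donors".

## Cross-modality correlation

Per-gene Pearson correlations are computed over the (donor, timepoint, cell
type) entries present in both tensors (mask intersection; entries outside
it never affect results); genes need at least 3 matched entries and
nonzero variance in both modalities. The null bound R0 pools correlations
between mismatched gene pairs over `n_shuffles` (default 1000) random
permutations of gene order, skipping self-pairs, and takes the upper
quantile (default 0.95). Pooling all shuffle correlations (rather than
averaging per-shuffle quantiles) is the documented choice; the run is
deterministic under a fixed seed. On independent Gaussian tensors R0
matches the analytic 95th percentile of the Pearson null with n-2 df
within Monte-Carlo error (in the test suite). The circos display renders
(gene, cell type) sectors with one ring per (modality, donor) and masked
entries in grey.

## Synthetic generators

`simulate_bulk_longitudinal` draws y[f,d,t] = mu_f + a[f,d] + b[f,t] + eps
with independent Gaussian components (defaults sigma2_donor = 1.0,
sigma2_time = 0.25, sigma2_resid = 0.5 around a baseline of 8, the scale of
log-intensity panels); the truth table stores the implied ICC fractions.
The `bulk6x10` preset mirrors a 6-donor x 10-week plasma study with 1042
features. Empirical components converge to the generating fractions (within
0.02 at 200 donors, tested).

`simulate_single_cell` draws per-(donor, timepoint) group means on the log
scale around a per-(gene, cell type) baseline, with the across-time log-SD
encoding the designed class: `global_stable` 0.02 everywhere,
`global_variable` 0.40 everywhere, `celltype_stable` 0.02 in one designated
cell type and 0.40 elsewhere, `null` 0.15. Cell-level expression is
lognormal around the group mean (log-SD 0.25) times a Bernoulli detection
indicator (p = 0.9), with 150 cells per group by default so the pseudo-bulk
sampling error (~3.5% CV) stays well clear of the 10% call threshold. The
`sc4x6x19` preset mirrors a 4-donor x 6-week x 19-cell-type design. A
sigma of 0 gives genuinely time-independent genes — the correct null for
type-I calibration (see the pseudoreplication caveat above).

What the generators do *not* emulate: count-level noise (library size,
overdispersion), batch effects, donor-specific cell-type composition
shifts, realistic dropout rates tied to expression level, or correlated
genes. Passing tests therefore establish correctness of the algorithms and
calibration under the stated models, not performance on raw scRNA-seq
counts.

Injections: `inject_outlier_timepoint` shifts a seeded random fraction of
features by `shift` empirical within-donor SDs at one sample;
`inject_temporal_trend` adds slope x (t - mean t) to expressing cells of
listed genes, floored at a small positive value so detection status never
changes (clip counts are recorded in the truth table). All generators are
bit-reproducible under a fixed seed.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen as the smallest sizes at
which the targeted property is statistically decidable: ICC recovery at 50
donors x 10 replicates averaged over 12 features; hurdle type-I over pooled
null fits (20 x 100 genes at 40 cells/timepoint in tests; SE ~ 0.005);
slope recovery at 200 cells/timepoint x 3 timepoints; the ODA null
false-flag control over 200 simulated datasets; the shuffle null at 150
genes x 24 matched entries.

## Known limitations

* VDA fits features independently; no shrinkage across features, and
  crossed random *slopes* or covariances between random effects are out of
  scope.
* CV is undefined around zero means; log-scale data that straddle zero
  yield undefined entries rather than absolute-mean CVs.
* The ODA binomial test inherits the normal-assumption rate and is
  conservative at few timepoints; shifts below ~5.5 within-donor SDs are
  structurally undetectable at z0 = 2.5 with 10 timepoints (see above).
* The hurdle model treats cells as exchangeable within a subset; cross-donor
  generalization requires donor-level replication, which is out of scope.
* The two-timepoint fallback reports a contrast coefficient, not a
  per-unit-time slope; the |slope| > 0.1 call threshold then applies to the
  between-timepoint difference.
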