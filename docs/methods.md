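# Methods

This note documents the statistical procedure implemented by `cmskit`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## The composite measure scheme

The workflow assumes one pooled table of animals from several studies and
models, with a treatment-group and a model label per animal and a battery of
numeric welfare-relevant parameters in heterogeneous units. The goal is a
single dimensionless severity score per animal, comparable across models,
plus an ordinal severity level derived from it.

**Filtering.** Parameters measured in only a subset of studies are removed
by a missingness rule: a parameter is dropped iff its missing fraction over
the pooled table is strictly greater than `max_missing_fraction`
(default 0.20), so a parameter missing in exactly 20% of animals survives.
Missingness is assessed on the pooled table, never per model or group,
because the scheme's purpose is cross-model comparability. Manual
exclusions are purely user-declared (via the parameter spec file); the tool
makes no domain judgement about, say, disease-phenotype measures. Animals
are never removed.

**Preprocessing.** The pipeline order is fixed and logged: Box-Cox on the
raw values (with offset `1 − min` applied first when the column minimum is
≤ 0), then z-scaling with the n−1 SD, then imputation. Applying Box-Cox
before scaling is the only well-defined order, since the transform requires
positive values and z-scores are not positive; the intent — normalize, then
standardize — is unchanged. λ is fitted per parameter by profile maximum
likelihood: a 101-point grid scan over [−5, 5] followed by bounded scalar
refinement to 1e-4. Box-Cox can be disabled to reproduce a plain z-score
pipeline.

Remaining missing cells are imputed with the scaled column mean, i.e. 0.
This choice is neutral twice over: an imputed cell contributes nothing to
the composite sum, and it does not shift the covariance structure the PCA
sees beyond shrinking that parameter's variance. Imputed cells are flagged
and counted out of each animal's `n_contributing`; an animal missing more
than half of the selected parameters is scored but flagged unreliable.
Every fitted constant (λ, offset, mean, SD) is written to a manifest so the
identical transform can be replayed on new animals bit-for-bit.

**Stability selection.** Severity-relevant parameters are those that
consistently drive the component separating treatment groups, not merely
those with large variance. Each of `n_runs` (default 100) iterations draws
a random 80% training subsample (without replacement; simple random by
default, stratified by group optionally), eigendecomposes the covariance
matrix of the scaled training data, and ranks parameters by absolute
loading on the chosen component. Loadings per component are sign-fixed so
the largest-magnitude loading is positive, which makes runs comparable
across eigen-solver implementations. The chosen component is, in auto mode,
the one among the first three whose training scores maximize the one-way
between-group F-statistic; a fixed index reproduces a manual choice. The
first component is typically dominated by overall phenotype variance (in
epilepsy batteries, open-field activity correlating with seizure burden)
and is deliberately not forced: the per-run F-statistics are recorded so
the user can audit which component carried group separation, and a run is
flagged when even the best F is below the 5% critical value.

The `top_k` (default 4) parameters per run are tallied; the `n_selected`
most frequent across runs form the selected set, ties broken by higher mean
absolute loading, then input column order — deterministic and auditable.
Correlated parameters from one behavioral domain compete for the same
loading mass, so a correlated but effect-free parameter can displace a
weaker informative one in individual runs; the frequency table makes this
visible rather than hiding it.

**Composite score.** The selected z-scored parameters are summed with unit
weights after directionality alignment: parameters for which a HIGH raw
value indicates higher severity are negated so that on the aligned scale a
lower composite always means putatively higher severity. Equal weights are
the default and the recommended usage; a loading-weighted variant was
considered and rejected as the default because loadings vary across runs
while the unit-weight sum is transparent and stable.

**Severity clustering.** Per run, an 80% training subsample of the
composite scores is clustered by k-means (k = 3 by default); the boundary
between adjacent clusters is summarized by the midpoint of the two scores
flanking it (the maximum of the lower cluster and the minimum of the upper
— its "outer values"), a symmetric and scale-free convention. All animals,
training and held-out, are then assigned levels by that run's thresholds,
so every animal has a membership in every run. Across runs each boundary is
aggregated into a mean and a percentile (2.5th/97.5th, linear
interpolation) 95% interval — distribution-free, and honest about skewed
threshold distributions where mean ± 1.96 SD would not be. Wide intervals
flag variance instability under resampling. Level k (worst) is the cluster
with the lowest centroid; a score exactly on a boundary is assigned to the
less severe side, conservative against over-reporting severity. Per-animal
stability is the fraction of runs agreeing with the animal's modal level.

The 1-D k-means solver is exact: for one-dimensional data every optimal
partition is contiguous in sorted order, so the global within-cluster
sum-of-squares optimum is found by dynamic programming over contiguous
partitions (O(k·n²) with prefix sums). Restart-based Lloyd iteration is
thereby unnecessary; the `n_init` parameter is accepted for interface
compatibility and ignored. This removes the only source of randomness
inside a clustering run — run-to-run variation comes solely from the
subsampling, which is the quantity the confidence intervals are meant to
capture.

**Frozen application.** A fitted CMS is exported as a bundle (selected
parameters, per-parameter λ/offset/mean/SD, directions, thresholds) and
applied to new animals without refitting. Missing values in new animals
contribute 0 after scaling, mirroring the training convention.

## Randomness and reproducibility

One user seed fans out to independent streams keyed by (seed, stage id,
run index), so the subsample of selection run 17 never changes when the
clustering stage adds runs. Identical inputs, config and seed give
byte-identical artifacts; the run manifest records input and artifact
SHA-256 digests and the fully resolved configuration.

## The synthetic-data generator

`cmskit.simulate` draws per-animal latent vectors from a multivariate
normal whose correlation is the Gaussian-copula image of the designed
Spearman targets (r = 2·sin(πρ/6)), applies standardized group/model mean
shifts (Cohen's d) on the latent scale, maps linearly to raw units, and
injects missingness completely at random. The reference design emulates a
pooled three-model epilepsy battery: 204 animals (3 models × naive/sham/
treated, 20/22/26 per cell), 17 raw parameters of which two are mostly
missing (exercising the filter) and two are meant for manual exclusion,
leaving 13; four parameters (burrowing-, open-field-distance-,
social-interaction- and saccharin-preference-like) carry d = −1.5 in the
treated groups of the two post-SE-like models and none in the
kindling-like model; rank-correlation targets are 0.50 between the
burrowing- and social-interaction-like parameters and 0.65/−0.54/−0.53
within the open-field block. Baseline means/SDs are plausible raw-unit
values (g burrowed, cm moved, s interacting, % preference). These are
simulation settings chosen to produce realistic structure, not
reproductions of any measured dataset.

Two smaller canned designs support validation: a 200-animal two-group
battery with 13 uncorrelated parameters and four planted at d = 1.5
(the planted-truth harness for stability selection — uncorrelated so the
planted set is unambiguous ground truth), and a direct composite-scale
draw from three severity strata (means −4/0/+2, SD 0.8, 60 animals each)
for the clustering stage.

What passing these tests shows: the pipeline recovers planted structure of
realistic strength at realistic sample sizes, its solver components are
exact or correctly calibrated, and the whole workflow is deterministic.
What it does not show: performance under informative (non-MCAR)
missingness, non-Gaussian marginals beyond what Box-Cox absorbs, batch
effects between pooled studies, or the behavior of any particular real
battery.

## Numerical choices and degenerate inputs

- SD uses the n−1 denominator throughout; a zero-variance column is a hard
  error naming the parameter.
- Box-Cox requires ≥ 3 non-missing values; z-scaling ≥ 2.
- PCA eigenvalues below numerical zero (rank-deficient input) are clipped
  to 0 and reported, not fatal.
- k-means requires at least k distinct values; exact ties at a cluster
  boundary are resolved by the contiguous-partition optimum.
- Spearman correlations use pairwise-complete observations with
  tie-corrected ranks; pairs with fewer than 3 complete observations are
  left missing with a warning.
- Subsample size is ⌊0.8·n + 0.5⌋ (round-half-up), e.g. 164 of 205.

## Known limitations

- The stratum-recovery ceiling is set by the planted overlap: strata 2.5 SD
  apart admit at most ≈ 92–93% correct assignment by any threshold rule, and
  the resampling CIs capture subsampling noise only, not the sampling noise
  of the single drawn dataset — they are stability diagnostics, not
  coverage-calibrated interval estimates of the population boundary.
- Column-mean imputation understates variance for heavily missing
  parameters; the 20% filter bounds, but does not eliminate, this effect.
- Auto component choice inspects only the first three components; batteries
  whose group separation lives deeper require a fixed index.
- Severity levels are ordinal and relative to the analyzed population; they
  are not absolute welfare categories and do not map onto EU Directive
  2010/63 classes without further processing and considerations.
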