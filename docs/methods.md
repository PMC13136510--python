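# Methods

This note records the statistical procedures the package implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Data model and preprocessing

Genotypes are diploid allele dosages: the count of ALT alleles (0/1/2) per
individual and locus, with an explicit missing mask. The orientation
(ALT vs REF counting) only flips the signs of ordination loadings; every
reported statistic — D², R², adaptive index differences, offset — is
sign-invariant, so the choice is inconsequential and fixed at ALT counts.
Multiallelic VCF records are skipped with a logged count.

**MAF filter.** A locus is removed when min(f, 1−f) < threshold (default 1%),
with f the mean dosage over non-missing entries divided by 2. The boundary is
strict: a locus exactly at the threshold is retained. The filter is
idempotent.

**Genotype imputation (LD-kNN).** For each missing call at locus *l*: the
m = 30 loci with the highest pairwise-complete |Pearson r| to *l* define an
LD panel; the distance between two individuals is the mean squared dosage
difference over panel loci observed in both; the call is the 1/d-weighted
mean dosage of the k = 5 nearest individuals observed at *l*, rounded into
{0,1,2}. Ties in distance break on the lower individual index, making the
result order-deterministic. When fewer than k usable neighbours exist the
rounded locus mean is used (logged). k and m follow the published defaults of
the LD-kNN imputation family and are config-exposed. The pairwise-complete
correlations are computed exactly with indicator-matrix products (a handful
of BLAS calls) rather than per-pair loops.

**Environment imputation.** Site-to-site distances use internally
standardized values over jointly observed variables; continuous cells get an
exp(−d)-weighted mean of the k = 10 nearest donor sites, binary cells a
weighted majority vote.

**Correlation pruning.** While any pair exceeds |r| > 0.7, the member of the
currently worst pair with the larger mean absolute correlation to all
remaining variables is dropped — a deterministic rule; ties favour dropping
the first-listed variable. A keep-list protects variables that must survive
across datasets (e.g. a variable retained in parallel analyses); if both
members of an offending pair are protected the pair is logged and tolerated.
Zero-variance variables are dropped first.

**Standardization.** Continuous variables are centered and scaled by the
sample standard deviation, with the parameters recorded per variable. Binary
(0/1) variables are left unscaled — their scale is already bounded, and
z-scoring a rare binary variable would inflate its leverage; a config switch
exists because reasonable analysts differ here. Future-scenario tables are
standardized **with the current scenario's parameters**, which is what makes
the adaptive index comparable across scenarios: a raw shift of δ becomes a
shift of δ/sd in model units.

## Diversity and differentiation

Per group (waterway by default): Ho is the heterozygote fraction; He is the
small-sample-corrected gene diversity (2n/(2n−1))·2p(1−p) with n genotyped
diploids, averaged over loci; Fis = 1 − mean(Ho)/mean(He), a ratio of
averages. Monomorphic groups report He = 0 and a missing Fis.

Pairwise Fst is a ratio of averages across loci, 1 − mean(Hw)/mean(Hb):
Hw is the average corrected within-group diversity and Hb = p₁q₂ + p₂q₁ the
between-group heterozygosity (the Hudson-family estimator). This variant was
chosen because its expectation under a two-population drift model with
divergence parameter F is F itself, which the Balding–Nichols recovery tests
verify; the Gst-style variant with pooled-frequency total diversity
(expectation F/(2−F) for two populations) is available as
`variant="nei_gst"`. Loci monomorphic in both groups, or with fewer than two
genotyped diploids in either, are excluded from the pair's means. Negative
estimates are reported as computed, not truncated.

## Ordination

`fit_rda` centers Y, residualizes Y and X on [1, Z] when conditioning
covariates are present, solves the least-squares problem with a
pseudoinverse, and takes the SVD of the fitted values. Inertia is on the
variance scale (denominator n − 1); since only inertia ratios are reported,
the denominator convention cancels. Rank-deficient predictor sets are
reduced to a maximal independent column subset by pivoted QR (relative
tolerance 1e−9), and the effective ranks q and c are what enter degrees of
freedom. Axis signs follow one convention: the largest-magnitude element of
each loading column is positive. Variable scores are Pearson correlations of
each residualized predictor with each site-score axis (biplot style).

Adjusted R² is Ezekiel's formula; for partial models the semipartial
difference adj(X|Z) = adjE(R² of X∪Z) − adjE(R² of Z), evaluated from the
fit's own inertia decomposition. A full-model table row is reproduced by
treating conditioning covariates as ordinary predictors.

Permutation significance uses the pseudo-F
(constrained/q)/(residual/(n−q−c−1)) with rows of the Z-residualized
response permuted (reduced-model permutation) and
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm). A numerically perfect fit maps to
F = ∞ so the minimum attainable p is returned rather than an overflow
artifact. The permutation only needs ‖QᵀY‖² for an orthonormal predictor
basis Q, so each permutation is one matrix product.

## Outlier detection

Locus loadings on the first K = 2 constrained axes are scored by squared
Mahalanobis distance against the loci's own location and scatter (classical
moments by default; minimum-covariance-determinant scatter via the `robust`
flag for heavy contamination). The genomic inflation factor
λ = median(D²)/median(χ²_K) rescales distances before the upper-tail χ²_K
transform; p-values are floored at 1e−300. Note λ can sit well below 1 when
strong outliers inflate the scatter estimate — the median-based correction
is exactly what restores null calibration in that case. Thresholds:
Bonferroni p < α/L (GEA default, α = 1%) or Benjamini–Hochberg step-up.

Neutral-locus selection runs the same scan on the loadings of a PCA of the
column-standardized dosage matrix, flags structural outliers at a
deliberately permissive 40% FDR, and refits the PCA on the surviving loci;
the first two score columns become the conditioning covariates for the GEA.
Scanning K and loading standardization are config-exposed defaults (K = 2,
unit-variance loci), not asserted as anyone else's choices. Constant loci
are excluded from the scan and counted as neutral.

The GEA scan is conditioned on the neutral PCs only. Longitude participates
in variance partitioning as the geography category but is not in the default
GEA conditioning set: an environmental gradient aligned with the main
geographic axis would otherwise be regressed out wholesale, removing
precisely the clines the method is meant to find. A `condition_on_longitude`
switch restores the stricter behaviour.

## Variance partitioning

The full model uses every predictor with no conditioning. A category's pure
effect is the constrained inertia of a partial RDA with that category as
predictors and all remaining predictors as covariates. The confounded
fraction is full − Σ pure by the standard partitioning identity, floored at
zero with a warning (it can legitimately be large when predictors are
collinear across categories). Percent-explainable divides by the full
model's variance, percent-total by total inertia. One seed drives all
permutation substreams through spawned seed sequences, so the table is
reproducible as a unit.

The category-size subsampling analysis redraws n = 4 variables (uniform,
without replacement) from each category larger than that, conditioning on
the *other* categories' variables, and reports both raw and adjusted pure
R² per iterate. Raw R² of a subsample can never exceed the full category's
(nested spans); adjusted R² of a noise category is ≈ 0 regardless of size,
so only the raw column carries a guaranteed monotonicity.

## Adaptive landscape and offset

The adaptively enriched RDA refits the same model on outlier loci only. The
adaptive index of a location on axis a is the inner product of its
standardized predictor values with that axis's variable scores; conditioning
covariates are excluded from projection since they have no future values.
Genomic offset is √Σ_a w_a(AI_a^fut − AI_a^cur)², unweighted by default with
eigenvalue-proportion weights available. Because variable scores are
correlations, AI has a per-model scale: offsets are comparable within one
fitted model, not across models. Offset is zero wherever the future equals
the current environment on all model variables, is invariant to axis sign
and predictor order, and scales linearly in a uniform single-variable shift.

## Synthetic data

Sites sit on a one-dimensional coordinate g ∈ [0,1] (an east–west transect)
and are dealt to R = 4 regions by a seed-determined permutation. Regions
model ancestral-lineage membership, which in river systems is shaped by
colonization and stocking history and is therefore *not* collinear with the
climatic gradient; making regions contiguous blocks of the transect instead
would place neutral structure almost perfectly collinear with the causal
gradient, and conditioning on structure would then remove the signal the
method targets. Drift is Balding–Nichols at two levels (F_region = 0.10,
F_site = 0.05 by default). Adaptive loci (20 of 1000 by default) add
β·z(site) to the logit of the site frequency, β = ±1.5 with random sign,
tracking the "temperature" gradient; genotypes are Binomial(2, p_site).
Environment variables: the causal gradient, a partner built to r ≈ 0.9 with
it (to exercise pruning), a weaker independent gradient, a barrier-like step
variable, a spatially clumped binary presence variable, and pure noise.
Genotype and environment cells go missing completely at random (2% and 5%).
The demo scenario is 40 sites × 20 diploids.

What the generator does **not** emulate: linkage along chromosomes (loci are
independent), migration and dendritic river-network topology, non-monotone
genotype–environment relationships, informative missingness, and
genotyping error. Passing tests therefore demonstrate correct behaviour
under hierarchical drift with monotone clines and MCAR missingness — not
robustness to LD pruning artifacts, isolation-by-distance confounding along
the gradient, or non-equilibrium demography.

## Degenerate inputs and tie-breaks

All-missing loci are dropped with a warning; zero-variance predictors error
in standardization and are dropped first in pruning; singular loading
covariances raise with a suggestion to reduce K; frequency draws are clipped
to [1e−4, 1−1e−4] before the logit and selected site frequencies to
[0.001, 0.999] (clips logged). Rounding of imputed dosages uses
floor(x + 0.5). Distance ties in kNN break on index order via stable sorts.

## Problem sizes in the test and acceptance suites

Simulation-backed checks use the demo scenario (800 individuals × 1000 loci)
with 20 replicate seeds for calibration and recovery statistics, 500-locus /
100-diploid populations for Fst recovery, and 15–45-observation random
instances for the brute-force ordination oracle — sizes at which the
quantities under test have comfortably converged while the full suite runs
in minutes on a single core.
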