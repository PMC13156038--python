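# Methods

This note documents the models and procedures implemented in `peptidemaps`,
the parameter choices that matter, what the synthetic data generators do and
do not emulate, and the numerical decisions a maintainer would want written
down.

## Data model

All regional data share a `RegionAtlas`: one row per region with a closed
structure vocabulary (cortex / subcortex / hypothalamus), a free-text
stratum (intrinsic network, anatomical structure or hypothalamic nucleus), a
hemisphere label and a 3-D centroid in millimetres. Tables on disk are
UTF-8, tab-delimited, with `region_id` as the join key; matrices are
re-ordered to atlas order on load. Missing cells are an explicit boolean
mask in memory (empty cells on disk); operations reject masked input unless
they declare otherwise (`aggregate_donors` is the main consumer of masked
data). Inter-region distance is Euclidean between centroids — the geometry
is synthetic, so a surface-geodesic alternative has no referent here.

## Synthetic data generators

All generators are pure functions of (parameters, seed).

**Gaussian random fields.** Regional maps are drawn from a zero-mean GRF
with exponential covariance `C(d) = sill·[(1−nugget)·exp(−d/ρ) + nugget·1{d=0}]`.
The exponential kernel has a single interpretable range parameter ρ (mm);
a jitter of 1e-10·sill is added to the diagonal before Cholesky
factorization. `corr_range = 0` degenerates cleanly to white noise.

**Atlas geometry.** Cortical centroids sit on a spherical shell (55–75 mm),
subcortical centroids in a central ball (≤ 25 mm), the hypothalamus near
the origin — disjoint blocks so cortex–subcortex contrasts are
geometrically meaningful. Strata cycle through 7 cortical networks and 7
subcortical structures; the full fixture has 400 + 54 + 1 = 455 regions.

**Gene pools** draw each column with ρ uniform in a stated interval and
return the per-column truth. **Donor stacks** mix a shared smooth per-gene
signal with donor noise as `√r·s + √(1−r)·ε`, so the expected inter-donor
correlation of each gene equals the reliability `r`.

**Planted latent dimension.** `make_planted_latent` shares one smooth
latent score (ρ = atlas diameter / 4, so spatial nulls are a real
challenge) between two blocks via unit-norm weight vectors, and solves for
the noise multiplier (Brent root-finding on the realized centered
cross-covariance) so that the first singular value carries exactly the
requested share of squared-singular-value mass. Note that this share is a
property of the cross-covariance, not of per-column signal-to-noise: at
share 0.9 the LV1 weights are recovered almost perfectly (cosine ≈ 0.99 at
n = 455) while LV1 score correlations sit near 0.6, which bounds
out-of-sample correlations at a similar level.

**Dominance designs** orthonormalize raw smooth fields (QR) before mixing,
so predictor k's population R² share equals `contributions[k]` exactly;
sample-level shares at n regions converge at the usual √n rate (±5
percentage points needs n ≈ 2,000). The default noise standard deviation is
`√(1 − Σ contributions)`, the value at which the planted decomposition is
exact.

What the generators do **not** emulate: microarray probe-level noise,
background intensity, donor demographics, hemispheric asymmetries, and any
mismatch between mRNA and protein abundance. Passing tests show the
statistical machinery is correct and calibrated under the assumed
covariance structure — not that those assumptions hold in real tissue.

## Preprocessing

**QC filter.** A gene is retained when mean intensity, RNA-seq correlation
and differential stability all clear their thresholds (defaults 0.2 / 0.2 /
0.1). Comparison is inclusive by default: published annotation tables print
metrics rounded to the same precision as the cuts, so a printed 0.20 must
count as passing a "> 0.2" rule.

**Differential stability** is the mean pairwise Pearson correlation of a
gene's regional profile across donor pairs (Spearman available via a flag;
the field-standard construction is Pearson). Zero-variance donor profiles
skip the affected pair with a warning.

**Robust sigmoid.** Per slice (column = gene across regions, or row =
region across genes), `x' = 1/(1 + exp(−(x − median)/(IQR/1.35)))` followed
by min–max rescaling to [0, 1]. The 1.35 divisor makes the IQR-based scale
consistent with the standard deviation under normality. A zero-IQR slice
raises by default; a constant-0.5 policy is available. The transform is
monotone within each slice and invariant to positive affine maps of the
input.

**Probe-level contract.** Background filtering and probe selection operate
on probe × sample tables upstream of everything regional. The background
rule is exposed with both readings (drop when below background in more
than, or in less than, a stated fraction of samples) because the natural-
language statement of such rules is ambiguous; the "more than" reading —
the one that removes unreliable probes — is the default. Probe selection
keeps, per gene, the probe maximally Pearson-correlated with an RNA-seq
reference, falling back to highest mean intensity when no reference exists.

## Variogram-matched surrogate maps

The surrogate generator fixes its parameters at construction:

1. Estimate the target's smoothed variogram: Gaussian-kernel-weighted
   semivariances at 25 equally spaced lags up to the 25th percentile of
   pairwise distances (long-lag pairs are sparse and noisy); kernel
   bandwidth 1.5 × lag spacing.
2. For each candidate smoothing scale (no smoothing, plus 10 exponential-
   kernel scales geometric between 5% and 200% of the max lag), compute the
   *expected* variogram of a smoothed permutation by averaging 24 reference
   permutations, and fit amplitudes (a², b²) for smooth + white-noise
   mixing by nonnegative least squares against the target variogram.
3. Select the scale with the smallest residual — unless the no-smoothing
   candidate is already within one sigma of it, where sigma is the
   fluctuation of a single permutation's variogram around the permutation
   expectation. This parsimony rule makes surrogates of a structureless
   map exactly plain permutations.

Each draw then permutes the target values, smooths at the selected scale,
refits the two amplitudes against the realized component variograms, mixes,
and re-ranks the result onto the original values — so every surrogate is an
exact value-permutation of the target (marginal preserved bit-exactly) with
approximately the target's variogram.

Fitting the scale against expected rather than per-draw realized variograms
is deliberate: per-draw fitting chases permutation-level variogram noise
and imprints spurious smoothness on surrogates of white targets. The
residual trade-off is small (mean relative L2 variogram error ≈ 0.12 at
n = 455 for a smooth target).

Calibration: for independent smooth map pairs, surrogate-based Spearman
p-values are uniform by Kolmogorov–Smirnov test; the rejection rate at 0.05
runs mildly high (~0.10), a known property of autocorrelation-preserving
surrogate tests on strongly smooth fields.

## Moran's I and matched-gene nulls

Moran's I uses row-normalized k-nearest-neighbour weights (k = 10 by
default; inverse-distance weights available). The weight scheme matters for
the matched-gene ranking and is therefore an explicit argument everywhere.

A matched null gene for a target map is chosen per draw by sampling 100
candidate genes from the background pool (excluding the target, its
receptor relatives and any stated exclusions), ranking |Moran's I
difference| ascending and the two-sample KS statistic ascending, and taking
the best mean rank; ties break by smaller |ΔI|, then lexicographic symbol.
Pool Moran's I and KS statistics are precomputed once per target, so draws
are cheap.

Calibration depends on pool size: with only a few hundred background genes
the best-of-100 selection recycles a handful of nulls and the resulting
p-values are anticonservative; at a transcriptome-scale pool (5,000 genes
here; ~15,000 in real data) they are uniform. The calibration suite uses
the 5,000-gene condition.

**Empirical p-values** use the add-one estimator `(k + 1)/(m + 1)`, so p = 0
is impossible and the floor with 10,000 nulls is ≈ 0.0001. Two-sided
extremity is |x − mean(nulls)| by default; doubling the smaller tail is
available behind a flag.

## Dominance analysis

R² for every predictor subset is computed by sweeping a single precomputed
cross-product matrix of the centered data — batched small solves grouped by
subset size — rather than refitting from raw data; 38 targets × 65,535
subsets (p = 16) take a few seconds. Total dominance of predictor k
averages its R² increment over subsets first within each subset size, then
across sizes; the totals sum to the full-model R² (machine precision), and
for p ≤ 5 they equal the all-orderings Shapley average exactly. Exhaustive
enumeration is capped at p = 20 (raise explicitly to go beyond). Adjusted
R² uses the standard (n−1)/(n−p−1) correction.

The receptor-class contrast averages per-target relative contributions
within the ionotropic and metabotropic predictor sets and compares the two
per-target vectors with an unpaired pooled-variance two-tailed t-test
(df = 2k − 2; with k = 38 targets, df = 74). The unpaired form is the
default because the degrees of freedom of the published analysis force it; a
paired variant and Welch variance are behind flags.

## PLSC

Both blocks are column-standardized; the SVD of X'Y/(n−1) gives singular
values, weights (orthonormal), scores (data × weights) and loadings
(Pearson correlation of each original column with its side's score). Signs
follow a deterministic convention: per LV, the largest-magnitude entry of
the concatenated weight vector is made positive. Covariance explained is
the squared-singular-value share.

*Permutation*: Y is rebuilt under either null family — per-column variogram
surrogates, or per-column independently matched null genes — and singular
values are compared rank-for-rank (greater tail, add-one p). Procrustes
alignment of permuted LVs onto the empirical basis is implemented behind
`align=True` but is not the default: aligning nulls to a basis chosen
post hoc to maximize LV1 shrinks the null LV1 distribution and is
anticonservative under a global null (rejection far above nominal in the
calibration suite), while the rank-for-rank comparison is calibrated.

*Bootstrap*: regions resampled with replacement, refit, bootstrap LVs
sign-aligned to the empirical LVs, percentile 95% intervals on loadings
(BCa adds complexity without changing the qualitative picture at these
sample sizes). Degenerate resamples are redrawn and counted.

*Cross-validation*: 70/30 splits (floor on the training size);
standardization parameters and weights are learned on training regions only
and applied to the test block — fitting them on all regions would leak.

## PCA

Column-centered SVD; variance explained percentages over the full rank
(min(n−1, p) components), non-increasing and summing to 100.

## Evolutionary statistics

Percent identity between aligned amino-acid sequences counts matching
columns among those where both sequences are ungapped (pairwise deletion);
a pair with no comparable columns is missing with a warning. The Friedman
test ranks rates within each branch (mid-ranks for ties) across the k
signaling categories; χ² = 12/(nk(k+1))·ΣR²_j − 3n(k+1) on k−1 df, with the
tie-correction divisor behind a flag (off by default, matching the common
implementation when ties are absent). Kendall's W = χ²/(n(k−1)) is the
concordance effect size; it is invariant to any strictly monotone
within-row transform, so testing log rates and raw rates is equivalent.

## Problem sizes

The packaged study conditions are chosen to make every stage meaningful at
desk scale: 455-region atlases for recovery checks and full-scale dominance
(p = 16), a 120 + 30 + 1-region atlas for calibration loops (200 replicates
× 200 nulls), 5,000-gene pools for matched-gene calibration, n = 2,000
regions for dominance share recovery, and 500-member ensembles in the
analysis drivers. The full published scale (10,000 surrogates, 10,000
bootstrap draws) is a parameter change, not a code path change.

## Known limitations

* Euclidean centroid distances ignore cortical folding; on real surface
  data a geodesic distance matrix should be substituted (the API accepts
  any `DistanceMatrix`).
* The surrogate fit is stationary and isotropic; fields with
  direction-dependent or locally varying autocorrelation are matched only
  on average.
* Matched-gene nulls assume the background pool is large and heterogeneous;
  with small pools their p-values are anticonservative (see above).
* The exhaustive dominance sweep is exponential in p; beyond ~20 predictors
  a sampling approximation would be needed.
* Bootstrap LV alignment uses sign-matching only; in data where bootstrap
  draws reorder close singular values, loading CIs for the affected LVs
  widen accordingly.
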