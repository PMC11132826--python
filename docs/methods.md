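# Methods

## Problem setting

Imaging-transcriptomics gene-set analysis asks whether the regional
expression profiles of a prior gene set are associated with a regional brain
phenotype map. The pipeline implemented here correlates one brain map
`x ∈ R^N` (one value per parcel) with every background gene's expression
profile, summarises the within-set correlations with a test statistic, and
compares the empirical statistic against a permutation null distribution.
`braingsa` implements this pipeline together with the machinery needed to
*evaluate* such tests: simulators for spatially autocorrelated maps and for
expression data with controllable structure, several permutation null
families, and the Psig aggregation and bias diagnostics that quantify how
each statistic × null-model combination misbehaves.

## Association

Associations are Pearson correlations of the map with each gene's profile
across the N parcels. Two-sided per-gene p-values use the exact t transform
`t = r·sqrt(N−2)/sqrt(1−r²)`; they are clipped into (0, 1] so that r = ±1
yields the smallest positive float rather than 0. Zero-variance gene
profiles are recorded as r = 0, p = 1 with a logged warning. A
leave-one-region-out variant recomputes the correlation N times with one
parcel removed and averages the estimates; its p-values are derived from the
averaged r at sample size N−1, which is a pragmatic convention (the averaged
estimate is not a single Pearson r) and is flagged in the profile metadata
(`estimator="pearson-loro"`).

Whether the underlying correlations should be Pearson or Spearman is an open
choice in this literature; Pearson is used throughout, consistent with the
t-transform p-values and the toolboxes this analysis models itself on.

## Test statistics

Eight summaries of the member correlations `r_g`, g in set S of size k, over
a background of G genes:

| name | definition | sign-sensitive |
|---|---|---|
| mean | mean of r_g | yes |
| meanabs | mean of \|r_g\| | no |
| meansqr | mean of r_g² | no |
| maxmean | max(mean of positive r_g, \|mean of negative r_g\|) | no |
| median | median of r_g | yes |
| signumber | count of BH-significant member correlations (α = 0.05) | no |
| ks | running-sum enrichment score, unit member weights | yes |
| weighted_ks | running-sum enrichment score, \|r_g\| member weights | yes |

"Sign-sensitive" means the value negates when every correlation is negated.

Maxmean averages each side over its *own* count (empty side contributes 0).
A consequence worth knowing: Maxmean is the larger of the two one-sided
means and therefore always ≥ Meanabs (their count-weighted average); the
Efron–Tibshirani variant that divides both sides by k (and sits below
Meanabs) is available as `total_size` behaviour is *not* exposed — the
per-side form is the default and only form, matching the verbal definition
"the mean value of positive correlations".

Sig Number applies Benjamini–Hochberg correction *within the member
p-values only* (the set is the family), counting corrected p < α. The BH
step-up is implemented as a vectorised recursion and is checked against
statsmodels in the tests.

### Running-sum statistics

Genes are ranked by r descending (ties by gene identifier in the scalar
path, by gene position in the batched paths; with continuous data ties have
probability zero). Walking the ranking, the cumulative sum rises at members
and falls at non-members; the statistic is the signed cumulative sum at the
position of maximum absolute deviation, taking the earliest position on
ties.

Two step conventions exist:

* **normalised (default, `variant="gsea"`)** — member steps
  `w_g / Σ_{S} w_g` (w_g = 1 unweighted, |r_g| weighted), non-member steps
  `−1/(G−k)`. The walk ends at 0 and the score is invariant to the overall
  magnitude of the correlations.
* **literal (`variant="literal"`)** — raw ±w_g steps.

The literal walk ends at the drift `Σ_S w_g − Σ_{S^c} w_g` (= 2k − G
unweighted), which for k ≪ G dominates the extreme deviation. Measured
consequences (which are why the normalised walk is the default): the literal
unweighted statistic is nearly constant at −(G−2k) and shows no positive
co-expression response under competitive nulls (fixture t ≈ −2.6 where the
normalised walk gives t ≈ +13), and the literal weighted walk scales with
the overall |r| level, so spin nulls — whose null correlations are near
zero — declare *every* set significant on maps with strong background
correlations (Psig-B = 1.0), the opposite of the conservative behaviour
rank-based enrichment scores are known for. Exact sign equivariance also
only holds for walks that end at zero; for the literal walk it is restricted
to balanced sets (k = G/2), and even there the sign can tie when +m and −m
are both attained (the deviation magnitude always mirrors).

The batched evaluators never materialise the walk: between member positions
the cumulative sum is strictly monotone, so its extremum is attained at a
member position, just before the next member, or at the end. Evaluating
those 2k+1 candidates per permutation reduces the per-permutation cost from
O(G) to O(k) and is what makes 10⁵-cell grids run in seconds. Batched and
scalar paths are cross-checked on random instances; an exact tie between the
positive and negative extremes can be broken either way by summation-order
noise, which the tests account for.

## Null models and p-values

* **competitive** — resample gene labels: each permutation draws a uniform
  same-sized subset of the background and evaluates the statistics on the
  *fixed* empirical profile. Sig Number reuses the empirical per-gene
  p-values of the resampled labels.
* **self_contained** — spin the map: each permutation recomputes the full
  profile against a spherically rotated map; membership is fixed, so
  within-set co-expression is preserved across iterations. Sig Number
  p-values are recomputed from the spun-map correlations.
* **coexpr_matched** — competitive with an acceptance predicate: a drawn
  set is kept only if its mean pairwise co-expression lies within a
  tolerance of the empirical set's value.
* **brain_specific** — competitive with the pool restricted to the
  brain-specific gene subset.
* **combined** — one spin *and* one label resampling per iteration.

P-values use the add-one convention, `p = (1 + #{null ⋟ emp})/(1 + B)`:
upper-tailed for sign-insensitive statistics and twice the smaller tail for
sign-sensitive ones (overridable via `tail=`). The add-one form guarantees
p > 0 and p = 1 attainable. The tail convention is a design choice — the
two-sided form is the only one consistent with sign-sensitive statistics
detecting associations of either sign while sign-insensitive statistics are
intrinsically one-sided.

Reproducibility and sharing: each gene-resampling permutation b draws from
`default_rng([seed, group, b])`. All resampling families share the same
group code, which yields two useful exact identities — a brain-specific null
whose pool is the whole background, or a matched null with infinite
tolerance, reproduces the competitive draws bit-for-bit. Draws depend only
on (seed, pool, set size), never on the map, so the grid runner caches them
per gene set across maps; spins are likewise drawn once per grid and shared
across gene sets, which the Psig-B aggregation implicitly assumes.

Matched-null sampling cannot rely on uniform proposals alone: a uniform
subset of the background has near-zero expected co-expression, so the
acceptance probability at targets ≳ 0.2 is effectively zero. Each
permutation therefore tries one uniform proposal first (preserving the
tolerance = ∞ identity) and then falls back to guided proposals that grow a
set greedily toward the target mean pairwise correlation, picking each next
member from a random candidate batch. Accepted sets always satisfy the
predicate; the resulting null is "same-sized sets with matching
co-expression", sampled non-uniformly within that class (a property shared
with matched nulls in the toolboxes this follows). Acceptance rates are
reported and a per-permutation attempt budget turns exhaustion into an
error.

## Spatial machinery

Moran's I uses inverse Euclidean centroid distance weights,
`I = (N/W)·Σ_ij w_ij z_i z_j / Σ_i z_i²` with z the centred map and
W = Σ w_ij; its null expectation is −1/(N−1) for any weight matrix, by
exchangeability. Maps with prescribed autocorrelation are *subsampled*: draw
a pool of uniform(−1, 1) maps, compute I for each, keep the n nearest the
target, and verify the selection is centred within one target-sd of the
target with sd ≤ target_sd (default 0.001); too-sparse pools raise an error
reporting how many maps qualified.

Spins are Haar-uniform 3-D rotations (via `scipy.stats.special_ortho_group`,
i.e. the orthonormalised-Gaussian construction) of the centroids followed by
greedy one-to-one nearest-neighbour reassignment, visiting parcels in random
order with index tie-breaks, so every spin is an exact permutation — no
duplicated parcels, value multisets preserved. No hemisphere mirroring is
applied (single-hemisphere analyses).

## Synthetic data

The generator is a latent-factor model: gene profiles are
`loadings @ components + noise`, where the components are smooth spatial
fields (random linear + quadratic forms of the centroid coordinates,
standardised per component) and loadings are Gaussian with sd
`loading_scale`. This gives spatially autocorrelated, mutually correlated
gene profiles: `loading_scale = 0` yields independent genes (the
calibration condition), larger values raise attainable within-set
co-expression. A `bimodal_fraction` of genes instead loads exactly ±scale
(evenly split) on component 0: a map aligned with that component correlates
strongly positively with half of them and strongly negatively with the other
half, producing the bimodal background-correlation histograms whose effect
on spin nulls the evaluation measures. Brain-specific labels are assigned to
the top fraction (default 30%) of a seeded per-gene specificity score —
only the *role* of the label (a restricted resampling pool) matters, so no
attempt is made to model real tissue specificity.

Geometry: parcel centroids are generated on the unit sphere as a paired-site
lattice — evenly spread Fibonacci-lattice sites, each split into a close
tangential pair (half-angle 0.07 rad) — plus a small seeded jitter (0.02).
The pairing is deliberate: real parcellations have strongly non-uniform
centroid spacing (adjacent sub-regions sit much closer than the typical
inter-regional distance), and that heterogeneity gives the
inverse-distance weights a heavy tail. On a perfectly even lattice the
weights are so homogeneous that Moran's I of random maps concentrates in a
narrow band around −1/(N−1) and the subsampling simulator cannot reach
positive targets like I = 0.03 with a tight spread; with the paired-site
lattice the selected-I sd stays below 0.001 for 1000 maps from a 100k pool
across seeds.

What the generator does **not** emulate: real AHBA preprocessing
(probe filtering, donor aggregation, normalisation), realistic gene–gene
correlation spectra (the paper-scale co-expression structure of cortical
transcriptomes is richer than a 3-factor model), anatomically meaningful
component maps, or real atlas geometry. Passing tests therefore demonstrate
the *mechanisms* — co-expression inflating competitive nulls, bimodality
inflating spin nulls, matched nulls absorbing the former — not quantitative
effect sizes on real data; full-scale counts from real cortical expression
matrices are outside what this synthetic harness can or should reproduce.

Co-expression-targeted sets are produced by the same greedy growth used for
matched proposals, with rejection on the final value and a
`SearchFailureError` carrying the best value found when the target is
unattainable.

## Evaluation

Psig-G is, per gene set, the fraction of maps flagged significant; Psig-B
mirrors it per map. Both come from one long-format result table and require
a complete set × map grid (missing cells raise an error listing offenders);
on a complete grid `mean(Psig-G) = mean(Psig-B)` exactly, which is asserted
in the tests as an identity, not approximately. Summary standard errors
follow the convention sd/n_units (not sd/√n) with ddof = 1, matching how
Psig spread is conventionally reported for these designs.

Bimodality of a correlation vector is measured by Hartigan's dip — the
sup-norm distance between the empirical CDF and the nearest unimodal CDF —
implemented here with the classical greatest-convex-minorant /
least-concave-majorant algorithm (no dip implementation exists in the
dependency stack). It is validated against an independent
linear-programming oracle that minimises sup|F_n − G| over piecewise-linear
unimodal CDFs directly (one LP per candidate mode placement, including
atoms at the mode); the two agree to 1e-8 on hundreds of random samples.
The dip of any non-degenerate sample is at least 1/(2n). The supplementary
mode-distance measure uses a Gaussian KDE with Silverman bandwidth on a
512-point grid over the data range and returns the absolute separation
between the highest interior density peaks at positive and negative
abscissae (0 if either side has none); the interior-peak requirement
excludes boundary artifacts.

Bias regressions are plain OLS (no robust errors): Psig-G on within-set
co-expression, Psig-B on the dip of the background correlations, optionally
Psig-G on size + co-expression + their interaction. Constant responses
(e.g. a statistic that never rejects) report t = 0, R² = 0 rather than NaN.

## Scales, defaults, determinism

Paper-style full scale is 500 gene sets × 1000 maps × 5000 permutations;
the default RunConfig keeps n_perm = 5000, α = 0.05, target Moran's I 0.03.
The test suite and the acceptance script run the same machinery at reduced
designs chosen to keep each study under ~a minute while leaving the
qualitative contrasts far from their decision thresholds: calibration at
20 sets × 100 maps × 1000 spins; the co-expression study at 40 sets
(targets 0–0.7, size 50) × 60 maps × 500 permutations; the bimodality study
at 40 sets × (30 aligned + 30 random maps) × 500 permutations. Every random
choice flows from explicit integer seeds; rerunning any entry point with the
same configuration reproduces byte-identical tables.

## Known limitations

* The matched-null proposal distribution is not uniform over matching sets;
  only the matching predicate is guaranteed.
* The leave-one-region-out p-value convention (n−1 df on an averaged r) is
  heuristic; use the correlations, not these p-values, for inference.
* `combined` nulls are evaluated per-iteration and are the slowest family;
  they are intended for small designs.
* Batched ranking ties break by gene position rather than identifier; with
  tied correlations (possible in quantised real data) batched and scalar
  running sums may pick different tie positions.
* The dip of heavily tied samples (many identical values) returns the
  algorithmic value for the sorted multiset; the LP oracle assumes distinct
  values and is only applied to continuous samples.
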