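# Methods

This note documents the models and procedures implemented in `metatrait`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Chemical-space structure (`metatrait.chemspace`)

**Property correlations and clustering.** The metabolite × property table is
summarized by its pairwise Pearson correlation matrix. Properties are
Ward-clustered on a correlation-derived distance; the number of clusters K is
the maximizer of the mean silhouette width over a scanned range, ties broken
toward smaller K.

- *Distance rule.* The default is `1 − r`, under which anticorrelated
  properties are distant. `1 − |r|` is offered (`distance_rule=
  "one_minus_abs_r"`) because strong negative relationships can be the same
  chemical facet with reversed sign; the choice is recorded in the result.
- *Scan range.* K = 2…8 by default. The lower bound is the smallest
  meaningful partition; the upper bound leaves several properties per cluster
  at 21 properties. Both ends are configurable.

**Representative subset.** One property per cluster. The `"default"` choice
names the five canonical representatives (molecular weight, H-bond acceptor
count, aromatic atom count, XlogP, sp³:sp² carbon hybridization ratio) and
errors when any is absent; explicit choices are validated for exactly-one-
per-cluster coverage.

**Varimax-rotated PCA.** PCA is computed on the correlation matrix
(columns standardized with the n−1 variance convention); loadings are
eigenvectors scaled by the square root of their eigenvalue. The retained
axes are rotated by the varimax criterion using the classical iterative
pairwise (Jacobi-style) algorithm with Kaiser row normalization,
convergence when the criterion gain per sweep falls below 1e−6, at most
1000 sweeps. Axis signs are fixed so each axis's largest-|loading| variable
loads positively. Scores follow the convention `standardized data @
loadings` (recorded on the results object); per-axis variance fractions are
recomputed from squared loadings after rotation, so rotation redistributes
but preserves the total retained variance (checked to 1e−8).

**Procrustes rotation test.** Both configurations are column-centered and
scaled to unit total sum of squares; the optimal rotation comes from the SVD
of the cross-product. The statistic is m12 with m12² = 1 − (Σσ)², evaluated
numerically as the residual sum of squares of the optimally aligned
configurations (algebraically identical, but exact — the direct formula
loses ~8 digits to cancellation when shapes coincide). Smaller m12 = closer
association; the permutation p-value counts permutations at least as close
as observed, with the +1 correction so the minimum p is 1/(n_perm+1).

**Equivalence scan.** Every combination of one property per cluster is
compared against the full-table PCA by (i) Pearson |r| between axis scores,
axes matched greedily by maximal |r| (the matching rule is an implementation
choice; nothing in the problem fixes it), and (ii) Procrustes m12 on the
first n_axes scores. A configurable cap (default 5000 combinations) guards
against combinatorial blow-up.

## 2. Trait tables (`metatrait.traits`)

**Presence collapse.** Peak heights of features mapping to the same
consensus metabolite are summed per species; presence is `sum > 0`.
All-zero species rows survive the collapse and are reported (and excluded)
downstream rather than silently dropped.

**Metabolic functional traits.** The trait value is the unweighted
arithmetic mean of a property over the metabolites present in a species.
Unweighted is deliberate: presence/absence is the unit of observation, and
weighting by abundance would mix acquisition intensity into the trait.

**Classical-trait cleaning.** Long-format records are dropped when the
reported error risk is ≥ 4 or the value falls outside documented per-trait
[min, max] limits (limits inclusive); survivors are averaged per species ×
trait, and per-trait drop/keep counts are reported (they partition the
input).

**Two-step gap-filling.** Step 1 repeats a pluggable stochastic imputer
`n_runs` times (default 90). The default imputer is taxonomic shrinkage: a
missing cell receives the genus mean when at least two congeneric
observations exist, else the family mean, else the trait grand mean, plus
Gaussian noise with the trait's pooled within-genus residual standard
deviation — the noise makes the across-run coefficient of variation
informative. Across runs, a cell is set back to missing if any run's value
strictly exceeds `extreme_factor` (default 1.5) × the trait's maximum
observed value, or if the across-run CV strictly exceeds `cv_max`
(default 1); boundary values are kept. Surviving cells receive the
across-run mean. Step 2 fills the re-blanked cells with `n_chain_iters`
(default 5) independent chained-equations imputations — stochastic per-trait
linear regression on all other traits, initialized by sampling observed
values, five Gauss–Seidel sweeps each — averaged across the independent
imputations. Observed cells are never altered and the output is complete or
the call raises. The CV filter uses the across-run CV per cell (the
alternative, a within-run posterior CV, presumes an imputer that returns
uncertainty, which the pluggable interface does not require).

**Genus fallback and transforms.** Species missing from a trait table
receive per-trait genus means over congeners, with per-cell provenance
(`species`/`genus`); traits with skewed distributions (plant height, seed
mass, leaf area in the classical set) are log10-transformed, with strict
positivity enforced and transform flags recorded.

## 3. Trait-space occupancy (`metatrait.hypervolume`)

Species are points in n-dimensional trait space on their analysis scale
(post log10, unstandardized by default; `standardize="zscore"` is exposed
because the literature is split on this and the hull volume is not
scale-invariant).

**Statistics.** Volume is the convex-hull volume (qhull). Lumpiness splits
each dimension into `bins_per_dim` (default 10) equal-width bins over the
point set's own range — maxima fall in the last bin — and reports the
minimum number of cells, taken in decreasing-count order with ties broken by
cell index, whose counts reach ⌈capture_fraction × n⌉ species (default 10%).
The greedy prefix is optimal for this objective: no k cells can cover more
than the k largest counts. Cells are stored sparsely, so 10ⁿ never
materializes. Each simulated cloud is binned on its own ranges by default
(`bin_range="observed"` bins everything on the observed ranges instead; the
choice matters because independence nulls widen marginals).

**Null models.** (i) `uniform_indep`: i.i.d. uniform per trait over the
observed [min, max]; (ii) `normal_indep`: i.i.d. normal per trait with
observed mean and sd; (iii) `permute_indep`: independent permutations of
each observed column (marginals exact, dependence destroyed);
(iv) `mvnormal`: rows i.i.d. multivariate normal with observed mean vector
and covariance. Normal draws are not truncated to the observed range (an
open choice; truncation would shrink null volumes and make the comparison
less conservative). A singular covariance raises with advice rather than
silently regularizing.

**Test.** The permutation p is two-sided around the null mean; the direction
of the effect is reported separately as the sign of the percent change
(100·(observed − mean null)/mean null), since "smaller/lumpier than null" is
a directional statement the two-sided p does not carry by itself. A
degenerate (rank-deficient) null draw counts as volume 0 with a warning
rather than aborting a 999-draw run; a degenerate *observed* configuration
is an error.

## 4. Specialization axes (`metatrait.specialization`)

Metabolic axes are a 2-axis varimax PCA of the five metabolic traits;
combined axes are a 4-axis varimax PCA of the 13 metabolic + classical
traits (both counts configurable). Every retained axis is anchored to every
trait by Pearson correlation (computed on rotated scores). The per-axis
**purity** is the share of the axis's total anchored r² carried by its
dominant trait block; purity 1 means the axis correlates with one block
only, and it is invariant to axis sign flips. Trait clustering reuses the
chemical-space machinery on the trait correlation matrix.

## 5. Synthetic studies (`metatrait.synthetic`)

The generator emulates the statistical structure the analysis assumes, with
ground truth retained for recovery tests. All generators are pure functions
of (parameters, seed).

**Property table.** 21 properties in 5 clusters of sizes (8, 5, 4, 2, 2),
mirroring the five facets of leaf metabolite chemistry (size/complexity,
conjugation/reactivity, polar intermolecular forces, lipophilicity, carbon
saturation); property p in cluster c is `within_loading·F_c + noise_sd·ε`
with independent standard-normal cluster factors F and noise ε. Defaults
`within_loading = 0.9`, `noise_sd = 0.3` give within-cluster r = 0.9 and
near-zero cross-cluster correlation. The first property of each cluster
carries the canonical representative name so the default subset applies.

**Metabolomes.** Metabolite j's chemistry score z_j is its coordinates on
the first `n_axes` (default 2) principal axes of the standardized property
table, each axis re-standardized; species i draws a latent position
u_i ~ N(0, species_sd²·I) and includes metabolite j with probability
logistic(baseline_logit + slope·⟨u_i, z_j⟩). Defaults `species_sd = 1`,
`slope = 1.5`, `baseline_logit = −2` give a mean prevalence near 0.2 — a
species carries a minority share of the global annotated metabolite pool, as
in cross-species untargeted LC-MS presence tables. Species drawn with empty
metabolomes are redrawn so species counts are exact.

**Classical traits.** Species values are genus effect + species effect,
multivariate normal with covariances summing to the target (half genus,
half species by default, so congeners resemble each other); the default
target is 8 traits in two independent blocks of 4 with within-block r = 0.7
(a "size" block and a "leaf economics" block), mean 10, unit variance,
50 genera × 6 species grouped 5 genera per family, 20% of entries missing
completely at random, and no injected outliers unless requested (outliers,
when requested, strictly exceed 1.5× the column maximum so they exercise the
filters).

**What the generator does and does not emulate.** It reproduces correlated
property clusters, low-rank metabolome composition, taxonomic signal, block
trait covariance, and missingness. It does **not** emulate: cross-cluster
property correlations (real chemical descriptors correlate across facets —
see the caveat below), abundance or acquisition noise, annotation error,
structured (non-random) missingness, or phylogenetic signal beyond the
genus/family hierarchy. Passing recovery tests therefore demonstrates that
the pipeline's machinery is correct on data satisfying its assumptions, not
that real leaf metabolomes satisfy them.

**Identifiability caveats discovered with this design.** (1) Because the
cluster factors are independent, the five subset representatives are
mutually uncorrelated, so a subset PCA has no stable axis ordering and
cannot closely Procrustes-match the full-table PCA the way strongly
cross-correlated real descriptors can; on planted data the meaningful
property is that *every* cluster-covering combination behaves alike (tight
spread of m12, every subset significantly closer than random permutations),
and that is what the tests assert. (2) The latent species positions are
isotropic, so the *plane* they span is identified but its in-plane
orientation is only weakly so: the two planted axes express through two of
the five subset traits, while the other three trait means have little
intrinsic variance and, once standardized, couple to randomly oriented
directions of the latent space. Axis-recovery tests therefore check the
leading greedily matched axis and, per planted axis, the correlation with
its best linear combination of the two retained scores.

## 6. Problem sizes and numerical choices

- Default synthetic scale is 3000 metabolites × 300 species × 21 properties:
  large enough for stable correlation structure and hull statistics, small
  enough that the full pipeline runs in seconds and a 999-simulation null
  distribution in under a minute.
- The acceptance script reports hull-based statistics for the five metabolic
  traits and grid-occupancy lumpiness for both trait sets; 8-dimensional
  hulls are supported but qhull's cost grows steeply with dimension, so
  volume nulls for the 8-trait classical set are disproportionate at this
  scale and are left to explicit user invocation.
- Permutation p-values always use the +1 correction; with 999 simulations
  the floor is 0.001.
- Correlation-derived distances are clipped at 0 to absorb floating-point
  negatives; tied silhouettes resolve to the smaller K; lumpiness ties
  resolve by lexicographic cell index — all deterministic.
- Gap-fill CV uses |mean| in the denominator; a zero mean with nonzero
  spread counts as infinitely uncertain (re-blanked).
- Eigendecomposition of the PSD covariance (not Cholesky) generates
  classical traits, so exactly singular block covariances are valid inputs.

## 7. Known limitations

- Chemical descriptors are taken as given; computing them from SMILES is out
  of scope (the `smiles` column travels through I/O untouched).
- The gap-filling imputers are transparent stand-ins with the documented
  filter-and-average wrapper; they are not Bayesian matrix factorization or
  full chained equations with predictive-mean matching.
- Trait-space comparisons are within one dataset; there is no overlap
  statistic between, e.g., tropical and temperate runs — they are separate
  invocations by design.
- Hull volumes in more than ~6 dimensions are computationally demanding and
  increasingly boundary-dominated; lumpiness is the more robust statistic
  there.
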