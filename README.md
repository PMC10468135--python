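# metatrait

Metabolic functional traits and the multidimensional structure of plant
trait space.

`metatrait` is for ecologists and chemoinformaticians who want to treat the
leaf metabolome as a source of species-level **functional traits**. Starting
from (i) a table of chemical properties for annotated metabolites, (ii) a
species × metabolite presence/absence matrix, and (iii) a table of classical
functional traits with a taxonomy, it:

1. **structures chemical space** — pairwise Pearson correlations between
   chemical properties, Ward clustering with the cluster count *K* chosen by
   maximal mean silhouette width, selection of one representative property
   per cluster, and varimax-rotated PCA of the representative subset, with
   Procrustes rotation tests of subset-vs-full equivalence;
2. **builds trait tables** — a species' *metabolic functional trait* for
   property *p* is the unweighted mean of *p* over all metabolites present in
   that species; classical traits are cleaned by error-risk and documented
   limits and gap-filled by a two-step procedure with extreme-value and
   coefficient-of-variation filters;
3. **tests trait-space structure** — the *n*-dimensional convex-hull volume
   and the grid-occupancy *lumpiness* of the species cloud are compared
   against four null models by permutation tests;
4. **characterizes specialization axes** — varimax-rotated PCAs of metabolic
   and metabolic+classical trait sets, with each axis anchored back to
   individual traits by Pearson correlation and a per-axis block-purity
   index quantifying orthogonality between metabolic and classical axes.

A first-class synthetic-data module generates complete studies with known
planted structure (property clusters, latent metabolome axes, taxonomically
structured classical traits with gaps), so the whole pipeline is testable
without any external download.

## The statistics at the core

**Metabolic functional trait.** For species *i* with present-metabolite set
*M<sub>i</sub>* and chemical property *x<sub>p</sub>*,
*t<sub>ip</sub>* = (1/|M<sub>i</sub>|) Σ<sub>j∈M<sub>i</sub></sub> x<sub>pj</sub> —
presence only, never abundance.

**Hypervolume null models.** With the species × trait matrix *T* (*n*
traits), the observed statistic (convex-hull volume, or the minimum number of
equal-width grid cells — 10 bins per dimension — needed to capture 10% of
species) is compared to 999 simulated trait tables under four nulls:
(i) independent uniform marginals over the observed ranges; (ii) independent
normal marginals with observed moments; (iii) independent permutations of
each observed column; (iv) multivariate normal with observed mean vector and
covariance. Significance is a two-sided permutation test around the null
mean, *p* = (#{|v − v̄| ≥ |v<sub>obs</sub> − v̄|} + 1)/(999 + 1), and effect
size is 100·(observed − mean null)/mean null (positive = observed larger).

**Varimax-rotated PCA.** Columns are standardized, the correlation matrix is
eigendecomposed, and the retained axes are rotated by the varimax criterion
(pairwise planar rotations, Kaiser row normalization) — orthogonality and
total retained variance are preserved.

**Procrustes rotation test.** Two score configurations are centered and
scaled to unit total sum of squares; after the optimal orthogonal rotation,
*m*<sub>12</sub>² = 1 − (Σσ)² (σ the singular values of the cross-product),
so *m*<sub>12</sub> = 0 means identical shapes; the permutation *p* uses 999
row permutations.

## Worked example

```python
import metatrait as mt

bundle = mt.gen_study(seed=42)                      # 3000 metabolites x 300 species
clusters = mt.cluster_properties(mt.corr_matrix(bundle.property_table), k_range=(2, 8))
print(f"property clusters: K = {clusters.K}")
subset = mt.select_subset(clusters, "default")
traits = mt.metabolic_traits(bundle.presence, bundle.property_table, subset)
res = mt.null_test(traits, "volume", mt.NullModelSpec("permute_indep", n_sim=999, seed=7))
print(res.summary())
axes = mt.metabolic_axes(traits, n_axes=2)
print(axes.summary())
```

prints

```
property clusters: K = 5
Trait-space volume vs null model 'permute_indep' (999 simulations)
  observed = 0.00310494, null mean = 0.00776057
  percent change = -60.0% (observed smaller than simulated), P = 0.001
Varimax-rotated PCA
  variables: 5, axes retained: 2
  variance fraction per axis: PC1=0.412, PC2=0.303
  total retained: 0.716
```

Reading the output: the silhouette scan recovers the five planted property
clusters; the five-trait species cloud occupies a hull 60% smaller than
expected if traits varied independently (*p* = 0.001, the permutation-test
floor), i.e. metabolic traits are interrelated and only a restricted set of
trait combinations occurs; and two rotated axes carry ~72% of metabolic
trait variance.

The same pipeline is scriptable from the shell:

```sh
metatrait simulate --seed 42 --out study/
metatrait run-all --config config.yaml
```

where the YAML config points at the four input TSVs (properties, presence,
classical traits, taxonomy) and sets the analysis knobs (silhouette K range,
subset choice, gap-fill runs and filters, null-model simulations, lumpiness
bins and capture fraction, retained axis counts). Every run directory gets a
manifest recording the config hash, seed, version, and per-stage status.

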