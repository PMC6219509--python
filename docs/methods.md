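# Methods

## The analysis model

The unit of analysis is the regional species pool of a habitat, not a
vegetation plot: each habitat contributes one list of species, and
species may belong to several habitats. Every statistical question is a
two-group contrast inside one habitat — naturalized vs. native or
invasive vs. native — under the sharp null hypothesis that the alien
group is an exchangeable random subset of the pooled species. All tests
are therefore randomization tests: the label permutation is exact under
exchangeability, which is what makes the type-I calibration checks in the
test suite binding rather than asymptotic.

Casual aliens (species without self-sustaining populations) are removed
globally before any analysis. Tree species are removed from open-habitat
pools, where they occur as juveniles whose measured traits describe
adults; growth form is reduced to the binary tree / non-tree because the
removal rule needs nothing finer.

Traits are analyzed on the log₁₀ scale throughout (all three are strictly
positive and right-skewed over orders of magnitude). Species missing the
tested trait are dropped from that test; species missing any trait are
dropped from the 3-D trait-space analyses — unless an imputed dataset is
analyzed instead.

## ΔCDF: the area between distance CDFs

Within a habitat the three log traits are z-scored over all pool species
(all status groups together — the groups are plotted and compared in a
single common space; standardizing on natives only is a defensible
alternative, and the difference is a per-axis affine factor). The native
centroid is the mean of native rows, distances are Euclidean in SD units,
and are rescaled to percent of the habitat's most distant species.

For a contrast, g(x) = F_alien(x) − F_native(x) is the difference of the
two right-continuous empirical CDFs of relative distance. g is piecewise
constant, so its integral over [0, 100] is computed exactly from the
sorted pooled support; per-value jump weights are aggregated from integer
counts, which makes the statistic exactly antisymmetric under swapping
the groups (an invariant the tests assert with `==`). When the CDFs
cross, [0, 100] is partitioned into maximal sign-constant regions
(zero-level stretches carry no area and merge with their neighbor); the
statistic is the signed area of the region with the largest absolute
area. This generalizes the two-region rule to any number of crossings;
the reported `dominant_fraction` (|ΔCDF| / Σ|region areas|) shows how
much of the total area the chosen region holds. Ties in |region area|
resolve to the earliest region, a measure-zero event on continuous data.

The randomization test re-shuffles the native/alien labels of the pooled
two-group subset (any third status group is excluded), and recomputes the
native centroid, the distances, the 100/max rescaling and the
dominant-region area inside every replicate, so the null distribution
reflects the full estimation pipeline. A fixed-centroid variant exists as
a sensitivity switch. p-values use the add-one convention
(1 + exceedances)/(n_perm + 1) everywhere, two-tailed via |Δ|.

## Phylogenetic signal and correction

Abouheif's proximity between two tips is the product over the internal
nodes on the path between them of 1/(number of direct descendants):
topology-only, so polytomies are handled natively and branch lengths are
irrelevant. C_mean is Moran's I under the row-standardized proximity
matrix; with rows summing to one the usual n/S₀ factor is 1, and on a
star tree the statistic collapses to −1/(n−1) exactly (a closed form the
tests check to 1e−10). Signal tests are one-sided toward positive
autocorrelation — phylogenetic signal is a directional hypothesis. The
multivariate statistic weights each column's Moran form by its inertia
(sum of squares), i.e. trace(XᵀWX)/trace(XᵀX) for column-centered X; its
permutation test reorders whole rows, preserving cross-trait correlation.

Phylogenetic eigenvectors are the positive-eigenvalue eigenvectors of the
double-centered proximity matrix H A H. Selection is greedy: at each step
every unselected eigenvector is tried in the OLS model of the target and
the one minimizing the residual autocorrelation statistic is kept (the
signed statistic, not its absolute value — the procedure targets positive
signal, matching the one-sided tests); the loop stops as soon as the
permutation test on the residuals exceeds α = 0.05, or at
max_k = min(m, n/2) (flagged). A target that starts nonsignificant
selects nothing. Eigenvector models are fit once on the global species
set (per trait for univariate analyses, on the z-scored complete-case
table with the multivariate statistic for the trait-space analyses) and
habitats subset the residuals; residual triples enter the trait space
as-is, with no re-standardization, since their scale is meaningful.
Species absent from the tree are dropped from phylogeny-aware analyses
with a logged warning rather than an error — supertree coverage of a
regional flora is imperfect in practice.

## Imputation

Three strategies, all leaving observed cells bit-identical:

- **taxonomic** — arithmetic mean of observed congeners on the natural
  trait scale; family mean if the genus is empty; global mean as a final
  (flagged) fallback.
- **rf** — missForest-style iteration: initialize gaps at column means,
  revisit trait columns in increasing missingness, refit a
  RandomForestRegressor (100 trees, mtry = ⌊√p⌋, per-column seeded) of
  observed entries on all other columns, re-predict the gaps; stop the
  first time the normalized squared change of the imputed values
  increases and return the previous iterate. Runs on log₁₀ traits (the
  analysis scale) and back-transforms, which also guarantees positivity.
- **rf_phylo** — the same with the first 10 phylogenetic eigenvector
  scores as additional predictors, so clumped gaps can borrow strength
  from phylogenetic position.

Imputation error is scored as log₁₀-scale RMSE on masked cells against
the generator's retained truth. Note the ordering rf ≤ column-mean
baseline is a property of trait-correlated data: with weak cross-trait
correlations a forest has nothing to regress on and matches the baseline,
which is why the error-ordering check runs on a strongly correlated
scenario while rf_phylo ≤ rf (driven by phylogenetic signal, not trait
correlation) holds more broadly.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, at
a desk scale of n = 400 species:

- **Tree**: pure-birth (Yule), rescaled to height 1; genus and family
  labels are the clades crossing the depths at which ~n/6 and ~n/20
  lineages existed, and a rounded 15% of family clades are flagged as
  trees.
- **Traits**: multivariate Brownian motion of the log₁₀ traits along the
  tree, root (1.3, −0.3, 0.0) — i.e. SLA ≈ 20 mm² mg⁻¹, height ≈ 0.5 m,
  seed ≈ 1 mg — with per-unit-height SDs (0.25, 0.5, 0.8) and positive
  correlations (SLA–height 0.3, SLA–seed 0.3, height–seed 0.5), strongest
  between height and seed weight. Tip values therefore carry strong
  phylogenetic signal by construction.
- **Statuses**: 15% naturalized, 8% invasive by random assignment.
  Invasive log traits receive a mean shift of `edge_shift` (default
  (0, +1.5, 0)) in SD units of the **standardized** trait space; because
  the shifted group inflates the pooled SD, the applied log-scale shift is
  s = e·sd/√(1 − f(1−f)e²), the closed-form correction that makes the
  realized standardized displacement equal the configured value.
- **Pools**: six habitats (the first four open), total sizes 100–300 of
  the 400 species — matching the ~24–77% of the full species list that
  the motivating study's habitat pools contained. Alien species are
  widespread by construction: each naturalized species enters a pool with
  probability 0.45 and each invasive with 0.65, yielding per-pool alien
  counts in the study's observed per-habitat ranges; natives fill the
  remainder, and three eligible species of every status are guaranteed
  per pool.
- **Missingness**: per-trait targets (29% SLA, 0% height, 33% seed
  weight). MCAR masks an exact-count uniform random subset (completely at
  random, with the realized fraction pinned to the target); the
  phylo-clumped mechanism removes whole genus clades (shuffled,
  accumulated to the target count, the last clade partially), so the
  missingness indicator itself carries significant C_mean.

What the generator does **not** emulate: vegetation-plot sampling and
species covers, realistic floristic composition, polytomies or supertree
topology artefacts (analysis code handles them; the generator produces
binary trees), trait measurement error, and missingness that depends on
the trait values themselves (MNAR). Passing tests therefore show the
machinery is correct and calibrated under the assumed structure, not that
any ecological conclusion transfers to real floras.

## Numerical and design choices

- Permutation p-values: add-one rule everywhere; n_perm defaults to 999.
- RNG: one root seed; every (dataset, habitat, comparison, analysis)
  tuple gets an independent stream via stable CRC-based hashing, so
  adding a habitat leaves all other numbers unchanged.
- BH families default to the six habitats within one comparison × trait
  set (and comparison set for ΔCDF); `per_comparison` and `global`
  policies are available, since the original family structure is a
  judgment call.
- z-scores use the n−1 SD; sign comparisons in the region partition use a
  1e−12 tolerance; eigenvalues above 1e−10 count as positive.
- Octant tie rule: a coordinate equal to the centroid counts as above
  (deterministic, measure-zero).
- Even-sized group medians use the midpoint convention.
- Degenerate inputs fail loudly: constant trait vectors (Moran undefined),
  fewer than 3 native species per habitat, fewer than 2 species per test
  group, fully missing trait columns, non-PSD Brownian rate matrices.

## Known limitations

- Per-pool power of the ΔCDF test at the default scale (~20 invasive
  species per pool) is ~85–90% for the +1.5 SD height displacement; a
  single unlucky draw of the invasive species set propagates to all six
  habitats of a run, so per-run outcomes are strongly correlated.
- The greedy eigenvector selection is not guaranteed globally optimal and
  can absorb 20–40 eigenvectors on strongly autocorrelated traits; its
  stop rule tests repeatedly, so the residual "p > α" is a stopping
  criterion, not a calibrated p-value.
- The missForest stopping rule compares successive change only; it does
  not estimate out-of-bag error.
- Habitat pools are treated as independent at the BH stage although they
  share species.
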