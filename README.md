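# traitspace

Tools for asking where alien plant species sit in the functional trait
space of the habitats they enter. Given a regional species pool per
habitat, three traits per species — specific leaf area (SLA, mm² mg⁻¹),
maximum height (m) and seed weight (mg) — and each species' invasion
status (native, naturalized non-invasive, or invasive), the package tests
whether naturalized species are trait-wise interchangeable with natives
while invasive species occupy the *edge* of the trait space. It is aimed
at invasion ecologists and comparative biologists working with species ×
trait tables, habitat species lists and a phylogeny.

## What it computes

For each habitat pool and each contrast (naturalized vs. native,
invasive vs. native):

- **Univariate median randomization tests.** Δ = median(alien) −
  median(native) per trait; the null re-shuffles values between the two
  groups with group sizes preserved; two-tailed
  p = (1 + #{|Δ*| ≥ |Δ|}) / (n_perm + 1), Benjamini–Hochberg corrected
  across habitats.
- **Trait-space geometry.** Traits are log₁₀-transformed and z-scored
  within the habitat pool; the native centroid is the mean of native
  species; each species gets an octant (above/below-centroid sign pattern
  on SLA, height, seed weight) and a Euclidean centroid distance in SD
  units, also expressed as % of the most distant species.
- **ΔCDF statistic.** The signed area between the empirical CDFs of
  relative centroid distances, F_alien − F_native, integrated exactly over
  [0, 100]. Where the CDFs cross, the sign-constant region with the
  largest absolute area provides the statistic (the dominant-area fraction
  is reported as a diagnostic). ΔCDF < 0 means the alien group sits
  farther from the native centroid — at the trait-space edge. Significance
  comes from re-shuffling group labels and recomputing centroid, distances
  and area per replicate.
- **Phylogenetic signal and correction.** Abouheif's C_mean — a Moran's I
  with topology-only proximities a(i,j) = ∏ 1/DD(node) over the internal
  nodes on the tip-to-tip path, row-standardized — tested by tip
  randomization. When signal is present, eigenvectors of the
  double-centered proximity matrix are selected greedily until the
  residual autocorrelation is nonsignificant, and all analyses repeat on
  the OLS residuals.
- **Imputation.** Missing traits filled by genus/family means, by an
  iterative random-forest imputer (missForest-style, 100 trees,
  mtry = ⌊√p⌋), or by the same forest with the first 10 phylogenetic
  eigenvectors as extra predictors.

A synthetic-data module generates complete study-like datasets (Yule
tree, correlated Brownian-motion log traits, overlapping habitat pools,
a configurable invasive "edge displacement", and MCAR or clade-clumped
missingness) so the whole pipeline is testable without any downloads.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
dataset (outputs land under `results/`):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_phylogenetic_signal.py
python analysis/03_impute_traits.py
python analysis/04_trait_comparisons.py
python analysis/05_phylogenetic_correction.py
```

Step 04 prints, for the raw dataset:

```
  naturalized_vs_native    mean ΔCDF   -2.58  significant in 0/6 habitats
  invasive_vs_native       mean ΔCDF  -33.07  significant in 6/6 habitats
  invasive Δmedian height_max      1.765  significant 6/6
  invasive Δmedian seed_weight     1.261  significant 2/6
  invasive Δmedian sla             1.158  significant 0/6
```

Read: naturalized species are statistically indistinguishable from
natives (ΔCDF near zero, nothing significant), invasive species sit
significantly toward the trait-space edge in every habitat, and the
univariate driver is maximum height (significantly taller invasives in
all six habitats; SLA never significant). Step 05 shows that the pattern
survives phylogenetic correction, and step 02/03 show the traits carry
strong phylogenetic signal (C_mean ≈ 0.68–0.79, p = 0.001) which the
eigenvector-assisted forest exploits: its imputation error on masked
cells (log₁₀ RMSE 0.25) beats both the trait-only forest (0.44) and
taxonomic means (0.29).

The same machinery is scriptable through the `traitspace` CLI
(`simulate`, `impute`, `signal`, `analyze`, `report`) or the library API
(`traitspace.RunConfig` / `run_full_analysis`).

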