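# lakeso

Quantitative analysis of how a lake's thermal stratification structure,
the vertical spatial overlap of its phytoplankton, and zooplankton
grazing jointly shape phytoplankton taxonomic and functional diversity.
The package is aimed at aquatic community ecologists working with
whole-lake (or mesocosm) experiments where per-event data consist of
temperature profiles, depth-resolved spectral chlorophyll-*a* profiles,
a genus-level biomass matrix with functional traits, and zooplankton
biomass.

## What it computes

**Stratification metrics.** Temperature profiles are converted to
density with the Martin & McCutcheon fresh-water polynomial; the
thermocline is the depth of the maximal density gradient
(layer-midpoint finite differences), and the metalimnion is bounded by
the depths where the gradient crosses 0.1 kg·m⁻³·m⁻¹ on either side of
it (linear interpolation between midpoints).

**Spatial overlap (SO).** Each spectral group's chlorophyll profile
becomes a unit-area Gaussian kernel density over depth *f(z)* (Silverman
bandwidth on concentration-weighted moments, boundary reflection at
surface and bottom). For a pair of groups the overlap is the shared
area ∫ min(f_a, f_b) dz ∈ [0, 1] — the kernel analogue of Schoener's
niche-overlap index — and SO is the mean over all pairs of present
groups.

**Diversity indices.** Taxonomic diversity is Shannon's
H′ = −Σ pᵢ ln pᵢ on biomass shares. Functional dispersion F_Dis is the
biomass-weighted mean distance of genera to the biomass-weighted
centroid in the principal-coordinate embedding of Gower trait
dissimilarities (mixed quantitative/categorical traits; negative
eigenvalues handled as imaginary axes). Per-trait variability uses the
community-weighted variance for cell size (CWvar_MLD = Σ pᵢ(xᵢ − CWM)²)
and the Shannon index over trait-modality biomass totals for the
categorical traits.

**Inference.** A recursive observed-variable path model links the five
event-level variables — thermocline depth and metalimnion width
(exogenous) → log cladoceran biomass, SO, and a diversity index — by
minimising the ML covariance discrepancy
F(θ) = ln|Σ(θ)| − ln|S| + tr(SΣ(θ)⁻¹) − p, reporting χ² = (N−1)F_min
(df = 1 for the default 8-path structure), GFI, standardized paths and
per-equation R², with nonparametric bootstrap standard errors and
p-values. Trait-variability indices are additionally regressed on the
four predictors with permutation-tested multiple regressions.

A synthetic whole-lake generator (three basins with thermoclines near
4, 6 and 8 m, plus a direct five-variable structural simulator with
known coefficients) makes the entire chain testable without field data.

## Worked example

Run the full synthetic pipeline (24 events = 3 basins × 8 dates):

```sh
cat > cfg.yaml <<EOF
n_boot: 2000
n_perm: 9999
EOF
lakeso run --seed 1 -o results -q --config cfg.yaml
```

prints

```
SEM [h_prime]: chisq=0.218 df=1 p=0.641 GFI=0.996 R2: Cladocera_Biom=0.130 SO=0.713 Diversity=0.194
SEM [f_dis]: chisq=0.218 df=1 p=0.641 GFI=0.996 R2: Cladocera_Biom=0.130 SO=0.713 Diversity=0.137
events: 24, excluded: 0
```

The non-significant χ² (p = 0.641 at df = 1) says the one
overidentifying constraint — uncorrelated residuals between cladoceran
biomass and SO — is consistent with the simulated data, and GFI ≈ 1
says the fitted structure reproduces the sample covariance almost
exactly. The R² line gives the variance explained for each endogenous
variable (SO is strongly driven by the thermocline manipulation in this
scenario). `results/` then contains the per-event table
(`event_table.csv`), both path-model summaries and bootstrap path
tables (`sem_*.json`, `sem_*_paths.csv`), the six-row permutation
regression table (`trait_regressions.csv`), the exclusion log and a
run manifest recording the seed and every parameter.

The same stages are available individually (`lakeso simulate`,
`physics`, `overlap`, `diversity`, `sem`, `traitreg`) and as library
functions (`lakeso.fit_ml`, `lakeso.spatial_overlap`, …).

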