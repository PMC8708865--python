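# Methods

This note records the models, the defaults and the open design choices
behind `lakeso`, in the order the pipeline runs them.

## Stratification metrics

Density is computed from temperature with the Martin & McCutcheon
fresh-water polynomial (zero salinity), exact at the density maximum
(ρ(3.9863 °C) = 1000 kg·m⁻³) and standard in limnology toolkits. The
gradient is a finite difference between adjacent sensors, located at
layer midpoints; no smoothing is applied by default (a centred
moving-average window is exposed for noisy thermistor strings).

* **Thermocline** = midpoint of the layer with maximal gradient,
  provided that maximum reaches `min_gradient` (default
  0.05 kg·m⁻³·m⁻¹; below it the column is reported unstratified — this
  guards against spurious thermoclines in near-isothermal spring
  profiles). Ties go to the shallowest maximum (deterministic).
* **Metalimnion bounds**: from the thermocline layer the gradient
  series is scanned outward to the first layer below the threshold
  (default 0.1 kg·m⁻³·m⁻¹) and the crossing is linearly interpolated
  between midpoints; if the gradient never drops below the threshold on
  one side the bound clamps to the profile end. If even the maximal
  gradient is below the threshold the bounds are undefined while the
  thermocline may still exist.

Two resolution facts worth knowing. First, with 0.5 m sensor spacing
the reported thermocline is a layer midpoint, so an inflection lying on
a sensor is recovered within 0.25 m; an inflection between sensors can
be off by up to one spacing. Second, because dρ/dT grows with
temperature, the density-gradient maximum of a wide thermal transition
sits genuinely shallower than the temperature inflection — this is
physics, not error, and it grows with transition width. A profile with
a missing top sensor is simply processed on the available depths.

## Spatial overlap

The kernel density of depth for one spectral group weights each
measurement depth by its concentration; the bandwidth follows
Silverman's rule on the concentration-weighted moments,
h = 0.9·min(σ, IQR/1.34)·n_eff^(−1/5) with
n_eff = (Σc)²/Σc² (an override is exposed). Mass leaking past the
surface or bottom is reflected back, so a uniform profile stays nearly
uniform; reflection can be disabled for comparisons against analytic
densities. Densities are evaluated on a 512-point grid over the water
column and renormalized to unit trapezoidal area, so identical profiles
give overlap exactly 1.

The pairwise overlap is the area under the pointwise minimum of the two
unit-area curves; SO is the arithmetic mean over pairs of *present*
groups. A group whose column-integrated concentration falls below the
detection floor (0.05 µg·L⁻¹·m) is excluded from the mean by default;
the alternative policy (count its pairs as overlap 0) is implemented as
a sensitivity switch because the original field protocol's choice is
not recoverable. SO is undefined (not zero) with fewer than two present
groups.

## Diversity indices

All Shannon-type indices use natural logarithms (nats; the base is an
option). Gower dissimilarity normalises quantitative traits by their
range over the *full* trait matrix — not per event — so distances are
comparable across events; categorical and binary traits contribute
symmetric 0/1 mismatches, and a zero-range quantitative trait is
dropped with a warning. MLD enters Gower and CWvar untransformed by
default (cell sizes are log-distributed, so a log option exists).

F_Dis embeds the Gower matrix by principal coordinates; axes with
negative eigenvalues (the non-Euclidean part of the Gower metric) are
kept as imaginary axes whose squared distances subtract, with the
squared distance to the biomass-weighted centroid clipped at zero
before the square root. This matches the standard mixed-trait
implementation: two genera at unit distance with biomass shares
0.75/0.25 give F_Dis = 0.375, a single present genus gives 0, and a
vanishing-biomass duplicate genus leaves the index unchanged (the
richness-insensitivity property). CWvar uses Σ pᵢ(xᵢ − CWM)² with no
small-sample correction.

The trait set comprises one quantitative trait (MLD) and five
categorical ones (N-fixation, Si-fixation, mixotrophy, coloniality,
pigment type with five levels), giving six per-trait variability
indices: CWvar_MLD plus five modality-Shannon indices.

## Path model

The hypothesis graph has thermocline depth and metalimnion width as
exogenous, and log cladoceran biomass, SO and one diversity index as
endogenous: both exogenous variables point at every endogenous one,
and cladoceran biomass and SO also point at diversity (8 paths). With
a saturated exogenous block (variances/covariance fixed at sample
values), 14 of the 15 covariance moments are free; the single
overidentifying constraint — uncorrelated residuals of cladoceran
biomass and SO — gives df = 1.

Fitting minimises F(θ) = ln|Σ(θ)| − ln|S| + tr(SΣ(θ)⁻¹) − p by BFGS
with an analytic gradient; residual variances are log-parameterised
for positivity. Internally the optimisation runs on the correlation
matrix — the discrepancy is invariant to diagonal rescaling and the
raw variables differ by two orders of magnitude in scale — and the
solution is mapped back to the raw scale, so reported estimates are
unstandardized, with the standardized solution derived afterward from
the model-implied variances. On recursive structures like this one the
ML solution coincides with per-equation least squares of each
endogenous variable on its graph parents; that equivalence is the
primary correctness oracle in the test suite, checked against an
independent OLS implementation. χ² = (N−1)·F_min (the conventional
normal-likelihood multiplier), GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²],
and R²ⱼ = 1 − ψⱼ/Σⱼⱼ with Σⱼⱼ the model-implied variance.

Path p-values come from a nonparametric bootstrap (events resampled
with replacement, default B = 10,000): the reported p is the two-sided
normal approximation from z = estimate/SE_boot, matching the
bootstrap-SE convention of the standard SEM software this mirrors;
percentile intervals are reported alongside. Replicates that fail to
refit (singular resampled covariance at small n) are dropped and
counted, with a warning above 10%. Cladoceran biomass is
log-transformed upstream in the event table, where the transform is
recorded. A lag-1 autocorrelation screen per basin-year flags series
whose |r₁| exceeds the approximate white-noise band 2/√n; note the
estimator is biased low on very short series, so the screen is
indicative, not a test.

## Permutation trait regressions

Each of the six trait-variability indices is regressed on thermocline
depth, metalimnion width, log cladoceran biomass and SO (always all
four, one model per response). Coefficients are ordinary least
squares; p-values permute the raw response vector and count
|t*| ≥ |t_obs| with the add-one correction
p = (exceedances + 1)/(n_perm + 1), two-tailed, default
n_perm = 10,000. An intercept is included by default; a through-origin
mode is available because the originally cited routine supports both
and the field protocol's choice is not documented. Freedman–Lane
residual permutation (per-coefficient reduced-model residuals) is
provided as a sensitivity scheme.

## Synthetic data

The generator has two tiers because the analysis spans two levels.

*Structural tier.* `gen_structural_dataset` draws the five model
variables directly from linear equations with known coefficients.
Defaults: exogenous thermocline depth ~ N(6, 1.5²) m and metalimnion
width ~ N(2, 0.7²) m with correlation 0.35 (the manipulation deepened
thermoclines and widened metalimnia together); path coefficients
(−0.30, 0.10) onto log cladoceran biomass, (0.040, 0.02) onto SO,
(0.02, 0.45, −0.35, 0.90) onto diversity from (depth, width,
cladocerans, SO); residual SDs 0.80, 0.14, 0.75; 66 events. These
values were fixed analytically so the implied R² of the endogenous
variables (≈ 0.225, 0.183, 0.345) and the coefficient signs match the
magnitudes reported for the study system. SO generated at this tier is
a plain linear variable and is not clipped to [0, 1].

*Mechanistic tier.* Temperature profiles are logistic in depth,
T(z) = T_hypo + (T_epi − T_hypo)/(1 + e^{(z−z_t)/s}), sampled at 0.5 m
from 0 to 10.5 m with additive Gaussian noise (default SD 0.1 °C); the
steepness s is calibrated by root-finding so the *detector itself*, run
on the noise-free profile on the same sensor grid, returns the
requested metalimnion width — widths below what the grid can resolve
(~1.4 m at 0.5 m spacing) collapse to a near-step profile. Spectral
profiles are truncated-Gaussian bumps on a 0.1 m grid scaled to a
column-total chlorophyll, with Gaussian noise clipped at zero. Group
peaks sit at fixed offsets from the thermocline, squeezed toward it as
the thermocline approaches the bottom, so deepening the thermocline
compresses vertical niches and raises SO; each peak is additionally
jittered per event (SD 0.5 m) so SO varies within a basin as it would
day to day. The default scenario is three basins stratifying near 4, 6
and 8 m (control, passively and actively deepened), eight dates each.
The community tier draws log-normal genus biomasses over a bundled
12-genus synthetic trait matrix typical of a meso-oligotrophic
temperate lake, with an optional driver that shifts the biomass share
of one trait modality (by default, mixotrophs decline with metalimnion
width); cladoceran log-biomass declines with thermocline depth. All
randomness flows from the scenario seed through spawned child
generators, so stages are independently reproducible.

What the generator does *not* emulate: seasonal succession, hydrodynamic
mixing transients, spatial heterogeneity within a basin, taxon-specific
vertical behaviour, or measurement artefacts of fluorometry (CDOM,
quenching). Passing tests therefore demonstrate correctness of the
*computations* under controlled conditions, not field realism.

## Problem sizes and numerical choices

`scripts/acceptance.py` runs the pipeline at the default 24-event
scenario with B = 2,000 bootstrap draws and 10,000 permutations, and
the calibration studies at 500 replicates (χ² rejection at n = 200;
permutation type-I at n = 66 with 999 permutations) and 200 replicates
for coefficient recovery at n = 5,000 — sizes chosen so the script
completes in about a minute on one CPU while keeping Monte-Carlo error
on the reported rates near half a percentage point. The library
defaults remain B = 10,000 and 10,000 permutations.

Degenerate inputs are handled explicitly rather than silently: all-zero
biomass vectors, absent spectral groups, unstratified columns and
non-positive zooplankton biomass each exclude the event with a logged
reason, and the event table asserts exact row accounting. Collinear
model columns raise naming the offending pair; non-convergence of the
optimizer raises with gradient diagnostics rather than returning a
doubtful fit.

## Known limitations

* The SO index inherits the spectral groups' coarseness: overlap within
  a group is invisible, so SO is an upper-level approximation of true
  taxon overlap.
* GFI is validated structurally (saturated model gives exactly 1,
  near-saturated close to 1); there is no external reference value for
  intermediate cases.
* The bootstrap p-value's normal approximation can be optimistic for
  strongly skewed path estimates at small n; percentile intervals are
  reported for cross-checking.
* The metalimnion detector cannot report widths below ~3 half-spacings
  of the sensor grid, and the thermocline of very gradual transitions
  is physically shallower than the temperature inflection.
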