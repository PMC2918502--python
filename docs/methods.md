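# Methods

This note documents the models implemented in `eggcolor`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Spectral processing

Raw spectra arrive as (wavelength, percent reflectance) pairs at the
instrument's native resolution (~0.4 nm). Processing is:

- **Truncation and gridding.** Curves are restricted to 300–700 nm and
  averaged onto the fixed grid 300, 305, …, 700 (81 points). The value at
  grid point *g* is the mean of the piecewise-linear interpolant over
  [*g* − 2.5, *g* + 2.5] ∩ [300, 700], computed from the exact cumulative
  trapezoid integral (edge windows shrink to the intersection). "Interpolated
  average" admits a second reading — plain interpolation at the grid
  points — which is exposed as `mode="point"`; window means are the default
  because they are the standard downsampling reading and are testable
  against closed forms (exact on constants and linear ramps).
- **Negative values.** Instrument noise can push raw reflectance below
  zero; values are clipped to 0 before averaging so downstream proportions
  are well defined. A reflectance table that round-trips through the writer
  and reader is value-identical (the writer uses 17-significant-digit
  formatting and the reader round-trip float parsing).
- **Relative spectra and the shape statistic.** A relative spectrum divides
  each 5-nm value by the curve's sum (over grid values, not a trapezoid
  integral). The summed absolute difference between two relative spectra is
  a total-variation-style statistic in [0, 2]: 0 iff the shapes match, 2 for
  disjoint support, invariant to positive scaling of either spectrum.
- **Achromatic statistics.** Luminance = Σ of the 41 grid values in
  500–700 nm inclusive (double-cone band; both endpoints included per the
  Σλ₅₀₀–₇₀₀ notation); brightness = Σ of all 81 values. By construction
  luminance + (sum below 500 nm) = brightness exactly.
- **Replicate SNR.** Per-wavelength mean / sample SD (n − 1 denominator,
  appropriate at n = 6) among an egg's replicate spectra; points with zero
  SD are masked undefined rather than propagated as infinities.

Region classification (UV/SWS/MWS/LWS by the location of the global
reflectance maximum, ties to the longest wavelength) uses the default
boundaries UV [300, 400), SWS [400, 475), MWS [475, 575), LWS [575, 700].
No authoritative numeric boundaries exist for the "receptor regions" of an
average avian eye; these are a documented approximation chosen so that the
blue-green region around 500 nm falls in MWS, and they are fully
configurable.

## Tetrachromatic visual model

- **Sensitivities.** Template mode builds each cone's curve from a
  log-normal visual-pigment nomogram parameterised only by λmax (defaults
  370, 445, 508, 565 nm for UVS/SWS/MWS/LWS and 565 nm for the double cone;
  width 0.05 in ln-wavelength). Curves are normalised to unit area on the
  grid (Σ values × 5 nm = 1). Templates are pigment-only — no ocular media
  or oil-droplet filtering; a published sensitivity set including droplet
  filtering can be supplied as a CSV table instead.
- **Illuminant.** Flat (equal-energy) by default: the measurements being
  modelled are museum reflectances with no natural light field, and a flat
  illuminant keeps loci a function of the shell alone. Any positive
  irradiance spectrum can be supplied; loci are *not* invariant to the
  illuminant (tested), only to scaling of the stimulus.
- **Receptor noise.** Noise of cone *i* is eᵢ = w·√(d_LWS/dᵢ) with Weber
  fraction w = 0.05 on the LWS cone and relative densities (1, 2, 2, 4) for
  (UVS, SWS, MWS, LWS) — conventional values in receptor-noise modelling,
  configurable.
- **Coordinates.** With fᵢ = ln qᵢ, squared discriminability between two
  catch vectors is ΔS² = Σ_{i<j} (e_k e_l)² (Δfᵢ − Δfⱼ)² / Σ_{i<j<k}
  (eᵢeⱼe_k)² (k, l the receptors not in the pair). This quadratic form is
  rank 3 with the all-ones vector in its null space (intensity invariance).
  Coordinates are fixed by projecting f onto a Helmert-style orthonormal
  basis of that subspace whose last row is the UV-opponent contrast, then
  applying the Cholesky factor of the induced 3×3 Gram matrix. Consequences:
  equal catches map to the origin; Euclidean distance reproduces ΔS to
  ~1e-13 (tested at 1e-10 on 1000 random pairs); and Z is a pure
  noise-scaled UV-vs-rest contrast. Any coordinate system with the same
  distance structure differs only by a fixed rotation, so axis *identities*
  (beyond the documented Z convention) carry no physical meaning here.
- **JND summary.** The median locus is the coordinate-wise median of
  species-average loci; the clustering fraction counts species with at
  least one individual locus within 1 JND of that median.

## Nested variance components

Hierarchical (Type I) nested ANOVA with five strata. Sums of squares come
from nested group means; expected-mean-square coefficients for the possibly
unbalanced design use the standard group-size formulas
(c_{r,s} = [Σ_{g∈r}(Σ_{h∈s,h⊂g} n_h²)/n_g − same at r−1]/df_r), and the
triangular EMS system is solved from the replicate stratum upward. The raw
(possibly negative) moment estimates are reported alongside estimates
truncated at zero; percentages are formed from the truncated values so
stacked profiles are interpretable. Constant data yield a flagged degenerate
result with zero percentages. On balanced designs the estimates equal the
textbook closed forms exactly (tested against an independent oracle); on
unbalanced designs the EMS coefficients are validated by Monte-Carlo
(mean estimates recover known components on a deliberately ragged design).
No REML or likelihood-based mixed model is involved: the method of the
original analysis is moment-based, and reproducing it is the point.

## Pagel's λ

C is the phylogenetic covariance matrix (entry = shared root-to-tip path
length); C_λ multiplies its off-diagonals by λ. For tip values y the mean is
profiled by GLS and the scale by its ML estimator (divisor n, so LR tests
compare ML log-likelihoods), leaving a 1-D profile likelihood evaluated via
Cholesky factorisation (identical to dense evaluation within 1e-8; the
dense-grid equivalence is tested). The search space is [0, 1]: the analyses
test only against the 0 and 1 endpoints, so the algebraic upper bound of λ
is not explored. Because the profile can be multimodal on small trees, the
optimiser first scans a 41-point coarse grid, then refines the bracketing
interval with a bounded scalar search (tolerance 1e-6); on ≤5-tip trees this
matches a 0.001-step grid scan within 0.01. LR statistics use a χ²(1)
reference; when λ̂ sits at a bound the fit carries an `at_bound` flag as a
caveat — boundary-corrected mixture references are out of scope.

Branch-length hypotheses: `equal` sets every branch to 1; `proportional`
assigns node heights proportional to (descendant tips − 1) and rescales to
unit depth (an ultrametric, Grafen-style construction — the published
description of "proportional" branch lengths is not operational, so this
documented choice is one admissible reading and is swappable); `as-given`
leaves the tree untouched. Polytomies are accepted as hard polytomies.

## Comparative tests

- **Sister pairs.** "Independent pairs" is read as: each species appears in
  at most one pair. The pairing is greedy shallowest-first (genera, then
  tribes, subfamilies, families, then across families) with lexicographic
  tie-breaks for determinism; on small taxonomies it matches an exhaustive
  search maximising the count vector at the shallowest levels. One species
  is left unpaired when the count is odd.
- **Storage effects.** Per species, the oldest and newest clutches (by
  collection year) are compared via clutch-average luminance and the
  absolute summed difference of clutch-average relative spectra. The paired
  t-test is on the luminance deltas; the two regressions are ordinary
  Gaussian-identity linear models of each delta on the natural log of the
  years between collections (the estimate ± SE / t format of the original
  analysis corresponds to this reduction; the log base is configurable by
  transforming the predictor).
- **Randomization.** Medians of `reps` draws without replacement form an
  empirical 2.5–97.5 percentile envelope; the focal sample is flagged
  biased if its median falls outside. Bit-reproducible under a fixed seed.
- **Maculation repeatability.** Species score = mean over eggs and the two
  observers; repeatability is the Pearson correlation of the two observers'
  per-species means.

## Synthetic data generator

The generator is the package's test bed: it must produce data whose ground
truth every stage can recover, while looking like a museum study.

- **Tree.** Families are clades: family stems join at the root and each
  family carries a pure-birth (Yule) subtree, rescaled so tips sit at depth
  1. The family-stem fraction is solved from the configured variance
  fractions: under the λ-transformed Brownian model the expected
  between-family share of species-level variance is λ(t_f + s̄_w), with s̄_w
  the realized mean within-family shared depth, so t_f = (target/λ − s̄)/(1 − s̄).
  This is feasible only when λ_true ≥ the targeted between-family share
  (an iid family effect *is* phylogenetic structure here, so λ = 0 cannot
  carry family variance); infeasible configurations raise.
- **Pigments.** Species reflectance is R(λ) = baseline(λ)·exp(−c_bv·A_bv(λ)
  − c_pp·A_pp(λ)): a logistic baseline rising to ~70% at 700 nm, biliverdin
  absorbance bands at 380/670 nm, protoporphyrin bands at 410 (strong,
  Soret-like) and 540/580 nm. Band positions are stylised defaults, not
  fits to published pigment spectra: they produce the qualitative blue-green
  (MWS-maximal at high biliverdin) vs red-brown (LWS-maximal) axis the tests
  need. One consequence worth knowing: between-species shape differences
  concentrate near the 670-nm biliverdin band in this model, whereas real
  eggshell datasets localise them around 400–500 nm.
- **Trait → concentration.** A single species trait z ~ N(0, C_λ) drives
  both pigments through a logistic squash (slope 0.5, offset −1.5, mapped
  into c_bv ∈ [0, 2.2] increasing and c_pp ∈ [0, 1.5] decreasing), making z
  a blue-brown axis. The offset biases the population toward low-pigment
  (brown/white, LWS-maximal) eggs, matching the composition of real
  collections; the gentle slope keeps the map quasi-linear so λ survives
  the nonlinearity (end-to-end recovery of λ = 0.7 from species-mean
  chromatic Z has mean absolute error ≈ 0.05 at 200 species).
- **Variance budget.** Clutch, egg and replicate effects are mean-one
  lognormal gains on the whole spectrum, with variances nested-corrected so
  each level's expected share of luminance variance equals its configured
  fraction; a small additive white floor (SD 0.5% reflectance at the raw
  step) supplies measurement texture and contributes negligibly (<0.1%) to
  the budget. White noise alone cannot carry a realistic replicate share:
  window-averaging onto the 5-nm grid attenuates it ~12.7×, and the SD
  required to survive that would drive reflectances below zero. Because the
  logistic pigment map compresses between-family differences, species
  spectra are additionally rescaled by a positive per-species factor
  (shape-preserving, so loci and relative spectra are untouched) chosen so
  the one-way family/species decomposition of species luminance matches the
  configured split exactly in realization. Nested-ANOVA recovery of the
  default shares (25, 25, 12.5, 12.5, 25)% is within ~1 point in the mean
  over replicate studies.
- **Maculation and years.** Species maculation scores {0, 1, 2} are drawn
  with probabilities (0.37, 0.33, 0.30) (roughly one-third immaculate, as
  in real collections); a second observer disagrees by ±1 with probability
  0.05, giving repeatability r ≈ 0.99. Replicate-gain variance is scaled by
  maculation class (×0.8/1.0/1.2, mean-one normalised) so immaculate eggs
  yield higher within-egg SNR. Collection years are uniform on 1825–2002
  per clutch; an optional drift coefficient tilts older clutches' spectra
  in proportion to ln(age) (default 0 — the quantitative storage-slope
  recovery test instead simulates old/new clutch pairs directly at the
  studied regime, slope 0.004 per ln-year at n = 108).
- **What passing tests do not show.** The generator emulates design
  structure, not real spectra: quantitative descriptive results (the median
  locus coordinates, the % of LWS-maximal species, the % within 1 JND, the
  wavelength of peak family-level variance) are properties of the synthetic
  world and are expected to differ from any real collection. Recovery tests
  demonstrate that the estimators are unbiased and correctly scaled under
  the stated model, not that the model is a faithful physical account of
  eggshell optics.

## Problem sizes and determinism

Simulation-based tests use the sizes at which the statistical guarantees
are stated: λ recovery on 200-tip trees (100 replicates per λ ∈
{0, 0.5, 1}), variance recovery on the 10 × 5 × 3 × 3 × 6 design (50
replicates), storage-slope recovery at n = 108 (100 replicates), and the
distance identity on 1000 random catch pairs. Every random draw flows from
an explicit seed (numpy `default_rng`); the pipeline is a pure function of
(inputs, config, seed), and regenerating a dataset with the same seed is
byte-identical.

## Known limitations

- The chromatic coordinate frame is a convention; only distances are
  physically meaningful. Published coordinate values from other frames can
  be compared only through distances.
- No chromatic adaptation (von Kries) step and no species-specific eye
  models; the "average UVS eye" is a deliberate neutral choice.
- Moment-based variance components can be negative in small samples; the
  truncation used for percentages introduces a small upward bias at levels
  whose true component is near zero.
- `proportional` branch lengths are one reading of an under-specified
  construction (see above).
- The storage-drift model in the generator is a spectral tilt, chosen for
  simplicity; it reproduces the direction, not the mechanism, of museum
  fading.
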