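# Methods

This note documents the models and estimators implemented in
`spotpatterns`, the numerical conventions they rely on, what the synthetic
data emulate, and the choices made where the underlying procedures are
conventionally under-specified.

## Spot extraction

The extraction chain mirrors classic particle-analysis practice:

1. **Analysis rectangle.** Manually defined torso region, 0-based half-open
   pixel coordinates, y down. Its height defines the giraffe unit:
   1 GU = height in pixels, so a pixel edge is `1/height` GU. This makes
   trait values approximately invariant to image resolution and animal size.
2. **Greyscale.** Luminance `round(0.299R + 0.587G + 0.114B)` on 8-bit RGB.
3. **Contrast stretch.** Linear rescale mapping the `f/2` and `1 − f/2`
   intensity quantiles to 0 and 255, clipping outside. The saturated
   fraction `f` defaults to 0.007 (0.35 % per tail), the long-standing
   default of interactive contrast-enhancement tools; it is exposed in the
   pipeline config. A constant image is passed through with a warning.
4. **Threshold.** Iterated intermeans (isodata): iterate
   `t ← round((mean(levels ≤ t) + mean(levels > t))/2)` from the mid-range
   until fixed. The method is exposed so alternatives can be plugged in.
   Spots are the **darker** phase: foreground = intensity ≤ t.
5. **Labelling.** 8-connected components, numbered in raster-scan order of
   each component's first pixel (verified exactly against an independent
   flood-fill oracle in the tests).
6. **Filters.** Components owning a pixel on the rectangle border are
   removed (incomplete spots would bias shape traits); components smaller
   than 10⁻⁵ GU² are removed as speckles. Filtering is idempotent and fully
   logged per component.

Rescaling an image by an integer factor changes retained GU areas by < 2 %
and leaves the retained-spot count unchanged for smooth spots of radius
≥ 0.03 GU (tested).

## Trait measurement

Per spot: area (pixel count × GU²/px²); perimeter as the chain-code length
of the Moore-traced outer boundary through pixel centres (straight step
1 px, diagonal √2 px; a single pixel counts 4 px). The chain-code estimator
overestimates smooth-curve length by up to ~5 % (a digitised circle of
r = 50 px measures ~4.5 % above 2πr), which is why measured circularities of
circles sit near 0.92 rather than 1.0 — the familiar behaviour of
particle-analysis software. The estimator choice matters for circularity
and solidity and is therefore isolated in one function.

The ellipse fit uses second central moments (including the 1/12 unit-square
pixel term) with axes rescaled so the ellipse area πMm/4 equals the pixel
area. Under this normalisation `roundness × aspect_ratio = 1` holds as an
algebraic identity (asserted to 10⁻⁹). Angles are mathematical (y up),
degrees in [0, 180).

Maximum caliper (Feret diameter) is the largest pairwise distance between
pixel-centre points, computed over convex-hull vertices and verified against
the O(n²) brute force. Pixel centres (rather than corners) are used because
they reproduce the expected degenerate answers — two pixels at (0,0) and
(3,4) give exactly 5, an axis-aligned bar gives angle 0 — while a single
pixel falls back to its corner square (√2 px). Solidity divides pixel area
by the convex-hull area **of pixel corners**, so thin and single-pixel
components have positive hull area; circularity and roundness are capped at
1.0 to absorb coarse-raster overshoot.

Mode shade is the most frequent packed 24-bit value 65536r + 256g + b over
the whole colour rectangle (ties break to the smallest packed value). The
per-animal profile is the arithmetic mean of each per-spot trait plus the
spot count and mode shade; an animal with no retained spots raises an
explicit error and is excluded with a log entry.

## Repeatability

Measurement repeatability is the intraclass correlation from a one-way
ANOVA with individual as the grouping factor:
`R = (MS_A − MS_W) / (MS_A + (k₀ − 1) MS_W)` with k₀ the Sokal–Rohlf
unbalanced group-size coefficient; negative estimates are truncated at 0.
The p-value is the ANOVA F test. The SE comes from a parametric bootstrap
(default 1000 replicates, seeded) drawing new data under the fitted variance
components — the same estimand as a Gaussian mixed-model fit for one-way
designs, but fully specified and dependency-free. Individuals with fewer
than two measurements are dropped with a warning. R is invariant to affine
transforms of the trait (tested to 10⁻⁹).

## Heritability

Narrow-sense heritability is estimated by single-parent–offspring
regression: OLS of the calf trait on the mother trait, `h² = 2 × slope`
(a single parent shares half the additive genetic variance), with
`SE(h²) = 2 × SE(slope)`. Traits are used unstandardised. The method cannot
separate additive genetic variance from maternal or shared-environment
effects; it is the appropriate tool when sires and sibships are unknown.
Multiple testing across the eleven traits uses Bonferroni α/m
(0.05/11 ≈ 0.0045, reported rounded to four decimals alongside full
precision); the two PCA-dimension tests are not included in the family.
Assumption checks: Shapiro–Wilk on residuals and the Breusch–Pagan score
test (χ²₁) of squared residuals against fitted values; both are skipped
with a warning for n < 5 or degenerate (all-zero-residual) fits. Pairs with
a missing value on either side are dropped listwise per trait.

## Phenotype clustering

The ten measured traits (mode shade excluded) are z-scored column-wise
(n − 1 denominator). PCA is the eigendecomposition of the resulting
correlation matrix; dimensions are ordered by eigenvalue, each loading
vector is flipped so its largest-magnitude entry is positive (sign is
otherwise arbitrary), and a trait's contribution to a dimension is
100 × loading². Scores reproduce the data exactly at full rank.

k-means uses k-means++ initialisation with 50 restarts (seed default
20120101) and Lloyd iteration. The number of phenotypes is chosen by the
gap statistic with reference data drawn uniformly over each feature's
observed range — the simplest published variant and deterministic given the
seed — using `gap(k) ≥ gap(k+1) − s_{k+1}` (first-SE-max) with
`s_k = sd_b(log W*) √(1 + 1/B)`. Because real coat data can support several
optima, the full gap curve is always emitted and the pipeline config can
force a specific k. Overlapping groups can be lumped afterwards; merged
centres are size-weighted means and the merged within-SS follows from the
parallel-axis decomposition, so lumping never decreases within-SS.

## Robust-design survival

The likelihood conditions on first capture and propagates each individual
through the hidden states {alive-inside, alive-outside, dead} across
primary occasions (4-month seasons, three per year, two back-to-back survey
events per occasion treated as closed). Between occasions the animal
survives with age-dependent apparent survival S (age A = integer seasons
since first capture; neonates enter at age 0), then transitions
inside→outside with γ″ or stays outside with γ′ (both kept free, with an
optional γ′ = γ″ constraint). Within an occasion an inside animal is
detected per event with p(t) before its first within-occasion capture and
c(t) after; outside and dead animals are never detected. Permanent
emigration is absorbed into apparent survival — no extra state. All
probabilities are logit-linked. The forward pass is exact: summing the
likelihood over every possible post-release history equals 1 to 10⁻¹⁰, and
with γ′ = γ″ = 0 and one event per occasion it reduces to the closed-form
CJS likelihood (both tested).

Group effects on S are additive (separate intercepts, common age slope) or
multiplicative (separate slopes). Individual covariates enter the S linear
predictor linearly or with a quadratic term (quadratic models retain the
linear term — standard polynomial nesting) and act only on intervals whose
starting age falls in a chosen window: first season {0}, first year
{0–2}, or first three years {0–8}. Covariates are z-scored before fitting
(optimiser conditioning; a flag disables it), and betas are reported on the
scale used.

Fitting is quasi-Newton (L-BFGS-B, numeric gradients, ftol 10⁻¹²) from zero
betas plus seeded jittered restarts; SEs come from the inverse of a
numerically differenced Hessian. Detection parameters that no history
informs (e.g. p at the first occasion when every animal is released there)
stay at their initial value with a singular-Hessian warning and a
pseudo-inverse; they are shared across a model set so ΔAICc comparisons are
unaffected. AICc uses effective sample size = number of individual
histories (config-exposed; orderings at these scales are insensitive to
the choice). Akaike weights, likelihood-ratio tests for nested specs, and
Burnham–Anderson model averaging (unconditional variance
Σ wᵢ(varᵢ + (θ̂ᵢ − θ̄)²)) complete the inference toolkit; a beta is flagged
significant when its 95 % CI excludes zero. An optional ĉ variance-inflation
multiplier exists but is off by default. Encounter histories round-trip
through a MARK-style `.inp` dialect (history, frequency, optional numeric
covariates, `;` terminator, `/* */` comments), and model structures can be
written as compact formula strings, e.g.
`"S(A+group) gpp(A) gp(A) p(t) c(t)"` or
`"S(A+aspect_ratio^2@first_year) gpp(A) gp(A) p(t) c(t)"`
(`SurvivalModelSpec.from_string`).

## Synthetic data: what it does and does not emulate

The coat renderer draws dark ellipse polygons (boundaries radially
perturbed by smoothed periodic noise with amplitude roughness × semi-minor
axis — perturbation directly lowers solidity and circularity the way
incised spot edges do) on a lighter ground, with a linear illumination
ramp and Gaussian pixel noise. Defaults target the observed coat statistics
of wild giraffes: ~19 spots per rectangle, mean spot area ≈ 0.04 GU², mean
aspect ratio ≈ 1.7, dark-on-light polarity. Spots are placed sequentially
with mutual repulsion (emulating the light reticulation between spots);
spots that still overlap merge into one raster component and are flagged,
as are spots crossing the rectangle edge, so recovery tests can skip them.
Ground-truth area/perimeter are exact ellipse formulas when smooth
(4aE(e²) for the perimeter) and shoelace/polyline integrals of the rendered
polygon when roughened. Not emulated: pelage texture, perspective,
vignetting, occlusion, or observer variation in rectangle placement —
passing tests therefore demonstrate correctness of the measurement chain,
not robustness to field-photography artefacts.

The demographic generator releases neonate cohorts at every occasion but
the last, forces the first capture at the cohort occasion's first event
(histories are conditioned on first detection), and simulates the same
state process the likelihood integrates over. Cohort sizes are a free
parameter. Observer effort heterogeneity and permanent emigration as a
distinct process are deliberately not simulated.

Mother–calf pairs draw mothers from N(μ, σ²) and set
calf = μ + slope·(mother − μ) + e with var(e) = σ²(1 − slope²), so the calf
variance equals the mother variance and the expected OLS slope is exactly
the design slope. Repeated measurements use the one-way decomposition
(individual variance R σ², residual (1 − R) σ²). Trait clusters are unit
spherical Gaussians with centres placed a stated number of SDs apart.

## Problem sizes and tolerances in the test suite

Simulation-based checks run at sizes chosen to make the suite complete in
minutes on one CPU while keeping the assertions at their stated strength:
survival-recovery and group-gap checks use ~2000 histories on the 13-
occasion × 2-event design (first-season Ŝ within 0.03; a 0.04–0.07
first-season survival gap detected by AICc in ≥80 % of seeds over 5 seeds);
covariate recovery uses ~3000 histories (β̂ within 0.15, CI excludes zero in
≥80 % of seeds); LRT null calibration uses 100 seeds of 150 histories on a
6-occasion design (KS uniformity at α = 0.01); gap-statistic recovery uses
10 seeds per true k ∈ {1, 3, 4} (≥90 % correct); repeatability coverage
uses 20 seeds of 30 × 3 designs (≥90 % CI coverage). Exact identities
(likelihood normalisation, CJS reduction, Feret-vs-brute-force, labelling
oracle, roundness × aspect ratio) are asserted to between 10⁻⁸ and 10⁻¹².

## Known limitations

* The chain-code perimeter biases circularity low for smooth spots; use the
  documented estimator consistently when comparing across studies.
* Mode shade is sensitive to lighting; it is computed but deliberately kept
  out of the clustered trait set.
* PO regression conflates additive genetic, maternal and shared-environment
  variance; h² > 1 point estimates (as both published shape traits imply)
  signal those confounds and/or sampling error, not biology.
* The robust-design implementation covers the model family used here
  (age-linear S and γ, time-dependent p/c, group and covariate effects on
  S); it is not a general MARK replacement (no multi-state, dead-recovery,
  or goodness-of-fit machinery).
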