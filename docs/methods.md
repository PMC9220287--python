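# Methods

This note documents the models, numerical choices and known limitations of
the package, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and distances

The analysis operates on a binary species × region incidence matrix (each
species carrying a suborder label) and a region table with centroid
coordinates, area (km²), and five climate variables: total annual
precipitation `pmean` (mm), mean annual temperature `tmean`, mean minimum
`tmin` and maximum `tmax` (°C), and the yearly range `delta_t = tmax −
tmin`, which is recomputed on load so the identity holds exactly.

Geographic distances are great-circle (haversine) distances between region
centroids on a sphere of radius 6371.0088 km (the IUGG mean radius; the
choice matters only in the fourth significant digit). Climatic distances
are Euclidean distances on variables z-scored across regions with the
sample (n−1) standard deviation; they are therefore invariant to affine
rescaling of any input variable, and a variable constant across regions is
rejected rather than silently dropped. `delta_t` is excluded whenever
`tmin` and `tmax` are both in the variable set (it is their exact
difference and would make the standardised design singular); the same rule
applies to the regression candidate pool. All distance matrices carry
region labels and every pairwise test re-aligns by label, so file order
never silently matters.

An alternative geographic matrix (e.g. minimum distances between region
borders) can be supplied as a pre-computed labelled CSV; the package never
derives distances from polygons.

## β-diversity partition

Pairwise dissimilarities use the a/b/c decomposition of two faunas (shared
/ exclusive counts): βsor = (b+c)/(2a+b+c), βsim = min(b,c)/(a+min(b,c)),
βnest = βsor − βsim. The additive identity is asserted to 1e−12 on every
constructed triplet. Degenerate pairs: two empty faunas score 0 on all
three; exactly one empty fauna scores βsor = 1, βsim = 0, βnest = 1, which
preserves the identity and flags pure richness loss. Note that βnest is
*not* monotone under adding a species shared by both regions (a counter-
example: (a,b,c) = (1,2,3) → (2,2,3) raises it); only βsor and βsim are,
and the tests assert exactly that.

## Permutation inference

Moran's I uses the conventional distance-based formulation with inverse
great-circle-distance weights, zero diagonal, no row standardisation, and
the permutation-moment (randomization) normal approximation with the
classical variance formula; the expectation is −1/(n−1) exactly. The
default alternative is two-sided.

Mantel tests correlate upper-triangle vectors and permute objects of one
matrix jointly over rows and columns; the partial Mantel test permutes the
*biogeographical* matrix (A) and recomputes the full first-order partial
correlation r_AB·C each draw. p-values use the add-one estimator
(1 + exceedances)/(1 + permutations), so the smallest attainable p is
1/(permutations + 1); the default is 999 permutations, tail "greater",
seeded. Controlling a matrix for itself (B identical to C) returns r = 0
with p = 1; any other perfectly correlated control is rejected as
degenerate.

A caveat the user should know: partial Mantel tests are exactly calibrated
when the tested matrix is exchangeable under the null (the suite verifies
the 5% level inside the 95% binomial band over thousands of simulated
nulls), but they are *liberal* when the two compared matrices share a
nonlinear dependence on the control — linear partial correlation cannot
fully remove a monotone-but-curved common response, a well-documented
limitation of the method. The random-split test inherits this: under a
fauna driven by Gaussian climate niches, splitting the pool and controlling
the linear climate distance still leaves shared curvature, and the test
fires far above the nominal rate even without any historical structure.
Its p-values should therefore be read as evidence against the *full* null
(no structure beyond chance), not as a sharp test of "history given
climate".

Dutilleul's modified t-test estimates the autocovariance of each variable
per great-circle distance class (equal-width bins, Sturges' rule on the
pair count by default), builds the two covariance matrices from the class
means of centred cross-products, and computes the effective sample size
M̂ = 1 + tr(BΣ̂xB)·tr(BΣ̂yB)/tr(BΣ̂xBΣ̂y) with B the centring matrix; the
corrected p comes from F = (M̂−2)r²/(1−r²) on F(1, M̂−2). M̂ is clamped to
[2, n]: the trace estimator can exceed n under sampling noise, and the
corrected test must never be more liberal than the classical one. With
fewer than two non-empty distance classes the classical test is returned
and flagged uncorrected.

## Model selection

All predictor subsets (including intercept-only) are fit by OLS; the
Gaussian log-likelihood uses the ML error variance RSS/n and includes the
full n·ln(2π) constant so AICc values are comparable with mainstream
statistical software. k counts the coefficients, the intercept and the
error variance. Subsets whose AICc correction is undefined (n ≤ k + 1) or
whose design is rank-deficient are skipped with a warning; a numerically
saturated fit (RSS ≈ 0) is rejected at the AICc step with a clear error.
Models with ΔAICc ≤ 2 are averaged with renormalised Akaike weights: the
full average substitutes 0 where a predictor is absent, the unconditional
standard error is √Σwᵢ(SEᵢ² + (βᵢ − β̄)²), p-values come from a two-sided
z-test, and each predictor reports its sum of weights. When exactly one
model is selected, its plain OLS estimates and t-test p-values are
reported instead and flagged `single_model`. An optional flag refits all
subsets on log-transformed predictors and reports both tables; the default
is untransformed.

## Ordination

The NMDS engine is non-metric SMACOF (scikit-learn) run from random starts;
the package recomputes Kruskal stress-1 — √(Σ(d − d̂)²/Σd²) over
configuration distances d and monotone disparities d̂ — itself, with
primary tie treatment (tied dissimilarities ordered by configuration
distance before the isotonic fit, letting ties break in stress's favour).
Restarts stop early once a new solution matches the best stress within
`tol` *and* lies within `tol` symmetric Procrustes distance of it —
i.e. the optimiser keeps finding the same minimum; otherwise the best of
`n_restarts` (default 50) is returned flagged unconverged. Zero
dissimilarities between distinct regions are perturbed by +1e−9 before the
rank transform, with a warning. Procrustes distance is the symmetric
root-sum-of-squares after optimal translation, unit scaling and
rotation/reflection of both configurations.

For the map colours, the axis with the larger variance is min-max scaled
to [0,1]; the second axis is scaled by the same factor (preserving aspect
ratio) and shifted to start at 0. Colours interpolate bilinearly between
the four corners of the bounding box — (0,0) blue, (0,ymax) green, (1,0)
yellow, (1,ymax) red — and are rounded to integer RGB. Which corner gets
which colour is a package convention (any corner permutation would be an
equally faithful map) and is recorded in the output metadata.

## Synthetic study systems

The generator emulates a 17-region system: 14 mainland regions strung
north-to-south along a gently bowed ~9° latitude span, plus three islands
offset west/south of the tip. Climate is linear in latitude plus Gaussian
noise — precipitation 60 mm per °lat (σ = 80 mm), mean temperature −0.9 °C
per °lat (σ = 0.6 °C), spanning ~8 °C across regions as elevation
reinforces latitude in the emulated system — with tmin/tmax at ±8 °C
around tmean and areas log-normal around 15 000 km². The fauna has 88
species, 35% in the weak-dispersing suborder.

Occupancy probability multiplies four factors: a Gaussian thermal-niche
match (breadth 2 °C), a rainfall factor (pmean/pmean_max)^1 capturing
freshwater dependence, exponential dispersal decay from a source region
(0.0030 km⁻¹ for the weak dispersers, 0.0012 km⁻¹ for the strong ones;
water crossings pay a 3× distance multiplier), and an optional historical
block modifier (species assigned to contiguous latitude blocks get boosted
occupancy inside their block and penalised outside). Presences are
independent Bernoulli draws; empty regions and everywhere-absent species
are re-seeded with their most probable candidate so downstream matrices
are non-degenerate. Four adjacent-area faunas (anchored north-west, north,
north-east and south of the system) pool the three regions nearest each
anchor plus a few external species.

Scenarios: `climate_only` (niche + rainfall, no decay, no blocks),
`distance_only` (decay from random sources only), `historical`
(climate_only plus two latitude blocks at effect 0.8), and `null` (flat
occupancy 0.5 — pure Bernoulli noise). What the generator does *not*
emulate: spatially autocorrelated occupancy residuals (off by default),
observation error, richness-dependent sampling effort, and any
species-area mechanism (area enters the region table but not the
occupancy model). Passing recovery tests therefore shows the pipeline
detects the encoded structure at realistic sizes and noise — not that real
checklist data are free of the confounds the generator omits.

## Problem sizes used in the automated checks

Calibration suites use 1000–2000 simulated null systems at 99 permutations
per test (the add-one estimator makes the 5% level exactly attainable);
scenario-recovery suites use 200 replicate systems; the NMDS restart
protocol uses up to 50 restarts on 17 × 17 matrices. These sizes keep each
suite in the seconds-to-a-couple-of-minutes range on a single CPU while
leaving the binomial bands tight enough to detect real miscalibration.

## Known limitations

* Partial-Mantel liberality under nonlinear shared structure (above) is a
  property of the method, faithfully reproduced, not corrected.
* The Dutilleul covariance estimate is not guaranteed positive definite;
  the implementation guards the trace ratio and falls back to the
  classical test if it degenerates.
* NMDS on strongly block-structured dissimilarities can reach near-zero
  stress (cluster solutions reproduce the rank order almost perfectly);
  stress magnitudes are then not comparable with those of noisy systems.
* The regression machinery is plain OLS: no spatial error models, no mixed
  models, and count responses are treated as Gaussian.
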