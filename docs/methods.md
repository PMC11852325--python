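# Methods

## The model

`deltafield` implements a joint (multi-species) spatio-temporal species
distribution model for fishery-dependent catch records, of the family used
for CPUE standardization and range-shift analysis in fisheries science.
Each record is one haul × species, with biomass `b_i >= 0` (zeros included)
and area swept `a_i` (km²). Two linear predictors drive the observation
model — `p1` for the log expected numbers density and `p2` for the log
average catchable weight:

```
p1_i = beta1(c,t) + omega1(s,c) + eps1(s,c,t) + eta1(v,c)
       + sum_p [gamma1(c,p) + sigma_xi1(c,p) * xi1(s,c,p)] * B_i(p)
p2_i = (analogous, plus an optional fixed gear-catchability term)
```

with species `c`, year `t`, knot `s`, vessel `v`, and covariate basis
columns `B_i`. The Poisson-link transform maps these to the encounter
probability and positive catch rate

```
r1 = 1 - exp(-a * exp(p1)),     r2 = a * exp(p1) * exp(p2) / r1,
```

so that `r1 * r2 = a * exp(p1 + p2)` identically and density at unit
reference area is `d = exp(p1 + p2)` (kg/km²). Zero catches contribute
`log(1 - r1)`; positive catches contribute `log r1` plus a gamma
log-density with mean `r2` and dispersion `sigma2(c)` (the squared CV:
shape `1/sigma2`, scale `r2*sigma2`).

Interspecies dependence enters through loading matrices: the
spatio-temporal term is `eps_j(s,c,t) = sum_f L_j[c,f] u_j(f,t,s)`, where
the `u_j` are standardized Matérn (smoothness 1) Gaussian random fields at
the knots, independent across factors and years. `L L'` scaled to unit
diagonal is the reported interspecies correlation matrix. Vessel effects
are iid normal catchability deviations per vessel × species × component.

### Assumptions

- Records are conditionally independent given the latent fields.
- Spatio-temporal fields are independent across years (no temporal
  autocorrelation on `eps` or on the yearly intercepts).
- A single isotropic Matérn-1 kernel with one shared decorrelation range
  for all components; marginal variances are carried by the loadings.
- Fields are piecewise constant over the nearest-knot partition (no
  triangulated SPDE mesh).
- Purely spatial fields (`omega`) and spatially varying covariate
  coefficients (`xi`) are implemented but off by default: in the intended
  applications their variance estimates are typically near zero, and the
  leaner default model is markedly faster.

## Spatial discretization

Knots are k-means centroids (10 seeded restarts; centroids ordered
lexicographically so the mesh is reproducible) of the haul locations after
projection to a local equidistant plane in km — distances in degrees are
anisotropic at mid-latitudes. Defaults are 200 knots and a target of 2000
extrapolation cells; cells form a regular grid clipped to the convex hull
of the data, each cell's area being its exact intersection with the hull
(so cell areas tile the hull area) and each cell inheriting its nearest
knot's random effects. How prediction cells should be derived from knots
is a genuinely open design point; the regular-grid + nearest-knot rule is
this package's documented choice.

## Covariate responses

Covariates enter through a fixed basis of the standardized value:
quadratic by default (captures the unimodal/monotone thermal-niche shapes),
with linear and cubic B-spline (df 4, intercept column dropped) variants.
The standardization (mean/SD) is stored in the fitted object so that
prediction and projection use exactly the fitting-time scale. Collinearity
is screened by iteratively dropping the largest-VIF covariate until all
VIFs are below 10 (`vif_screen`, backed by statsmodels).

## Estimation

The marginal likelihood integrates over all random effects by the Laplace
approximation. Three design choices matter:

1. **Profiling.** The linear fixed effects (yearly intercepts `beta`,
   covariate coefficients `gamma`, gear effect) join the random effects in
   the inner Newton optimization, but the log-determinant correction is
   taken over the random-effect block only. The outer optimizer then sees
   only the variance-type parameters (loadings, log kernel range, log
   vessel SDs, log dispersions) — typically ~20 instead of ~80 parameters.
2. **Structured linear algebra.** With only spatio-temporal fields and
   vessel effects active, the random-effect Hessian block is
   block-diagonal by year (observations couple factor fields only within
   one knot-year) apart from a small vessel border, which is eliminated by
   a Schur complement; the log-determinant costs a few year-sized
   Cholesky factorizations assembled from per-(year, knot, species
   [, vessel]) weight sums instead of one large factorization. The
   identity of the structured and dense computations is asserted in the
   test suite.
3. **Warm-started finite differences.** No automatic differentiation is
   used: outer gradients are central (or, far from the optimum, forward)
   finite differences of the profiled Laplace objective, where each
   perturbed evaluation re-centers the inner mode with a single Newton
   correction using the unperturbed Hessian factor. This keeps the O(h)
   dependence of the mode on the parameters inside the difference
   quotient, so the finite-difference gradient agrees with a brute-force
   differentiation of the full marginal to ~1e-6 (tested).

The outer loop is L-BFGS-B followed by an optional damped-Newton polish on
a finite-difference outer Hessian. Convergence is reported per the usual
criteria — maximum absolute marginal-likelihood gradient below 1e-4 and a
positive-definite Hessian over the variance parameters. A fit is marked
`converged` only when both were actually verified; fits run with
`check_hessian=False` report `hessian_pd=None` and never claim
convergence. Replicated simulation fits may pass the previous optimum and
outer Hessian as warm starts (`init_theta`, `outer_hessian`); this changes
run time, not the estimates.

Wald standard errors for `beta`/`gamma` come from the corresponding block
of the inverse joint Hessian over (random effects, profiled fixed effects)
at the optimum — conditional on the variance parameters, the standard
GLMM-style interval. Uncertainty in the variance parameters themselves is
not propagated into these SEs.

Identifiability: loading matrices are lower-triangular; factor signs are
normalized after fitting so diagonals are non-negative. AIC counts all
estimated top-level parameters (intercepts, covariate coefficients,
loadings, kernel, vessel SDs, dispersions); deviance is reported as
`-2 log L`, and percent deviance explained is computed against a
temporal-intercept-only null model, since the natural baseline for that
column is otherwise underdetermined.

## Derived quantities

From predicted density `d(s,c,t)` on the cells: abundance index
`I = sum_s a(s) d(s,c,t)` (kg); biomass-weighted mean density
`D = sum_s [a d / I] d` (kg/km², ≥ the area-weighted mean by
Cauchy–Schwarz); center of gravity `Z = sum_s z(s,m) a d / I` computed in
projected km and back-transformed to lon/lat. Density predictions exclude
vessel and gear terms (catchability, not population density).

Scenario projection applies the fitted fixed effects and covariate
responses to shifted or supplied future covariate fields with the
spatio-temporal random effects at their zero mean and the yearly
intercepts at their across-year mean — the conservative choice when the
future latent fields are unobserved. (Simulating future fields for
uncertainty bands is possible via `simulate_grf` but is not the default.)

## Overlap indices

Levins, Schoener, Pianka and Morisita–Horn overlap, computed by default on
area-weighted proportion vectors `p(s) = a(s) d(s) / sum a d` — the
normalization under which the latter three provably stay in [0, 1]. Levins
is asymmetric (pair "A-B" = B's overlap on A's distribution) and can
exceed 1 even on proportions; values above 1 are reported as computed with
a warning, never clipped. A raw-density mode is available behind a flag.

## The synthetic-data generator

The generator draws from the exact generative model above, so the
estimator's target is known. Defaults emulate a fishery-log data set from
a mid-latitude marginal-sea system: a 117–125°E / 30–40°N box, 11 years,
four species with trophically motivated rank-2 factor structure (three
predator-like species sharing a positive factor, one prey-like species
loading negatively), haul positions snapped to 0.5° operational cells,
~2000 hauls per year, 20 vessels with catchability SD 0.2, two gear codes
with a +0.25 effect on `p2`, lognormal area swept (median 1 km², log-SD
0.3), gamma CV 0.8, kernel scale 150 km, and three smooth standardized
covariates (the first carrying a deterministic north–south gradient, an
SST analog) with quadratic responses. Tow effort is simulated directly as
area swept because a duration-to-area conversion is not well defined;
gear is treated as a two-level catchability covariate.

What the generator does **not** emulate: preferential sampling (vessels
targeting high density), vessel movement dynamics, real environmental
raster structure, temporal autocorrelation of the fields, or
measurement error in locations beyond the 0.5° snapping. Passing tests
therefore demonstrate correctness of the estimator under its own model
assumptions, not robustness to the ways real fishery-dependent data
violate them.

## Numerical choices

- Matérn correlation via `(d/rho) K1(d/rho)`; non-PD covariances repaired
  by an escalating diagonal jitter (1e-8 to 1e-4 of the marginal variance,
  then failure).
- Poisson-link computed with `expm1`/series so the identity
  `r1*r2 = a*exp(p1+p2)` holds to ~1e-15 down to vanishing intensities.
- Inner Newton: dense Cholesky with escalating ridge repair and a halving
  line search; gradient tolerance 1e-8.
- Finite-difference steps: 1e-4 (relative) for gradients, 1e-3 for the
  outer Hessian.
- k-means ties and factor-sign ambiguity resolved deterministically.

## Problem sizes used in the shipped studies

The simulation studies bundled with the tests and the acceptance script
run at desk scale, chosen to exercise every model component while keeping
a full run in minutes: the covariate-recovery study uses 4 species, 50
knots, 5 years, 5000 hauls and 20 replicates (8 in the acceptance script);
the model-selection study uses 2 species, 20 knots, 3 years, 1500 hauls
and 10 replicates; the pipeline demo uses 2 species, 15 knots and ~750
hauls. The full default mesh (200 knots / 2000 cells) is supported for
data analysis but is not exercised by the bundled studies.

## Known limitations

- No temporal autoregression on intercepts or fields; no anisotropy; no
  MCMC alternative to the Laplace approximation.
- Laplace bias for strongly skewed positive-catch distributions at low
  encounter rates is not corrected (no importance-sampling check).
- Derived-quantity uncertainty (delta-method or simulation-based) is not
  propagated; only fixed-effect Wald SEs are reported.
- Dense inner linear algebra: models beyond a few thousand latent effects
  (e.g., full rank × many years × hundreds of knots) are not practical.
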