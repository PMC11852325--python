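# deltafield

Joint spatio-temporal species distribution modelling for fishery-dependent
catch data: a multi-species **Poisson-link delta-GLMM** with Gaussian
random fields, plus the spatial summaries and overlap indices used to study
climate-driven range shifts.

## Who this is for

Fisheries and spatial ecologists who have haul-level catch records (with
zeros), environmental covariate fields, and want to (1) standardize CPUE
while separating encounter probability from positive catch rate, (2)
estimate interspecies spatio-temporal correlations, (3) derive abundance
indices, biomass-weighted densities and centers of gravity, and (4)
project densities and pairwise spatial overlap under environmental
scenarios. It also ships a synthetic-data generator that draws from the
exact generative model, so every estimator can be validated against known
ground truth.

## The model

Per haul × species record `i` with area swept `a_i`, two linear predictors

    p1_i = β1(c,t) + ε1(s,c,t) + η1(v,c) + Σ_p γ1(c,p)·B_i(p)   (+ ω, ξ terms)
    p2_i = analogous (+ gear catchability)

feed the Poisson-link transform

    r1 = 1 − exp(−a·e^{p1}),      r2 = a·e^{p1}·e^{p2}/r1,

so `r1·r2 = a·e^{p1+p2}` exactly. Zero catches have probability `1 − r1`;
positive catches are gamma with mean `r2` and dispersion σ²(c).
Interspecies structure comes from factor loadings:
`ε_j(s,c,t) = Σ_f L_j[c,f]·u_j(f,t,s)` with Matérn-1 Gaussian random
fields `u` at k-means knots; `LL'` (unit-scaled) is the species
correlation matrix. Estimation is by Laplace-approximated maximum
likelihood with the linear fixed effects profiled into the inner Newton
step — see `docs/methods.md` for the full account.

Derived quantities per species/time: abundance index `I = Σ_s a(s)·d(s)`,
biomass-weighted density `D = Σ_s [a·d/I]·d`, center of gravity
`Z = Σ_s z(s)·a·d/I`; overlap between species pairs via Levins, Schoener,
Pianka and Morisita–Horn indices on area-weighted proportion vectors.

## Worked example

Simulate a three-species fishery with two environmental covariates, fit
the model, and project a warming scenario:

```python
import numpy as np
from deltafield import *
from deltafield.basis import CovariateBasis

truth = TruthConfig(n_years=3, n_obs_per_year=600, n_vessels=8, n_species=3,
                    n_covariates=2, n_factors=2, seed=42).resolve()
X = generate_covariate_fields(truth)
rng = np.random.default_rng(42)
lon = rng.uniform(truth.lon_min, truth.lon_max, 3000)
lat = rng.uniform(truth.lat_min, truth.lat_max, 3000)
mesh = build_mesh(lon, lat, n_knots=25, n_cells=250, seed=42)
obs = simulate_observations(truth, mesh, X)

basis = CovariateBasis(kind="quadratic").fit(
    X.values.reshape(-1, X.n_cov), names=X.names)
Xh = X.at(obs.lon.to_numpy(), obs.lat.to_numpy(), obs.year.to_numpy())
m = fit(obs, mesh, Xh, ModelConfig(n_factors=2), basis=basis)

Xc = X.at_cells(mesh)
field = predict_density(m, mesh, Xc, times=[0, 1, 2])
summ = derived_summary(field)
warm, warm_sum = project_scenario(
    m, mesh, Xc[:, -1:, :] + np.array([2.0, 0.0]), scenario="warm")
```

Output (printed by the statements in `scripts/`-style usage):

```
records: 5400  encounter rate: 0.367
log-likelihood -7746.3  AIC 15608.6  converged True
SST linear effect on encounter (per species): [ 0.476  0.295 -0.134]  truth: [ 0.5  0.3 -0.2]
encounter-field species correlations:
 [[ 1.    0.89 -0.67]
 [ 0.89  1.   -0.26]
 [-0.67 -0.26  1.  ]]
COG northward shift under +2 SD SST [km]: [232.1 185.   78. ]
```

Reading this: the fit converged (max gradient < 1e-4, positive-definite
Hessian); the estimated SST effects on encounter probability recover the
generating coefficients within sampling error; the loading matrix implies
two positively correlated "predator-like" species and a negatively
correlated third; and a +2 SD uniform warming pushes every species'
center of gravity north, most strongly for the most SST-sensitive one.

A full pipeline (screen → fit → select → predict → project → overlap) is
available as a library call (`run_pipeline(RunConfig(...))`) or a CLI:

```bash
deltafield run --seed 3 --output-dir out/
# writes catch.csv, selection.csv, summaries.csv, overlap.csv,
# density.nc, cog_current.geojson, manifest.json
```

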