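"""Synthetic fishery-dependent data from a fully known generative model.

Emulates commercial-log catch records in a regional sea: haul locations
snapped to 0.5-degree operational cells, several species with cross-species
correlation induced by shared latent factor fields, zero-inflated
positive-skewed catches from the Poisson-link delta-gamma observation model,
vessel-level catchability heterogeneity, a two-level gear effect on the
catch-rate predictor, and smooth spatially/temporally varying environmental
covariate fields.  Every quantity is reproducible from the configuration
seed, so downstream estimation can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .basis import CovariateBasis
from .likelihood import poisson_link
from .mesh import KernelParams, SpatialMesh, _chol_with_jitter, matern_covariance
from .model import ParameterSet, RandomEffects, linear_predictors

GEARS = ("OTB", "PTB")


def _default_loadings(C: int, F: int, scale: float, flip: int | None = None) -> np.ndarray:
    """Lower-triangular loadings giving a trophically plausible pattern:
    strong shared variation among the first species, one species (the last,
    the prey analog) loading negatively on the shared factor."""
    L = np.zeros((C, F))
    for c in range(C):
        for f in range(min(c + 1, F)):
            if f == 0:
                L[c, 0] = scale * (1.0 if c < C - 1 else -0.6)
            elif f == c or f == F - 1:
                L[c, f] = 0.7 * scale
    if flip is not None and flip < F:
        L[:, flip] *= -1.0
    for f in range(min(C, F)):
        if L[f, f] < 0:
            L[:, f] *= -1.0
    return L


@dataclass
class TruthConfig:
    """Ground-truth configuration of the generative delta-GLMM.

    Defaults emulate the study system: a 117-125 E / 30-40 N box, four
    species, eleven years, 0.5-degree operational cells, three environmental
    covariates with quadratic responses, two shared latent factors per
    predictor component, and vessel-level catchability spread.  Arrays left
    as None are filled deterministically by ``resolve()``.
    """

    lon_min: float = 117.0
    lon_max: float = 125.0
    lat_min: float = 30.0
    lat_max: float = 40.0
    n_years: int = 11
    first_year: int = 2012
    n_species: int = 4
    n_vessels: int = 20
    n_obs_per_year: int = 2000
    n_covariates: int = 3
    n_factors: int = 2
    beta1: np.ndarray | None = None
    beta2: np.ndarray | None = None
    gamma1: np.ndarray | None = None      # (C, n_cov * n_basis), basis columns
    gamma2: np.ndarray | None = None
    loadings_epsilon: tuple | None = None  # (L1, L2), species x factor
    loadings_omega: tuple | None = None    # purely spatial fields; default off
    kernel_range: float = 150.0            # km
    vessel_sd: float = 0.2                 # link scale, both components
    gear_effect: float = 0.25              # added to p2 for the second gear
    gamma_cv: float = 0.8                  # CV of positive catches
    area_lognorm_sd: float = 0.3           # area swept ~ lognormal, median 1 km2
    basis: str = "quadratic"
    snap_deg: float = 0.5
    covariate_deg: float = 0.25
    anomaly_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.kernel_range <= 0:
            raise ValueError("kernel_range must be positive")
        if self.gamma_cv <= 0:
            raise ValueError("gamma_cv must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("empty domain box")

    @property
    def years(self) -> list:
        return [self.first_year + t for t in range(self.n_years)]

    @property
    def species(self) -> list:
        return [f"sp{c + 1:02d}" for c in range(self.n_species)]

    @property
    def n_basis(self) -> int:
        return {"linear": 1, "quadratic": 2, "bspline": 3}[self.basis]

    def resolve(self) -> "TruthConfig":
        """Fill unset parameter arrays with the deterministic defaults."""
        C, T, F = self.n_species, self.n_years, self.n_factors
        P = self.n_covariates * self.n_basis
        out = replace(self)
        if out.beta1 is None:
            base = np.linspace(-0.4, -1.0, C)[:, None]
            wiggle = 0.25 * np.sin(2 * np.pi * np.arange(T) / max(T, 2)
                                   + np.arange(C)[:, None])
            out.beta1 = base + wiggle
        if out.beta2 is None:
            base = np.linspace(1.2, 0.6, C)[:, None]
            wiggle = 0.15 * np.cos(2 * np.pi * np.arange(T) / max(T, 2)
                                   + 0.5 * np.arange(C)[:, None])
            out.beta2 = base + wiggle
        if out.gamma1 is None:
            g = np.zeros((C, P))
            for c in range(C):
                for p in range(self.n_covariates):
                    g[c, p * self.n_basis] = [0.5, 0.3, -0.2, 0.1][c % 4] / (p + 1)
                    if self.n_basis > 1:
                        g[c, p * self.n_basis + 1] = -0.15 / (p + 1)
            out.gamma1 = g
        if out.gamma2 is None:
            out.gamma2 = 0.5 * np.asarray(out.gamma1)
        if out.loadings_epsilon is None:
            out.loadings_epsilon = (_default_loadings(C, F, 0.5),
                                    _default_loadings(C, F, 0.4))
        out._check_shapes()
        return out

    def _check_shapes(self):
        C, T = self.n_species, self.n_years
        P = self.n_covariates * self.n_basis
        for name, arr, shape in (("beta1", self.beta1, (C, T)),
                                 ("beta2", self.beta2, (C, T)),
                                 ("gamma1", self.gamma1, (C, P)),
                                 ("gamma2", self.gamma2, (C, P))):
            if np.asarray(arr).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
        for L in self.loadings_epsilon:
            if np.asarray(L).shape[0] != C:
                raise ValueError("loadings must have one row per species")

    def to_parameter_set(self, basis: CovariateBasis) -> ParameterSet:
        cfg = self.resolve() if self.beta1 is None else self
        L1, L2 = cfg.loadings_epsilon
        Lo1, Lo2 = cfg.loadings_omega if cfg.loadings_omega else (None, None)
        return ParameterSet(
            beta1=np.asarray(cfg.beta1, float), beta2=np.asarray(cfg.beta2, float),
            L1_eps=np.asarray(L1, float), L2_eps=np.asarray(L2, float),
            L1_omega=Lo1, L2_omega=Lo2,
            kernel=KernelParams(cfg.kernel_range, 1.0),
            gamma1=np.asarray(cfg.gamma1, float), gamma2=np.asarray(cfg.gamma2, float),
            vessel_sd1=cfg.vessel_sd, vessel_sd2=cfg.vessel_sd,
            sigma2=np.full(cfg.n_species, cfg.gamma_cv ** 2),
            gear2=cfg.gear_effect, basis_spec=basis)


# ---------------------------------------------------------------------------
# covariate fields
# ---------------------------------------------------------------------------

@dataclass
class CovariateFields:
    """Gridded covariates X(s, t, p), standardized over all cells and years."""

    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray          # (n_grid, n_years, n_cov)
    years: list
    names: list

    def __post_init__(self):
        self._tree = None

    @property
    def n_cov(self) -> int:
        return self.values.shape[2]

    def at(self, lon, lat, year) -> np.ndarray:
        """Nearest-grid-point covariate values; year may be scalar or array."""
        if self._tree is None:
            self._tree = cKDTree(np.column_stack([self.lon, self.lat]))
        _, idx = self._tree.query(np.column_stack(
            [np.atleast_1d(lon), np.atleast_1d(lat)]))
        year = np.atleast_1d(year)
        t = np.searchsorted(np.asarray(self.years), year)
        if np.any(t >= len(self.years)) or np.any(np.asarray(self.years)[t] != year):
            raise KeyError("year not present in covariate fields")
        return self.values[idx, t, :]

    def at_cells(self, mesh: SpatialMesh) -> np.ndarray:
        """(n_cells, n_years, n_cov) sampled at mesh cell centers."""
        if self._tree is None:
            self._tree = cKDTree(np.column_stack([self.lon, self.lat]))
        _, idx = self._tree.query(mesh.cells_lonlat)
        return self.values[idx, :, :]

    def shifted(self, shift) -> "CovariateFields":
        return make_scenario(self, shift)


def _smooth_field(rng, lon_n, lat_n, lon_span, lat_span, n_waves=4):
    """Sum of low-frequency plane waves over normalized coordinates."""
    out = np.zeros(lon_n.shape)
    for _ in range(n_waves):
        kx, ky = rng.uniform(0.5, 2.0, size=2) * rng.choice([-1, 1], size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.4, 1.0)
        out += amp * np.cos(2 * np.pi * (kx * lon_n + ky * lat_n) + phase)
    return out


def generate_covariate_fields(config: TruthConfig,
                              n_covariates: int | None = None) -> CovariateFields:
    """Smooth standardized covariate fields on a regular grid over the box.

    Each covariate is a fixed low-frequency spatial surface (the first one
    carries a deterministic north-south gradient, an SST-like structure) plus
    a yearly low-frequency anomaly scaled by ``anomaly_amplitude``; the
    result is standardized to mean 0, SD 1 over all cells and years.
    Deterministic given ``config.seed``.
    """
    n_cov = n_covariates if n_covariates is not None else config.n_covariates
    if n_cov < 1:
        raise ValueError("need at least one covariate")
    res = config.covariate_deg
    lons = np.arange(config.lon_min + res / 2, config.lon_max, res)
    lats = np.arange(config.lat_min + res / 2, config.lat_max, res)
    if lons.size == 0 or lats.size == 0:
        raise ValueError("empty covariate grid: box smaller than resolution")
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel(), glat.ravel()
    lon_n = (glon - config.lon_min) / (config.lon_max - config.lon_min)
    lat_n = (glat - config.lat_min) / (config.lat_max - config.lat_min)

    rng = np.random.default_rng(config.seed + 1_000_003)
    T = config.n_years
    vals = np.empty((glon.size, T, n_cov))
    for p in range(n_cov):
        base = _smooth_field(rng, lon_n, lat_n, 1.0, 1.0)
        if p == 0:
            base = base * 0.5 - 2.5 * lat_n   # warmer south: SST-like gradient
        for t in range(T):
            anom = config.anomaly_amplitude * _smooth_field(
                rng, lon_n, lat_n, 1.0, 1.0, n_waves=2)
            vals[:, t, p] = base + anom
    mean = vals.reshape(-1, n_cov).mean(axis=0)
    sd = vals.reshape(-1, n_cov).std(axis=0)
    vals = (vals - mean) / sd
    names = ["sst", "chla", "scv"][:n_cov] + [
        f"cov{j}" for j in range(3, n_cov)]
    return CovariateFields(lon=glon, lat=glat, values=vals,
                           years=config.years, names=names)


def make_scenario(X: CovariateFields, shift) -> CovariateFields:
    """Uniformly shifted covariate fields: X'(s,t,p) = X(s,t,p) + shift(p)."""
    shift = np.asarray(shift, dtype=float).ravel()
    if shift.size != X.n_cov:
        raise ValueError(
            f"shift has {shift.size} entries for {X.n_cov} covariates")
    return CovariateFields(lon=X.lon, lat=X.lat,
                           values=X.values + shift[None, None, :],
                           years=list(X.years), names=list(X.names))


# ---------------------------------------------------------------------------
# observation simulation
# ---------------------------------------------------------------------------

def _snap(x, lo, res):
    return lo + (np.floor((x - lo) / res) + 0.5) * res


def simulate_observations(truth: TruthConfig, mesh: SpatialMesh,
                          X: CovariateFields) -> pd.DataFrame:
    """Draw a fishery-dependent catch table from the generative model.

    Returns one row per haul x species with zero catches included; columns
    follow the catch-CSV schema (lon, lat, year, vessel, gear,
    area_swept_km2, species, catch_kg).
    """
    truth = truth.resolve()
    rng = np.random.default_rng(truth.seed)
    C, T, F = truth.n_species, truth.n_years, truth.n_factors
    n = truth.n_obs_per_year * T

    lon = rng.uniform(truth.lon_min, truth.lon_max, size=n)
    lat = rng.uniform(truth.lat_min, truth.lat_max, size=n)
    lon = _snap(lon, truth.lon_min, truth.snap_deg)
    lat = _snap(lat, truth.lat_min, truth.snap_deg)
    year = np.repeat(truth.years, truth.n_obs_per_year)
    vessel = rng.integers(0, truth.n_vessels, size=n)
    gear = np.asarray(GEARS)[rng.integers(0, 2, size=n)]
    area = np.exp(rng.normal(0.0, truth.area_lognorm_sd, size=n))

    # latent factor fields at the knots, iid across factors and years
    R = matern_covariance(mesh.knot_distances(),
                          KernelParams(truth.kernel_range, 1.0))
    chol = _chol_with_jitter(R, 1.0)
    K = mesh.n_knots

    def draw_fields(n_fields):
        return (chol @ rng.standard_normal((K, n_fields))).T

    L1, L2 = (np.asarray(a, float) for a in truth.loadings_epsilon)
    u1 = draw_fields(L1.shape[1] * T).reshape(L1.shape[1], T, K)
    u2 = draw_fields(L2.shape[1] * T).reshape(L2.shape[1], T, K)
    eta1 = rng.normal(0.0, truth.vessel_sd, size=(truth.n_vessels, C))
    eta2 = rng.normal(0.0, truth.vessel_sd, size=(truth.n_vessels, C))
    re = RandomEffects(u1=u1, u2=u2, eta1=eta1, eta2=eta2)
    if truth.loadings_omega is not None:
        Fo = np.asarray(truth.loadings_omega[0]).shape[1]
        re.omega1 = draw_fields(Fo)
        re.omega2 = draw_fields(Fo)

    basis = CovariateBasis(kind=truth.basis).fit(
        X.values.reshape(-1, X.n_cov), names=X.names)
    params = truth.to_parameter_set(basis)
    params.validate()

    obs = pd.DataFrame({
        "lon": np.tile(lon, C), "lat": np.tile(lat, C),
        "year": np.tile(year, C),
        "vessel": np.tile(vessel, C), "gear": np.tile(gear, C),
        "area_swept_km2": np.tile(area, C),
        "species": np.repeat(truth.species, n),
    })
    X_obs = X.at(obs["lon"].to_numpy(), obs["lat"].to_numpy(),
                 obs["year"].to_numpy())
    p1, p2 = linear_predictors(params, re, mesh, X_obs, obs)
    r1, r2 = poisson_link(p1, p2, obs["area_swept_km2"].to_numpy())

    enc = rng.uniform(size=len(obs)) < r1
    # gamma with mean r2 and CV gamma_cv: shape = 1/cv^2, scale = mean * cv^2
    shape = 1.0 / truth.gamma_cv ** 2
    pos = rng.gamma(shape, scale=np.where(enc, r2, 1.0) * truth.gamma_cv ** 2)
    obs["catch_kg"] = np.where(enc, pos, 0.0)
    obs.attrs["truth_seed"] = truth.seed
    return obs
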