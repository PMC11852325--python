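"""Derived spatial summaries of a fitted (or true) model.

From predicted density d(s,c,t) on the extrapolation cells:

    abundance index          I(c,t) = sum_s a(s) d(s,c,t)
    biomass-weighted density D(c,t) = sum_s [a(s) d(s,c,t) / I(c,t)] d(s,c,t)
    center of gravity        Z(c,t,m) = sum_s z(s,m) a(s) d(s,c,t) / I(c,t)

Density is evaluated at unit reference area, so d = r1*r2 = exp(p1+p2) in
kg per km^2.  Predictions use the posterior modes of the random effects
where estimated; scenario projections set the spatio-temporal random
effects to their zero mean and average the temporal intercepts over the
fitted years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import poisson_link
from .mesh import SpatialMesh
from .model import FittedModel, ParameterSet, RandomEffects
from .simulate import CovariateFields


@dataclass
class DensityField:
    """Predicted density per cell/species/time (kg per km^2)."""

    d: np.ndarray               # (n_cells, n_species, n_times)
    mesh: SpatialMesh
    species: list
    times: list
    scenario: str = "current"

    def __post_init__(self):
        if np.any(self.d < 0):
            raise ValueError("density must be non-negative")
        if self.d.shape[0] != self.mesh.n_cells:
            raise ValueError("density rows must match mesh cells")

    def to_frame(self) -> pd.DataFrame:
        s, c, t = np.meshgrid(np.arange(self.mesh.n_cells),
                              np.arange(len(self.species)),
                              np.arange(len(self.times)), indexing="ij")
        return pd.DataFrame({
            "lon": self.mesh.cells_lonlat[s.ravel(), 0],
            "lat": self.mesh.cells_lonlat[s.ravel(), 1],
            "area_km2": self.mesh.cell_area_km2[s.ravel()],
            "species": np.asarray(self.species)[c.ravel()],
            "time": np.asarray(self.times)[t.ravel()],
            "scenario": self.scenario,
            "density_kg_km2": self.d.ravel(),
        })


@dataclass
class DerivedSummary:
    """Abundance index, biomass-weighted density and center of gravity."""

    I: np.ndarray               # (C, T) kg
    D: np.ndarray               # (C, T) kg per km^2
    Z_km: np.ndarray            # (C, T, 2) projected easting/northing
    Z_lonlat: np.ndarray        # (C, T, 2) geographic mirror
    species: list
    times: list
    scenario: str = "current"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, sp in enumerate(self.species):
            for ti, tm in enumerate(self.times):
                rows.append({
                    "species": sp, "time": tm, "scenario": self.scenario,
                    "abundance_index_kg": self.I[ci, ti],
                    "weighted_density_kg_km2": self.D[ci, ti],
                    "cog_easting_km": self.Z_km[ci, ti, 0],
                    "cog_northing_km": self.Z_km[ci, ti, 1],
                    "cog_lon": self.Z_lonlat[ci, ti, 0],
                    "cog_lat": self.Z_lonlat[ci, ti, 1]})
        return pd.DataFrame(rows)


def _cell_covariates(X, mesh: SpatialMesh, n_times: int):
    if isinstance(X, CovariateFields):
        Xc = X.at_cells(mesh)
    elif X is None:
        return None
    else:
        Xc = np.asarray(X, dtype=float)
    if Xc.ndim == 2:
        Xc = np.repeat(Xc[:, None, :], n_times, axis=1)
    if Xc.shape[0] != mesh.n_cells:
        raise ValueError("covariates must be given for every cell")
    bad = np.where(~np.isfinite(Xc).all(axis=(1, 2)))[0]
    if bad.size:
        raise ValueError(f"missing covariate values at cells {bad[:20].tolist()}"
                         + ("..." if bad.size > 20 else ""))
    return Xc


def predict_density(model, mesh: SpatialMesh, X=None, times=None,
                    use_random_effects: bool = True,
                    scenario: str = "current") -> DensityField:
    """Predicted density field from a fitted model or explicit parameters.

    ``model`` may be a FittedModel, a ParameterSet, or a (ParameterSet,
    RandomEffects) pair.  Vessel and gear catchability effects are excluded:
    density describes the population, not the observation process.  ``times``
    selects/labels prediction times; times beyond the fitted years use the
    mean temporal intercept and zero spatio-temporal effects.
    """
    if isinstance(model, FittedModel):
        params, re = model.params, model.random_effects
    elif isinstance(model, tuple):
        params, re = model
    else:
        params, re = model, None
    if not use_random_effects:
        re = None
    re = re or RandomEffects()
    C, T_fit = params.beta1.shape
    times = list(times) if times is not None else list(range(T_fit))
    n_t = len(times)
    Xc = _cell_covariates(X, mesh, n_t)
    k = mesh.cell_knot
    S = mesh.n_cells

    d = np.empty((S, C, n_t))
    beta_mean1 = params.beta1.mean(axis=1)
    beta_mean2 = params.beta2.mean(axis=1)
    for ti, tm in enumerate(times):
        in_fit = isinstance(tm, (int, np.integer)) and 0 <= tm < T_fit
        for c in range(C):
            p1 = np.full(S, params.beta1[c, tm] if in_fit else beta_mean1[c])
            p2 = np.full(S, params.beta2[c, tm] if in_fit else beta_mean2[c])
            if in_fit and params.L1_eps is not None and re.u1 is not None:
                p1 += params.L1_eps[c, :] @ re.u1[:, tm, :][:, k]
            if in_fit and params.L2_eps is not None and re.u2 is not None:
                p2 += params.L2_eps[c, :] @ re.u2[:, tm, :][:, k]
            if params.L1_omega is not None and re.omega1 is not None:
                p1 += params.L1_omega[c, :] @ re.omega1[:, k]
            if params.L2_omega is not None and re.omega2 is not None:
                p2 += params.L2_omega[c, :] @ re.omega2[:, k]
            if Xc is not None and params.gamma1 is not None:
                B = params.basis_spec.expand(Xc[:, ti, :])
                p1 += B @ params.gamma1[c, :]
                p2 += B @ params.gamma2[c, :]
                if params.sigma_xi1 is not None and re.xi1 is not None:
                    p1 += (B * params.sigma_xi1[c, :]
                           * re.xi1[c, :, :][:, k].T).sum(axis=1)
                if params.sigma_xi2 is not None and re.xi2 is not None:
                    p2 += (B * params.sigma_xi2[c, :]
                           * re.xi2[c, :, :][:, k].T).sum(axis=1)
            r1, r2 = poisson_link(p1, p2, 1.0)
            d[:, c, ti] = r1 * r2
    species = getattr(params, "species", None) or [f"sp{c + 1:02d}" for c in range(C)]
    return DensityField(d=d, mesh=mesh, species=species, times=times,
                        scenario=scenario)


def abundance_index(field: DensityField) -> np.ndarray:
    """I(c,t) = sum_s a(s) d(s,c,t), in kg."""
    return np.einsum("s,sct->ct", field.mesh.cell_area_km2, field.d)


def weighted_density(field: DensityField) -> np.ndarray:
    """Biomass-weighted average density D(c,t); NaN where I(c,t) = 0."""
    I = abundance_index(field)
    num = np.einsum("s,sct->ct", field.mesh.cell_area_km2, field.d ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / I
    D[I == 0] = np.nan
    return D


def center_of_gravity(field: DensityField) -> tuple[np.ndarray, np.ndarray]:
    """Z(c,t,m): density-weighted mean location, in projected km and lon/lat.

    NaN where the abundance index is zero.
    """
    I = abundance_index(field)
    w = field.mesh.cell_area_km2[:, None, None] * field.d
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.stack([np.einsum("s,sct->ct", field.mesh.cells_xy[:, m], w) / I
                      for m in (0, 1)], axis=-1)
    Z[I == 0] = np.nan
    C, T = I.shape
    Z_ll = np.full_like(Z, np.nan)
    flat = Z.reshape(-1, 2)
    ok = np.isfinite(flat).all(axis=1)
    if ok.any():
        Z_ll.reshape(-1, 2)[ok] = field.mesh.projection.to_lonlat(flat[ok])
    return Z, Z_ll


def derived_summary(field: DensityField) -> DerivedSummary:
    I = abundance_index(field)
    D = weighted_density(field)
    Z, Z_ll = center_of_gravity(field)
    return DerivedSummary(I=I, D=D, Z_km=Z, Z_lonlat=Z_ll,
                          species=field.species, times=field.times,
                          scenario=field.scenario)


def project_scenario(model, mesh: SpatialMesh, X_future, times=None,
                     scenario: str = "scenario") -> tuple[DensityField, DerivedSummary]:
    """Project density under scenario covariates.

    Fixed effects and fitted covariate responses are applied to the scenario
    fields; spatio-temporal random effects are set to their zero mean (the
    conservative projection default) and the temporal intercepts to their
    across-year mean.
    """
    if isinstance(X_future, CovariateFields):
        n_t = X_future.values.shape[1]
        times = list(times) if times is not None else list(X_future.years)
        if len(times) != n_t:
            raise ValueError("times must match the scenario covariate years")
    else:
        X_future = np.asarray(X_future, dtype=float)
        n_t = X_future.shape[1] if X_future.ndim == 3 else 1
        times = list(times) if times is not None else [f"proj{j}" for j in range(n_t)]
    field = predict_density(model, mesh, X_future, times=times,
                            use_random_effects=False, scenario=scenario)
    return field, derived_summary(field)
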