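"""Readers and writers for the pipeline's file formats.

Catch tables are CSV with one row per haul x species (zero catches
included); covariates are NetCDF (dims cell/year, via the scipy NetCDF3
engine) or long-format CSV (lon, lat, year, covariate, value); meshes are
JSON+CSV bundles; results go to tidy CSV/JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import SpatialMesh
from .model import REQUIRED_COLUMNS
from .simulate import CovariateFields

logger = logging.getLogger(__name__)


def write_catch_csv(obs: pd.DataFrame, path) -> None:
    obs.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def read_catch_csv(path) -> pd.DataFrame:
    """Validated catch table; logs per-species encounter summaries."""
    obs = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"catch CSV missing columns: {missing}")
    bad = obs.index[obs["catch_kg"] < 0].tolist()
    if bad:
        raise ValueError(f"negative catch_kg at rows {bad[:10]}")
    bad = obs.index[obs["area_swept_km2"] <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive area_swept_km2 at rows {bad[:10]}")
    logger.info("read %d records, %d species, %d years", len(obs),
                obs["species"].nunique(), obs["year"].nunique())
    for sp, grp in obs.groupby("species"):
        logger.info("  %s: encounter frequency %.3f over %d records",
                    sp, float((grp["catch_kg"] > 0).mean()), len(grp))
    return obs


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def write_covariates_csv(X: CovariateFields, path) -> None:
    rows = []
    for p, name in enumerate(X.names):
        for t, year in enumerate(X.years):
            rows.append(pd.DataFrame({
                "lon": X.lon, "lat": X.lat, "year": year,
                "covariate": name, "value": X.values[:, t, p]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_covariates_netcdf(X: CovariateFields, path) -> None:
    import xarray as xr

    ds = xr.Dataset(
        {name: (("cell", "year"), X.values[:, :, p])
         for p, name in enumerate(X.names)},
        coords={"lon": ("cell", X.lon), "lat": ("cell", X.lat),
                "year": list(X.years)})
    ds.to_netcdf(path, engine="scipy")


def read_covariates(path, names=None) -> CovariateFields:
    """Read gridded covariates from long CSV or NetCDF into CovariateFields."""
    path = Path(path)
    if path.suffix.lower() in (".nc", ".cdf", ".netcdf"):
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        names = names or [v for v in ds.data_vars]
        lon = ds["lon"].values
        lat = ds["lat"].values
        years = [int(y) for y in ds["year"].values]
        vals = np.stack([ds[n].values for n in names], axis=-1)
        return CovariateFields(lon=lon, lat=lat, values=vals, years=years,
                               names=list(names))
    long = pd.read_csv(path)
    required = {"lon", "lat", "year", "covariate", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"covariate CSV must have columns {sorted(required)}")
    names = names or sorted(long["covariate"].unique().tolist())
    years = sorted(long["year"].unique().tolist())
    pts = long[["lon", "lat"]].drop_duplicates().to_numpy()
    key = {tuple(p): i for i, p in enumerate(pts)}
    vals = np.full((len(pts), len(years), len(names)), np.nan)
    tix = {y: i for i, y in enumerate(years)}
    pix = {n: i for i, n in enumerate(names)}
    for (year, cov), grp in long.groupby(["year", "covariate"]):
        if cov not in pix:
            continue
        idx = [key[(lo, la)] for lo, la in zip(grp["lon"], grp["lat"])]
        vals[idx, tix[year], pix[cov]] = grp["value"].to_numpy()
    return CovariateFields(lon=pts[:, 0], lat=pts[:, 1], values=vals,
                           years=years, names=list(names))


def regrid_to_cells(X: CovariateFields, mesh: SpatialMesh,
                    max_missing_frac: float = 0.2) -> np.ndarray:
    """Nearest-neighbour regrid of covariate fields onto mesh cells.

    Source points with NaN values are ignored; cells falling nearest to a
    missing point are filled from the nearest non-missing point (counted and
    logged).  More than ``max_missing_frac`` missing within the domain is an
    error.
    """
    finite = np.isfinite(X.values).all(axis=(1, 2))
    frac_missing = 1.0 - finite.mean()
    if frac_missing > max_missing_frac:
        raise ValueError(
            f"{100 * frac_missing:.1f}% of covariate grid points are missing")
    pts = np.column_stack([X.lon, X.lat])
    tree_all = cKDTree(pts)
    _, idx = tree_all.query(mesh.cells_lonlat)
    filled = 0
    if not finite.all():
        bad = ~finite[idx]
        if bad.any():
            tree_ok = cKDTree(pts[finite])
            _, sub = tree_ok.query(mesh.cells_lonlat[bad])
            idx[bad] = np.where(finite)[0][sub]
            filled = int(bad.sum())
    if filled:
        logger.info("filled %d cells from nearest non-missing neighbours", filled)
    return X.values[idx, :, :]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_selection_csv(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={
        "effects": "Effects Included", "AIC": "AIC", "dAIC": "dAIC",
        "deviance": "Deviance",
        "pct_deviance_explained": "Percent Deviance Explained"})
    out.to_csv(path, index=False)


def write_fitted_json(fitted, path) -> None:
    def conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        return x

    p = fitted.params
    doc = {
        "label": fitted.label, "effects": fitted.effects,
        "loglik": fitted.loglik, "aic": fitted.aic, "k": fitted.k,
        "deviance": fitted.deviance,
        "max_abs_gradient": fitted.max_abs_gradient,
        "hessian_pd": fitted.hessian_pd, "converged": fitted.converged,
        "n_obs": fitted.n_obs, "fingerprint": fitted.fingerprint,
        "params": {
            "beta1": conv(p.beta1), "beta2": conv(p.beta2),
            "L1_eps": conv(p.L1_eps), "L2_eps": conv(p.L2_eps),
            "gamma1": conv(p.gamma1), "gamma2": conv(p.gamma2),
            "kernel_range_km": None if p.kernel is None else p.kernel.range_km,
            "vessel_sd1": p.vessel_sd1, "vessel_sd2": p.vessel_sd2,
            "sigma2": conv(p.sigma2), "gear2": p.gear2,
            "basis": None if p.basis_spec is None else p.basis_spec.to_dict(),
        },
        "se": {k: conv(v) for k, v in fitted.se.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_density_netcdf(fields, path) -> None:
    import xarray as xr

    fields = fields if isinstance(fields, (list, tuple)) else [fields]
    arrays = {}
    for f in fields:
        arrays[f.scenario] = xr.DataArray(
            f.d, dims=("cell", "species", "time"),
            coords={"lon": ("cell", f.mesh.cells_lonlat[:, 0]),
                    "lat": ("cell", f.mesh.cells_lonlat[:, 1]),
                    "area_km2": ("cell", f.mesh.cell_area_km2),
                    "species": [str(s) for s in f.species],
                    "time": [str(t) for t in f.times]})
    xr.Dataset(arrays).to_netcdf(path, engine="scipy")


def write_cog_geojson(summary, path) -> None:
    feats = []
    for ci, sp in enumerate(summary.species):
        coords = [[float(summary.Z_lonlat[ci, ti, 0]),
                   float(summary.Z_lonlat[ci, ti, 1])]
                  for ti in range(len(summary.times))
                  if np.isfinite(summary.Z_lonlat[ci, ti]).all()]
        feats.append({"type": "Feature",
                      "properties": {"species": str(sp),
                                     "scenario": summary.scenario},
                      "geometry": {"type": "LineString", "coordinates": coords}})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
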