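"""Spatial discretization and Gaussian random-field machinery.

The spatial layout follows the standard knot/extrapolation-cell design of
spatio-temporal delta-GLMMs: random effects live at a reduced set of *knots*
obtained by k-means clustering of the observed haul locations, and densities
are predicted on a fine regular grid of *cells* clipped to the convex hull of
the data, each cell inheriting the random effects of its nearest knot.

Coordinates are projected from geographic degrees to a local equidistant
plane (km) before clustering and distance computation, because a degree of
longitude at 30-40 N is substantially shorter than a degree of latitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import kv
from shapely.geometry import MultiPoint, box
from sklearn.cluster import KMeans

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection about a reference point (lon0, lat0).

    x = R * cos(lat0) * (lon - lon0) in radians, y = R * (lat - lat0).
    Adequate for regional domains (a few hundred km); distances are
    near-geodesic away from the poles.
    """

    lon0: float
    lat0: float

    def to_km(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.deg2rad(lon - self.lon0) * EARTH_RADIUS_KM * np.cos(np.deg2rad(self.lat0))
        y = np.deg2rad(lat - self.lat0) * EARTH_RADIUS_KM
        return np.column_stack([x, y])

    def to_lonlat(self, xy):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        lon = self.lon0 + np.rad2deg(xy[:, 0] / (EARTH_RADIUS_KM * np.cos(np.deg2rad(self.lat0))))
        lat = self.lat0 + np.rad2deg(xy[:, 1] / EARTH_RADIUS_KM)
        return np.column_stack([lon, lat])


@dataclass
class SpatialMesh:
    """Knots plus extrapolation cells.

    Attributes
    ----------
    knots_xy : (n_knots, 2) projected km
    cells_xy : (n_cells, 2) projected km, cell centers
    cell_area_km2 : (n_cells,) area of each cell clipped to the data hull
    cell_knot : (n_cells,) index of the nearest knot for every cell
    """

    projection: LocalProjection
    knots_xy: np.ndarray
    cells_xy: np.ndarray
    cell_area_km2: np.ndarray
    cell_knot: np.ndarray
    knots_lonlat: np.ndarray = field(default=None)
    cells_lonlat: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.knots_lonlat is None:
            self.knots_lonlat = self.projection.to_lonlat(self.knots_xy)
        if self.cells_lonlat is None:
            self.cells_lonlat = self.projection.to_lonlat(self.cells_xy)
        if np.any(self.cell_area_km2 <= 0):
            raise ValueError("all cell areas must be positive")
        if self.cell_knot.shape[0] != self.cells_xy.shape[0]:
            raise ValueError("cell_knot must have one entry per cell")

    @property
    def n_knots(self) -> int:
        return self.knots_xy.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells_xy.shape[0]

    def knot_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances (km) between knots."""
        d = self.knots_xy[:, None, :] - self.knots_xy[None, :, :]
        return np.sqrt((d ** 2).sum(axis=-1))

    def assign_knot(self, lon, lat) -> np.ndarray:
        """Nearest-knot index for arbitrary geographic points."""
        xy = self.projection.to_km(lon, lat)
        _, idx = cKDTree(self.knots_xy).query(xy)
        return idx

    # -- serialization (JSON + CSV bundle) ---------------------------------
    def to_files(self, prefix) -> None:
        meta = {"lon0": self.projection.lon0, "lat0": self.projection.lat0,
                "n_knots": int(self.n_knots), "n_cells": int(self.n_cells)}
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        pd.DataFrame({"x_km": self.knots_xy[:, 0], "y_km": self.knots_xy[:, 1],
                      "lon": self.knots_lonlat[:, 0], "lat": self.knots_lonlat[:, 1]}
                     ).to_csv(f"{prefix}_knots.csv", index=False)
        pd.DataFrame({"x_km": self.cells_xy[:, 0], "y_km": self.cells_xy[:, 1],
                      "lon": self.cells_lonlat[:, 0], "lat": self.cells_lonlat[:, 1],
                      "area_km2": self.cell_area_km2, "knot": self.cell_knot}
                     ).to_csv(f"{prefix}_cells.csv", index=False)

    @classmethod
    def from_files(cls, prefix) -> "SpatialMesh":
        with open(f"{prefix}_meta.json") as fh:
            meta = json.load(fh)
        proj = LocalProjection(meta["lon0"], meta["lat0"])
        knots = pd.read_csv(f"{prefix}_knots.csv")
        cells = pd.read_csv(f"{prefix}_cells.csv")
        return cls(projection=proj,
                   knots_xy=knots[["x_km", "y_km"]].to_numpy(),
                   cells_xy=cells[["x_km", "y_km"]].to_numpy(),
                   cell_area_km2=cells["area_km2"].to_numpy(),
                   cell_knot=cells["knot"].to_numpy(int),
                   knots_lonlat=knots[["lon", "lat"]].to_numpy(),
                   cells_lonlat=cells[["lon", "lat"]].to_numpy())


def build_mesh(lon, lat, n_knots: int = 200, n_cells: int = 2000,
               seed: int = 0) -> SpatialMesh:
    """Build the knot/cell discretization from observed locations.

    Knots are k-means centroids (10 restarts, seeded) of the projected
    locations; cells are a regular grid over the bounding box clipped to the
    convex hull of the data, with each cell's area equal to its intersection
    with the hull and each cell assigned to its nearest knot.  ``n_cells`` is
    a target: the realized count is the number of grid cells intersecting the
    hull at the resolution chosen to approximate the target.
    """
    lon = np.asarray(lon, dtype=float).ravel()
    lat = np.asarray(lat, dtype=float).ravel()
    pts = np.column_stack([lon, lat])
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < n_knots:
        raise ValueError(
            f"need at least n_knots={n_knots} distinct locations, got {distinct.shape[0]}")
    proj = LocalProjection(float(lon.mean()), float(lat.mean()))
    xy = proj.to_km(lon, lat)

    if n_knots == 1:
        knots = xy.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=n_knots, n_init=10, random_state=seed)
        km.fit(xy)
        # sort centroids lexicographically for a reproducible, order-free mesh
        order = np.lexsort((km.cluster_centers_[:, 1], km.cluster_centers_[:, 0]))
        knots = km.cluster_centers_[order]

    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if hull.area <= 0:
        raise ValueError("degenerate (collinear) locations: empty hull")
    size = np.sqrt(hull.area / n_cells)
    x0, y0, x1, y1 = hull.bounds
    nx = max(1, int(np.ceil((x1 - x0) / size)))
    ny = max(1, int(np.ceil((y1 - y0) / size)))
    xs = x0 + size * np.arange(nx)
    ys = y0 + size * np.arange(ny)
    centers, areas = [], []
    for yi in ys:
        for xi in xs:
            cell = box(xi, yi, xi + size, yi + size)
            a = cell.intersection(hull).area
            if a > 0:
                centers.append((xi + size / 2, yi + size / 2))
                areas.append(a)
    cells_xy = np.asarray(centers)
    areas = np.asarray(areas)
    _, cell_knot = cKDTree(knots).query(cells_xy)
    return SpatialMesh(projection=proj, knots_xy=knots, cells_xy=cells_xy,
                       cell_area_km2=areas, cell_knot=cell_knot)


@dataclass(frozen=True)
class KernelParams:
    """Matern (smoothness 1) kernel parameters.

    ``range_km`` is the scale parameter rho of C(d) = variance*(d/rho)*K1(d/rho);
    the practical decorrelation distance (correlation ~0.1) is roughly
    sqrt(8)*rho, the usual SPDE "range" convention.
    """

    range_km: float
    variance: float = 1.0

    def __post_init__(self):
        if self.range_km <= 0 or self.variance < 0:
            raise ValueError("range_km must be > 0 and variance >= 0")


def matern_covariance(distances: np.ndarray, params: KernelParams) -> np.ndarray:
    """Matern smoothness-1 covariance matrix from a distance matrix (km)."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if d.ndim == 2:
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
    u = d / params.range_km
    with np.errstate(invalid="ignore", over="ignore"):
        c = u * kv(1, u)
    c = np.where(u == 0, 1.0, c)
    c = np.where(np.isfinite(c), c, 0.0)  # kv underflows to 0 at huge u
    return params.variance * c


_JITTER_START = 1e-8
_JITTER_MAX = 1e-4


def _chol_with_jitter(cov: np.ndarray, variance: float) -> np.ndarray:
    """Cholesky factor with the bounded diagonal-jitter repair policy."""
    scale = variance if variance > 0 else 1.0
    jitter = 0.0
    while True:
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            jitter = _JITTER_START * scale if jitter == 0 else jitter * 10
            if jitter > _JITTER_MAX * scale:
                raise np.linalg.LinAlgError(
                    "covariance not positive definite after jitter up to "
                    f"{_JITTER_MAX * scale:g}")


def simulate_grf(mesh: SpatialMesh, params: KernelParams, n_draws: int = 1,
                 seed: int = 0) -> np.ndarray:
    """Draw mean-zero Gaussian random fields at the mesh knots.

    Returns an (n_draws, n_knots) array; deterministic given ``seed``.
    """
    cov = matern_covariance(mesh.knot_distances(), params)
    if params.variance == 0:
        return np.zeros((n_draws, mesh.n_knots))
    chol = _chol_with_jitter(cov, params.variance)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((mesh.n_knots, n_draws))
    return (chol @ z).T
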