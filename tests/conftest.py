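"""Shared fixtures: one small synthetic world reused across test modules."""

import numpy as np
import pytest

from deltafield import (ModelConfig, TruthConfig, build_mesh, fit,
                        generate_covariate_fields, simulate_observations)
from deltafield.basis import CovariateBasis


@pytest.fixture(scope="session")
def small_truth():
    return TruthConfig(n_years=3, n_obs_per_year=300, n_vessels=6,
                       n_species=2, n_covariates=1, n_factors=1,
                       seed=11).resolve()


@pytest.fixture(scope="session")
def small_fields(small_truth):
    return generate_covariate_fields(small_truth)


@pytest.fixture(scope="session")
def small_mesh(small_truth):
    rng = np.random.default_rng(11)
    lon = rng.uniform(small_truth.lon_min, small_truth.lon_max, 2000)
    lat = rng.uniform(small_truth.lat_min, small_truth.lat_max, 2000)
    return build_mesh(lon, lat, n_knots=20, n_cells=150, seed=11)


@pytest.fixture(scope="session")
def small_obs(small_truth, small_mesh, small_fields):
    return simulate_observations(small_truth, small_mesh, small_fields)


@pytest.fixture(scope="session")
def small_basis(small_truth, small_fields):
    X = small_fields
    return CovariateBasis(kind=small_truth.basis).fit(
        X.values.reshape(-1, X.n_cov), names=X.names)


@pytest.fixture(scope="session")
def small_fit(small_obs, small_mesh, small_fields, small_basis):
    """One fully converged small fit shared by several tests."""
    X = small_fields
    Xh = X.at(small_obs["lon"].to_numpy(), small_obs["lat"].to_numpy(),
              small_obs["year"].to_numpy())
    return fit(small_obs, small_mesh, Xh,
               ModelConfig(n_factors=1, label="full"),
               basis=small_basis, check_hessian=True)
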