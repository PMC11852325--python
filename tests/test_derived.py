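"""Derived spatial summaries: abundance index, biomass-weighted density,
center of gravity, prediction and scenario projection."""

import numpy as np
import pytest

from deltafield import (DensityField, KernelParams, LocalProjection,
                        ParameterSet, RandomEffects, SpatialMesh,
                        abundance_index, center_of_gravity, poisson_link,
                        predict_density, project_scenario, weighted_density)
from deltafield.derived import derived_summary


def grid_mesh(xs, ys, areas=None):
    """Small handmade mesh with explicit cell coordinates (projected km)."""
    proj = LocalProjection(120.0, 35.0)
    cells = np.array([(x, y) for y in ys for x in xs], dtype=float)
    n = len(cells)
    areas = np.ones(n) if areas is None else np.asarray(areas, float)
    return SpatialMesh(projection=proj, knots_xy=cells[:1].copy(),
                       cells_xy=cells, cell_area_km2=areas,
                       cell_knot=np.zeros(n, dtype=int))


def field_from(d, mesh, species=None):
    d = np.asarray(d, dtype=float)
    if d.ndim == 1:
        d = d[:, None, None]
    C, T = d.shape[1], d.shape[2]
    return DensityField(d=d, mesh=mesh,
                        species=species or [f"sp{c}" for c in range(C)],
                        times=list(range(T)))


class TestHandCases:
    def test_two_cell_abundance_index(self):
        # a = (2, 3) km^2, d = (1, 2) kg/km^2 -> I = 8 kg
        mesh = grid_mesh([0.0, 10.0], [0.0], areas=[2.0, 3.0])
        f = field_from([1.0, 2.0], mesh)
        assert abundance_index(f)[0, 0] == pytest.approx(8.0, abs=1e-12)

    def test_two_cell_weighted_density(self):
        # D = (2*1^2 + 3*2^2)/8 = 1.75
        mesh = grid_mesh([0.0, 10.0], [0.0], areas=[2.0, 3.0])
        f = field_from([1.0, 2.0], mesh)
        assert weighted_density(f)[0, 0] == pytest.approx(1.75, abs=1e-12)

    def test_two_cell_cog(self):
        # x = (0, 10), equal areas, d = (1, 3) -> Z_x = 7.5
        mesh = grid_mesh([0.0, 10.0], [0.0])
        f = field_from([1.0, 3.0], mesh)
        Z, _ = center_of_gravity(f)
        assert Z[0, 0, 0] == pytest.approx(7.5, abs=1e-12)

    def test_point_mass_cog_is_that_cell(self):
        mesh = grid_mesh([0.0, 5.0, 10.0], [0.0, 4.0])
        d = np.zeros(6)
        d[4] = 3.3
        Z, _ = center_of_gravity(field_from(d, mesh))
        assert np.allclose(Z[0, 0], mesh.cells_xy[4])

    def test_symmetric_uniform_cog_is_center(self):
        mesh = grid_mesh([0.0, 2.0], [0.0, 2.0])
        Z, _ = center_of_gravity(field_from(np.ones(4), mesh))
        assert np.allclose(Z[0, 0], [1.0, 1.0])

    def test_zero_field_gives_zero_index_and_missing_summaries(self):
        mesh = grid_mesh([0.0, 1.0], [0.0])
        f = field_from([0.0, 0.0], mesh)
        assert abundance_index(f)[0, 0] == 0.0
        assert np.isnan(weighted_density(f)[0, 0])
        assert np.all(np.isnan(center_of_gravity(f)[0][0, 0]))


@pytest.fixture()
def random_field():
    rng = np.random.default_rng(8)
    mesh = grid_mesh(np.arange(6.0), np.arange(5.0),
                     areas=rng.uniform(0.5, 2.0, 30))
    d = rng.gamma(1.5, 1.0, size=(30, 3, 2))
    return field_from(d, mesh)


class TestProperties:

    def test_linear_algebra_matches_brute_force_loops(self, random_field):
        f = random_field
        I = abundance_index(f)
        D = weighted_density(f)
        Z, _ = center_of_gravity(f)
        a = f.mesh.cell_area_km2
        for c in range(3):
            for t in range(2):
                I_bf = sum(a[s] * f.d[s, c, t] for s in range(30))
                D_bf = sum(a[s] * f.d[s, c, t] / I_bf * f.d[s, c, t]
                           for s in range(30))
                Zx_bf = sum(f.mesh.cells_xy[s, 0] * a[s] * f.d[s, c, t]
                            for s in range(30)) / I_bf
                assert abs(I[c, t] - I_bf) < 1e-10 * I_bf
                assert abs(D[c, t] - D_bf) < 1e-10 * D_bf
                assert abs(Z[c, t, 0] - Zx_bf) < 1e-10 * max(abs(Zx_bf), 1)

    def test_doubling_areas_doubles_index(self, random_field):
        f = random_field
        mesh2 = grid_mesh(np.arange(6.0), np.arange(5.0),
                          areas=2 * f.mesh.cell_area_km2)
        f2 = field_from(f.d, mesh2)
        assert np.allclose(abundance_index(f2), 2 * abundance_index(f))

    def test_cog_invariant_to_uniform_scaling(self, random_field):
        f = random_field
        Z1, _ = center_of_gravity(f)
        Z2, _ = center_of_gravity(field_from(2 * f.d, f.mesh))
        assert np.allclose(Z1, Z2)

    def test_weighted_density_at_least_mean_density(self, random_field):
        # Cauchy-Schwarz: biomass-weighted mean >= area-weighted mean
        f = random_field
        D = weighted_density(f)
        a = f.mesh.cell_area_km2
        mean_d = np.einsum("s,sct->ct", a, f.d) / a.sum()
        assert np.all(D >= mean_d - 1e-12)
        # equality iff the field is constant
        fc = field_from(np.full((30, 1, 1), 1.7), f.mesh)
        assert weighted_density(fc)[0, 0] == pytest.approx(1.7, abs=1e-12)


class TestPredictDensity:
    def test_intercept_only_constant_over_cells(self, small_mesh):
        params = ParameterSet(beta1=np.array([[0.1, 0.4]]),
                              beta2=np.array([[1.0, 0.2]]),
                              sigma2=np.array([1.0]))
        f = predict_density(params, small_mesh)
        assert np.allclose(f.d, f.d[:1, :, :])
        assert f.d.shape == (small_mesh.n_cells, 1, 2)

    def test_density_composes_poisson_link(self):
        mesh = grid_mesh([0.0, 1.0, 2.0, 3.0], [0.0])
        params = ParameterSet(beta1=np.array([[0.3]]),
                              beta2=np.array([[0.7]]),
                              sigma2=np.array([1.0]))
        f = predict_density(params, mesh)
        r1, r2 = poisson_link(0.3, 0.7, 1.0)
        assert np.allclose(f.d, r1 * r2)

    def test_raising_beta2_multiplies_density(self, small_mesh):
        base = ParameterSet(beta1=np.array([[0.1]]), beta2=np.array([[0.5]]),
                            sigma2=np.array([1.0]))
        up = ParameterSet(beta1=np.array([[0.1]]), beta2=np.array([[1.2]]),
                          sigma2=np.array([1.0]))
        f0 = predict_density(base, small_mesh)
        f1 = predict_density(up, small_mesh)
        assert np.allclose(f1.d, f0.d * np.exp(0.7))

    def test_missing_covariate_cells_error(self, small_mesh):
        basis = (__import__("deltafield").CovariateBasis)(
            kind="linear", means=np.zeros(1), sds=np.ones(1), names=["sst"])
        params = ParameterSet(beta1=np.zeros((1, 1)), beta2=np.zeros((1, 1)),
                              gamma1=np.array([[0.5]]),
                              gamma2=np.array([[0.1]]),
                              sigma2=np.array([1.0]), basis_spec=basis)
        X = np.full((small_mesh.n_cells, 1, 1), np.nan)
        X[0] = 1.0
        with pytest.raises(ValueError, match="cells"):
            predict_density(params, small_mesh, X, times=[0])


class TestProjectScenario:
    def make_params(self, gamma1=0.6):
        basis = (__import__("deltafield").CovariateBasis)(
            kind="linear", means=np.zeros(1), sds=np.ones(1), names=["sst"])
        return ParameterSet(beta1=np.full((1, 2), 0.2),
                            beta2=np.full((1, 2), 0.5),
                            gamma1=np.array([[gamma1]]),
                            gamma2=np.array([[0.0]]),
                            sigma2=np.array([1.0]), basis_spec=basis)

    def test_identity_scenario_equals_zero_effect_prediction(self, small_mesh):
        params = self.make_params()
        rng = np.random.default_rng(0)
        X = rng.normal(size=(small_mesh.n_cells, 1, 1))
        f_proj, _ = project_scenario(params, small_mesh, X)
        f_pred = predict_density(params, small_mesh, X, times=["t0"],
                                 use_random_effects=False)
        assert np.allclose(f_proj.d, f_pred.d)

    def test_zero_coefficients_are_scenario_invariant(self, small_mesh):
        params = self.make_params(gamma1=0.0)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(small_mesh.n_cells, 1, 1))
        f0, _ = project_scenario(params, small_mesh, X)
        f1, _ = project_scenario(params, small_mesh, X + 2.0)
        assert np.allclose(f0.d, f1.d)

    def test_positive_coefficient_warming_raises_abundance(self, small_mesh):
        params = self.make_params(gamma1=0.6)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(small_mesh.n_cells, 1, 1))
        _, s0 = project_scenario(params, small_mesh, X)
        _, s1 = project_scenario(params, small_mesh, X + 1.0)
        assert s1.I[0, 0] > s0.I[0, 0]

    def test_latitudinal_gradient_warming_shifts_cog_north(self, small_mesh):
        """Density follows a south-warm covariate; uniform warming pushes the
        covariate optimum north.  The projected COG shift must match the
        independently computed centroid of the generative density."""
        basis = (__import__("deltafield").CovariateBasis)(
            kind="quadratic", means=np.zeros(1), sds=np.ones(1), names=["sst"])
        params = ParameterSet(beta1=np.zeros((1, 1)), beta2=np.zeros((1, 1)),
                              gamma1=np.array([[0.0, -0.5]]),
                              gamma2=np.array([[0.0, 0.0]]),
                              sigma2=np.array([1.0]), basis_spec=basis)
        lat = small_mesh.cells_lonlat[:, 1]
        sst = -(lat - lat.mean()) / lat.std()  # warm south, standardized
        X = sst[:, None, None]
        a = small_mesh.cell_area_km2
        y = small_mesh.cells_xy[:, 1]

        def oracle_cog(x):
            d = np.exp(-0.5 * (x ** 2).ravel())  # independent hand expression
            return (y * a * d).sum() / (a * d).sum()

        _, s0 = project_scenario(params, small_mesh, X)
        _, s1 = project_scenario(params, small_mesh, X + 1.0)
        shift = s1.Z_km[0, 0, 1] - s0.Z_km[0, 0, 1]
        expected = oracle_cog(X + 1.0) - oracle_cog(X)
        assert shift > 0
        assert shift == pytest.approx(expected, rel=1e-10)


def test_summary_frame_roundtrip(small_mesh):
    params = ParameterSet(beta1=np.array([[0.1]]), beta2=np.array([[0.4]]),
                          sigma2=np.array([1.0]))
    f = predict_density(params, small_mesh)
    s = derived_summary(f)
    frame = s.to_frame()
    assert len(frame) == 1
    assert frame["abundance_index_kg"].iloc[0] == pytest.approx(
        abundance_index(f)[0, 0])
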