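"""Delta-GLMM estimation tests: linear predictors, closed-form fit oracles,
species correlations, model selection bookkeeping, and the VIF screen."""

import numpy as np
import pandas as pd
import pytest

from deltafield import (CovariateBasis, KernelParams, ModelConfig,
                        ModelSummary, ParameterSet, RandomEffects, fit,
                        linear_predictors, model_selection,
                        species_correlations, vif_screen)


def three_obs_table():
    return pd.DataFrame({
        "lon": [117.5, 118.0, 118.5], "lat": [31.0, 32.0, 33.0],
        "year": [2012, 2012, 2013], "vessel": [0, 1, 0],
        "gear": ["OTB", "OTB", "OTB"], "area_swept_km2": [1.0, 1.0, 1.0],
        "species": ["sp01", "sp01", "sp01"], "catch_kg": [0.0, 1.0, 2.0]})


@pytest.fixture(scope="module")
def tiny_mesh():
    from deltafield import build_mesh

    rng = np.random.default_rng(0)
    return build_mesh(rng.uniform(117, 119, 50), rng.uniform(30, 34, 50),
                      n_knots=3, n_cells=12, seed=0)


class TestLinearPredictors:
    def test_intercept_only(self, tiny_mesh):
        params = ParameterSet(beta1=np.array([[0.3, -0.2]]),
                              beta2=np.array([[1.0, 0.5]]),
                              sigma2=np.array([1.0]))
        p1, p2 = linear_predictors(params, RandomEffects(), tiny_mesh, None,
                                   three_obs_table())
        assert np.allclose(p1, [0.3, 0.3, -0.2])
        assert np.allclose(p2, [1.0, 1.0, 0.5])

    def test_hand_sum_with_linear_covariate(self, tiny_mesh):
        # p1 = beta1 + gamma1 * (x - mean)/sd, computed by hand
        basis = CovariateBasis(kind="linear", means=np.array([10.0]),
                               sds=np.array([2.0]), names=["sst"])
        params = ParameterSet(beta1=np.array([[0.3, -0.2]]),
                              beta2=np.array([[1.0, 0.5]]),
                              gamma1=np.array([[0.8]]),
                              gamma2=np.array([[-0.4]]),
                              sigma2=np.array([1.0]), basis_spec=basis)
        x = np.array([[8.0], [10.0], [14.0]])
        p1, p2 = linear_predictors(params, RandomEffects(), tiny_mesh, x,
                                   three_obs_table())
        z = (x.ravel() - 10.0) / 2.0
        assert np.allclose(p1, np.array([0.3, 0.3, -0.2]) + 0.8 * z)
        assert np.allclose(p2, np.array([1.0, 1.0, 0.5]) - 0.4 * z)

    def test_vessel_effect_shifts_its_records_exactly(self, tiny_mesh):
        params = ParameterSet(beta1=np.zeros((1, 2)), beta2=np.zeros((1, 2)),
                              vessel_sd1=0.5, sigma2=np.array([1.0]))
        eta1 = np.zeros((2, 1))
        base_p1, _ = linear_predictors(
            params, RandomEffects(eta1=eta1.copy()), tiny_mesh, None,
            three_obs_table())
        eta1[1, 0] = 0.5
        p1, _ = linear_predictors(params, RandomEffects(eta1=eta1), tiny_mesh,
                                  None, three_obs_table())
        assert np.allclose(p1 - base_p1, [0.0, 0.5, 0.0])

    def test_unmapped_level_raises(self, tiny_mesh):
        params = ParameterSet(beta1=np.zeros((1, 1)), beta2=np.zeros((1, 1)),
                              sigma2=np.array([1.0]))
        with pytest.raises(KeyError):
            linear_predictors(params, RandomEffects(), tiny_mesh, None,
                              three_obs_table())  # two years, one beta column


class TestFitOracles:
    def test_intercept_only_matches_closed_form_mle(self, tiny_mesh):
        # iid data, unit area: the Poisson-link MLE reparameterizes the
        # (encounter rate, mean positive catch) MLE
        rng = np.random.default_rng(7)
        n = 4000
        p_true, mean_pos = 0.45, 2.5
        enc = rng.uniform(size=n) < p_true
        catch = np.where(enc, rng.gamma(2.0, mean_pos / 2.0, n), 0.0)
        obs = pd.DataFrame({
            "lon": rng.uniform(117, 119, n), "lat": rng.uniform(30, 34, n),
            "year": 2012, "vessel": 0, "gear": "OTB",
            "area_swept_km2": 1.0, "species": "sp01", "catch_kg": catch})
        cfg = ModelConfig(spatiotemporal=False, vessel=False)
        m = fit(obs, tiny_mesh, None, cfg, check_hessian=False)
        p_hat = enc.mean()
        lam_hat = -np.log1p(-p_hat)
        beta1_expected = np.log(lam_hat)
        r2_hat = catch[enc].mean()
        beta2_expected = np.log(r2_hat * p_hat / lam_hat)
        assert m.params.beta1[0, 0] == pytest.approx(beta1_expected, abs=1e-6)
        assert m.params.beta2[0, 0] == pytest.approx(beta2_expected, abs=1e-6)

    def test_refit_from_optimum_is_fixed_point(self, small_fit, small_obs,
                                               small_mesh, small_fields,
                                               small_basis):
        X = small_fields
        Xh = X.at(small_obs["lon"].to_numpy(), small_obs["lat"].to_numpy(),
                  small_obs["year"].to_numpy())
        again = fit(small_obs, small_mesh, Xh, ModelConfig(n_factors=1),
                    basis=small_basis, init_theta=small_fit.theta,
                    check_hessian=False)
        assert abs(again.loglik - small_fit.loglik) < 1e-6

    def test_all_zero_species_raises_with_name(self, tiny_mesh):
        obs = three_obs_table()
        obs["catch_kg"] = 0.0
        with pytest.raises(ValueError, match="sp01"):
            fit(obs, tiny_mesh, None, ModelConfig(spatiotemporal=False,
                                                  vessel=False))


class TestOptionalComponents:
    @pytest.mark.parametrize("kwargs", [
        {"spatial": True},                 # time-constant omega fields
        {"spatially_varying_coef": True},  # xi* coefficient fields
        {"gear": True},                    # fixed gear catchability on p2
        {"basis": "bspline"},
    ], ids=["omega", "svc", "gear", "bspline"])
    def test_configurable_components_fit_and_report(self, kwargs, small_obs,
                                                    small_mesh, small_fields):
        X = small_fields
        Xh = X.at(small_obs["lon"].to_numpy(), small_obs["lat"].to_numpy(),
                  small_obs["year"].to_numpy())
        cfg = ModelConfig(n_factors=1, **kwargs)
        m = fit(small_obs, small_mesh, Xh, cfg, check_hessian=False,
                gtol=1e-3)
        assert np.isfinite(m.loglik)
        assert m.max_abs_gradient < 1e-2
        if kwargs.get("spatial"):
            assert m.params.L1_omega is not None
        if kwargs.get("spatially_varying_coef"):
            assert m.params.sigma_xi1 is not None
            assert np.all(m.params.sigma_xi1 > 0)
        if kwargs.get("gear"):
            assert "gear" in m.se


class TestSpeciesCorrelations:
    def test_identity_loadings_give_identity(self):
        assert np.allclose(species_correlations(np.eye(3)), np.eye(3))

    def test_rank_one_shared_factor(self):
        assert species_correlations(np.array([[1.0], [2.0]]))[0, 1] == \
            pytest.approx(1.0)
        assert species_correlations(np.array([[1.0], [-2.0]]))[0, 1] == \
            pytest.approx(-1.0)

    def test_zero_row_returns_missing_not_zero(self):
        corr = species_correlations(np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert np.isnan(corr[0, 1]) and np.isnan(corr[1, 1])
        assert corr[0, 0] == 1.0

    def test_monte_carlo_oracle(self):
        L = np.array([[0.6, 0.0], [0.2, 0.7], [-0.5, 0.3]])
        rng = np.random.default_rng(5)
        draws = rng.standard_normal((10000, 2)) @ L.T
        emp = np.corrcoef(draws.T)
        assert np.allclose(emp, species_correlations(L),
                           atol=3 / np.sqrt(10000) * 1.5)


class TestModelSelection:
    def test_aic_arithmetic(self):
        models = [ModelSummary("a", loglik=-10.0, k=3, fingerprint="x"),
                  ModelSummary("b", loglik=-9.0, k=5, fingerprint="x")]
        tab = model_selection(models)
        a = tab.set_index("model")
        assert a.loc["a", "AIC"] == pytest.approx(26.0)
        assert a.loc["b", "AIC"] == pytest.approx(28.0)
        assert a.loc["a", "dAIC"] == 0.0
        assert a.loc["b", "dAIC"] == pytest.approx(2.0)

    def test_aic_ordering_invariant_to_loglik_shift(self):
        rng = np.random.default_rng(2)
        lls = rng.normal(-500, 30, 5)
        ks = rng.integers(2, 10, 5)
        base = model_selection([ModelSummary(f"m{i}", ll, int(k), "f")
                                for i, (ll, k) in enumerate(zip(lls, ks))])
        shifted = model_selection([ModelSummary(f"m{i}", ll + 123.4, int(k), "f")
                                   for i, (ll, k) in enumerate(zip(lls, ks))])
        assert list(base["model"]) == list(shifted["model"])
        assert np.allclose(base["dAIC"], shifted["dAIC"])

    def test_percent_deviance_explained_against_null(self):
        null = ModelSummary("null", loglik=-100.0, k=2, fingerprint="x")
        m = ModelSummary("m", loglik=-80.0, k=4, fingerprint="x")
        tab = model_selection([m, null], null_model=null)
        pct = tab.set_index("model").loc["m", "pct_deviance_explained"]
        assert pct == pytest.approx(100 * (1 - 160.0 / 200.0))

    def test_mismatched_fingerprints_raise(self):
        models = [ModelSummary("a", -10.0, 3, "x"),
                  ModelSummary("b", -9.0, 3, "y")]
        with pytest.raises(ValueError, match="different data"):
            model_selection(models)


class TestVifScreen:
    def test_orthogonal_columns_all_retained_with_unit_vif(self):
        rng = np.random.default_rng(0)
        # mutually orthogonal AND orthogonal to the intercept
        q, _ = np.linalg.qr(np.column_stack([np.ones(200),
                                             rng.normal(size=(200, 3))]))
        res = vif_screen(q[:, 1:], names=["a", "b", "c"])
        assert res.retained == ["a", "b", "c"]
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in res.vif.values())

    def test_duplicated_column_is_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 2))
        X = np.column_stack([x, x[:, 0]])
        res = vif_screen(X, names=["a", "b", "a_copy"])
        assert len(res.dropped) == 1
        assert res.dropped[0] in ("a", "a_copy")
        assert all(v < 10 for v in res.vif.values())

    def test_known_correlation_vif_hand_computation(self):
        rng = np.random.default_rng(3)
        n = 100000
        z = rng.standard_normal(n)
        x1 = z
        x2 = 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        x3 = rng.standard_normal(n)
        X = np.column_stack([x1, x2, x3])
        res = vif_screen(X, names=["x1", "x2", "x3"], threshold=100.0)
        # regress x1 on (x2, x3) by hand: VIF = 1/(1 - R^2)
        A = np.column_stack([np.ones(n), x2, x3])
        coef, *_ = np.linalg.lstsq(A, x1, rcond=None)
        resid = x1 - A @ coef
        r2 = 1 - resid.var() / x1.var()
        assert res.vif["x1"] == pytest.approx(1 / (1 - r2), abs=1e-8)

    def test_constant_column_raises(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="constant"):
            vif_screen(X)
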