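"""Synthetic-data generator tests against closed-form expectations."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from deltafield import (TruthConfig, build_mesh, generate_covariate_fields,
                        make_scenario, simulate_observations)


class TestCovariateFields:
    def test_seeded_reproducibility(self, small_truth):
        a = generate_covariate_fields(small_truth)
        b = generate_covariate_fields(small_truth)
        assert np.array_equal(a.values, b.values)

    def test_zero_anomaly_gives_time_constant_fields(self, small_truth):
        cfg = replace(small_truth, anomaly_amplitude=0.0)
        X = generate_covariate_fields(cfg)
        assert np.allclose(X.values, X.values[:, :1, :])

    def test_standardized_to_unit_moments(self, small_fields):
        flat = small_fields.values.reshape(-1, small_fields.n_cov)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(flat.std(axis=0), 1.0, atol=1e-12)

    def test_empty_grid_raises(self):
        cfg = TruthConfig(lon_min=117.0, lon_max=117.1, lat_min=30.0,
                          lat_max=30.1, covariate_deg=0.25)
        with pytest.raises(ValueError, match="empty covariate grid"):
            generate_covariate_fields(cfg)


class TestMakeScenario:
    def test_zero_shift_is_identity(self, small_fields):
        out = make_scenario(small_fields, np.zeros(small_fields.n_cov))
        assert np.array_equal(out.values, small_fields.values)

    def test_shift_moves_mean_exactly(self, small_fields):
        shift = np.zeros(small_fields.n_cov)
        shift[0] = 2.0
        out = make_scenario(small_fields, shift)
        delta = out.values.mean(axis=(0, 1)) - small_fields.values.mean(axis=(0, 1))
        assert delta[0] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(delta[1:], 0.0, atol=1e-12)

    def test_shift_then_inverse_recovers_input(self, small_fields):
        shift = np.full(small_fields.n_cov, 0.7)
        back = make_scenario(make_scenario(small_fields, shift), -shift)
        assert np.allclose(back.values, small_fields.values, atol=1e-12)

    def test_shape_mismatch_raises(self, small_fields):
        with pytest.raises(ValueError):
            make_scenario(small_fields, np.zeros(small_fields.n_cov + 1))


class TestSimulateObservations:
    def test_seeded_determinism(self, small_truth, small_mesh, small_fields):
        a = simulate_observations(small_truth, small_mesh, small_fields)
        b = simulate_observations(small_truth, small_mesh, small_fields)
        pd.testing.assert_frame_equal(a, b)

    def test_schema_and_zero_catches_present(self, small_obs, small_truth):
        assert set(small_obs.columns) >= {"lon", "lat", "year", "vessel",
                                          "gear", "area_swept_km2", "species",
                                          "catch_kg"}
        n_hauls = small_truth.n_obs_per_year * small_truth.n_years
        assert len(small_obs) == n_hauls * small_truth.n_species
        assert (small_obs["catch_kg"] == 0).any()
        assert (small_obs["catch_kg"] > 0).any()
        assert (small_obs["catch_kg"] >= 0).all()

    def test_locations_snapped_to_half_degree_centers(self, small_obs,
                                                      small_truth):
        offs = (small_obs["lon"] - small_truth.lon_min) / small_truth.snap_deg
        assert np.allclose(offs % 1, 0.5, atol=1e-9)

    def test_deeply_negative_intercept_gives_all_zeros(self, small_truth,
                                                       small_mesh,
                                                       small_fields):
        cfg = replace(small_truth,
                      beta1=np.full_like(np.asarray(small_truth.beta1), -20.0))
        obs = simulate_observations(cfg, small_mesh, small_fields)
        assert (obs["catch_kg"] == 0).all()

    def test_encounter_frequency_matches_closed_form(self, small_mesh):
        # all random effects and covariates off: r1 = 1 - exp(-a exp(beta1))
        cfg = TruthConfig(n_years=1, n_obs_per_year=20000, n_vessels=1,
                          n_species=1, n_covariates=1, n_factors=1,
                          beta1=np.array([[-0.5]]), beta2=np.array([[1.0]]),
                          gamma1=np.zeros((1, 2)), gamma2=np.zeros((1, 2)),
                          loadings_epsilon=(np.zeros((1, 1)), np.zeros((1, 1))),
                          vessel_sd=0.0, gear_effect=0.0, seed=21)
        X = generate_covariate_fields(cfg)
        obs = simulate_observations(cfg, small_mesh, X)
        a = obs["area_swept_km2"].to_numpy()
        r1 = 1 - np.exp(-a * np.exp(-0.5))
        p_hat = (obs["catch_kg"] > 0).mean()
        p_exp = r1.mean()
        se = np.sqrt((r1 * (1 - r1)).sum()) / len(obs)
        assert abs(p_hat - p_exp) < 3 * se

    def test_positive_catch_mean_matches_r2(self, small_mesh):
        from deltafield import poisson_link

        cfg = TruthConfig(n_years=1, n_obs_per_year=20000, n_vessels=1,
                          n_species=1, n_covariates=1, n_factors=1,
                          beta1=np.array([[0.2]]), beta2=np.array([[0.8]]),
                          gamma1=np.zeros((1, 2)), gamma2=np.zeros((1, 2)),
                          loadings_epsilon=(np.zeros((1, 1)), np.zeros((1, 1))),
                          vessel_sd=0.0, gear_effect=0.0, gamma_cv=0.8,
                          seed=22)
        X = generate_covariate_fields(cfg)
        obs = simulate_observations(cfg, small_mesh, X)
        a = obs["area_swept_km2"].to_numpy()
        _, r2 = poisson_link(0.2, 0.8, a)
        pos = obs["catch_kg"] > 0
        expected = r2[pos.to_numpy()].mean()
        observed = obs.loc[pos, "catch_kg"].mean()
        se = observed * cfg.gamma_cv / np.sqrt(pos.sum())
        assert abs(observed - expected) < 3 * se

    def test_zero_fraction_monotone_in_beta1(self, small_mesh, small_fields,
                                             small_truth):
        fractions = []
        for b1 in (-2.0, -1.0, 0.0, 1.0):
            cfg = replace(small_truth,
                          beta1=np.full_like(np.asarray(small_truth.beta1), b1))
            obs = simulate_observations(cfg, small_mesh, small_fields)
            fractions.append((obs["catch_kg"] == 0).mean())
        assert all(a > b for a, b in zip(fractions, fractions[1:]))

    def test_nonfinite_parameter_raises(self, small_mesh, small_fields,
                                        small_truth):
        bad = np.asarray(small_truth.beta1, dtype=float).copy()
        bad[0, 0] = np.nan
        cfg = replace(small_truth, beta1=bad)
        with pytest.raises(FloatingPointError):
            simulate_observations(cfg, small_mesh, small_fields)

    def test_cross_species_field_correlation_matches_loadings(self):
        """Simulated log-density field correlations converge to the
        correlation implied by the loading matrix."""
        from deltafield import species_correlations

        L = np.array([[0.8, 0.0], [0.5, 0.4], [-0.3, 0.6]])
        rng = np.random.default_rng(0)
        n = 20000
        fields = rng.standard_normal((n, 2)) @ L.T
        emp = np.corrcoef(fields.T)
        expected = species_correlations(L)
        assert np.allclose(emp, expected, atol=3.5 / np.sqrt(n) * 3)
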