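"""End-to-end pipeline: simulate/load -> screen -> fit -> predict -> project
-> overlap, with a written manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as dfio
from .derived import derived_summary, predict_density, project_scenario
from .mesh import build_mesh
from .model import ModelConfig, ModelData, fit, model_selection, vif_screen
from .overlap import overlap_table
from .simulate import CovariateFields, TruthConfig, generate_covariate_fields, \
    make_scenario, simulate_observations

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``catch_csv``/``covariate_file`` point at input files, or
    ``simulate`` is true and a synthetic data set is generated from
    ``truth`` (scaled-down defaults).
    """

    output_dir: str = "deltafield_out"
    catch_csv: str | None = None
    covariate_file: str | None = None
    simulate: bool = True
    truth: dict = field(default_factory=dict)
    n_knots: int = 40
    n_cells: int = 400
    covariates: list = field(default_factory=lambda: ["sst", "chla", "scv"])
    vif_threshold: float = 10.0
    basis: str = "quadratic"
    n_factors: int | None = 2
    vessel: bool = True
    gear: bool = False
    spatial: bool = False
    scenarios: dict = field(default_factory=lambda: {
        "warm_2050": [1.0, 0.0, 0.0], "warm_2100": [2.0, 0.0, 0.0]})
    seed: int = 0
    check_hessian: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.vif_threshold <= 1:
            raise ValueError("VIF threshold must exceed 1")
        if self.n_knots > self.n_cells:
            raise ValueError("n_knots must not exceed n_cells")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _truth_from(config: RunConfig) -> TruthConfig:
    scaled = dict(n_years=4, n_obs_per_year=400, n_vessels=8,
                  n_covariates=len(config.covariates), seed=config.seed)
    scaled.update(config.truth)
    return TruthConfig(**scaled)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of the main artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- data -------------------------------------------------------
        stage = "data"
        if config.simulate:
            truth = _truth_from(config).resolve()
            X = generate_covariate_fields(truth)
            locs_rng = np.random.default_rng(truth.seed)
            pre_lon = locs_rng.uniform(truth.lon_min, truth.lon_max, 4000)
            pre_lat = locs_rng.uniform(truth.lat_min, truth.lat_max, 4000)
            mesh = build_mesh(pre_lon, pre_lat, n_knots=config.n_knots,
                              n_cells=config.n_cells, seed=config.seed)
            obs = simulate_observations(truth, mesh, X)
            dfio.write_catch_csv(obs, out / "catch.csv")
            dfio.write_covariates_csv(X, out / "covariates.csv")
        else:
            obs = dfio.read_catch_csv(config.catch_csv)
            X = dfio.read_covariates(config.covariate_file,
                                     names=config.covariates)
            mesh = build_mesh(obs["lon"], obs["lat"], n_knots=config.n_knots,
                              n_cells=config.n_cells, seed=config.seed)
        mesh.to_files(str(out / "mesh"))

        haul_X = X.at(obs["lon"].to_numpy(), obs["lat"].to_numpy(),
                      obs["year"].to_numpy())

        # ---- covariate screen -------------------------------------------
        stage = "screen"
        if haul_X.shape[1] >= 2:
            vif = vif_screen(haul_X, names=X.names,
                             threshold=config.vif_threshold)
        else:
            vif = None
        keep = [X.names.index(n) for n in (vif.retained if vif else X.names)]
        haul_X = haul_X[:, keep]
        cov_names = [X.names[j] for j in keep]
        logger.info("covariates retained: %s", cov_names)

        # ---- fit candidate models ---------------------------------------
        stage = "fit"
        base = ModelConfig(n_factors=config.n_factors, vessel=config.vessel,
                           gear=config.gear, spatial=config.spatial,
                           basis=config.basis)
        null_cfg = replace(base, spatiotemporal=False, vessel=False,
                           label="null")
        from .basis import CovariateBasis

        cov_basis = CovariateBasis(kind=config.basis).fit(
            X.values.reshape(-1, X.n_cov)[:, keep], names=cov_names)
        m_null = fit(obs, mesh, None, null_cfg,
                     check_hessian=config.check_hessian)
        m_full = fit(obs, mesh, haul_X, replace(base, label="full"),
                     basis=cov_basis, check_hessian=config.check_hessian)
        models = {"null": m_null, "full": m_full}
        table = model_selection(list(models.values()), null_model=m_null)
        dfio.write_selection_csv(table, out / "selection.csv")
        for name, m in models.items():
            dfio.write_fitted_json(m, out / f"fit_{name}.json")
        best = m_full if m_full.aic <= m_null.aic else m_null

        # ---- prediction and projection ----------------------------------
        stage = "predict"
        Xc = dfio.regrid_to_cells(X, mesh)[:, :, keep]
        field = predict_density(best, mesh, Xc,
                                times=list(range(len(X.years))))
        field.times = list(X.years)
        summary = derived_summary(field)
        fields = [field]
        summaries = [summary]
        stage = "project"
        for name, shift in config.scenarios.items():
            shift = np.asarray(shift, float)[keep]
            Xf = Xc + shift[None, None, :]
            f_s, s_s = project_scenario(best, mesh, Xf[:, -1:, :],
                                        times=[name], scenario=name)
            fields.append(f_s)
            summaries.append(s_s)

        # ---- overlap ----------------------------------------------------
        stage = "overlap"
        ov = overlap_table(fields)
        ov.to_csv(out / "overlap.csv", index=False)
        import pandas as pd

        pd.concat([s.to_frame() for s in summaries], ignore_index=True
                  ).to_csv(out / "summaries.csv", index=False)
        dfio.write_density_netcdf(fields, out / "density.nc")
        dfio.write_cog_geojson(summary, out / "cog_current.geojson")

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        import deltafield

        manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                    "seed": config.seed, "version": deltafield.__version__,
                    "covariates_retained": cov_names,
                    "models": {k: {"aic": m.aic, "loglik": m.loglik,
                                   "converged": m.converged}
                               for k, m in models.items()}}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return {"mesh": mesh, "models": models, "selection": table,
                "fields": fields, "summaries": summaries, "overlap": ov,
                "manifest": manifest}
    except Exception:
        logger.exception("pipeline failed at stage %r (partial outputs in %s)",
                         stage, out)
        raise
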