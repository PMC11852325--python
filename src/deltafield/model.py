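"""The multi-species Poisson-link delta-GLMM.

Model structure
---------------
Two linear predictors per record i (species c, year t, knot s, vessel v):

    p1_i = beta1(c,t) + omega1(s,c) + eps1(s,c,t) + eta1(v,c)
           + sum_p [gamma1(c,p) + sigma_xi1(c,p) * xi1(s,c,p)] * B_i(p)

and analogously p2, where B_i are covariate basis columns.  Interspecies
structure comes from loading matrices: eps_j(s,c,t) = sum_f L_j[c,f] *
u_j(f,t,s) with u_j standardized Matern-1 Gaussian random fields at the
knots, independent across factors and years.  Vessel effects are iid normal
catchability deviations.  Observations follow the Poisson-link delta-gamma
likelihood (see ``likelihood``).

Estimation
----------
Random effects are integrated out by the Laplace approximation.  The linear
fixed effects (temporal intercepts beta, covariate coefficients gamma, gear
effect) are *profiled*: they join the random effects in the inner Newton
optimization, while the log-determinant correction is taken over the
random-effect block only.  The outer optimizer (L-BFGS-B) therefore only
sees the variance-type parameters (loadings, kernel range, vessel SDs,
gamma dispersions), with central finite-difference gradients that reuse the
inner mode through a single warm-started Newton correction per perturbation.
Wald standard errors for the profiled fixed effects come from the inverse of
the full joint Hessian at the optimum, conditional on the variance
parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize

from .basis import CovariateBasis
from .likelihood import delta_gamma_nll
from .mesh import KernelParams, SpatialMesh, matern_covariance

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# configuration and parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Structural switches of the delta-GLMM.

    Defaults follow the applied setting: spatio-temporal factor fields on,
    purely spatial fields off, spatially varying covariate coefficients off,
    vessel catchability effects on, quadratic covariate basis, full-rank
    factors (n_factors=None means one factor per species).
    """

    n_factors: int | None = None
    spatiotemporal: bool = True
    spatial: bool = False
    spatially_varying_coef: bool = False
    vessel: bool = True
    gear: bool = False
    basis: str = "quadratic"
    estimate_range: bool = True
    range_init_km: float = 100.0
    label: str = "model"


@dataclass
class ParameterSet:
    """All top-level parameters of the delta-GLMM (link scale).

    Loading matrices are species x factor, lower-triangular with
    non-negative diagonal for identifiability.  ``sigma2`` is the gamma
    dispersion (squared CV of positive catches) per species.
    """

    beta1: np.ndarray
    beta2: np.ndarray
    L1_eps: np.ndarray | None = None
    L2_eps: np.ndarray | None = None
    L1_omega: np.ndarray | None = None
    L2_omega: np.ndarray | None = None
    kernel: KernelParams | None = None
    gamma1: np.ndarray | None = None
    gamma2: np.ndarray | None = None
    sigma_xi1: np.ndarray | None = None
    sigma_xi2: np.ndarray | None = None
    vessel_sd1: float = 0.0
    vessel_sd2: float = 0.0
    sigma2: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    gear2: float = 0.0
    basis_spec: CovariateBasis | None = None

    def validate(self) -> None:
        for name in ("L1_eps", "L2_eps", "L1_omega", "L2_omega"):
            L = getattr(self, name)
            if L is None:
                continue
            if not np.allclose(L, np.tril(L)):
                raise ValueError(f"{name} must be lower-triangular")
            if np.any(np.diag(L)[: min(L.shape)] < 0):
                raise ValueError(f"{name} diagonal must be non-negative")
        if self.vessel_sd1 < 0 or self.vessel_sd2 < 0:
            raise ValueError("vessel SDs must be non-negative")
        if np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("sigma2 must be strictly positive")


@dataclass
class RandomEffects:
    """Posterior modes (or simulated values) of the latent effects.

    Factor fields are indexed (factor, year, knot); omega (factor, knot);
    xi (species, basis column, knot); vessel effects (vessel, species).
    Missing components are treated as exactly zero.
    """

    u1: np.ndarray | None = None
    u2: np.ndarray | None = None
    omega1: np.ndarray | None = None
    omega2: np.ndarray | None = None
    xi1: np.ndarray | None = None
    xi2: np.ndarray | None = None
    eta1: np.ndarray | None = None
    eta2: np.ndarray | None = None


# ---------------------------------------------------------------------------
# observation-level data container
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("lon", "lat", "year", "vessel", "gear",
                    "area_swept_km2", "species", "catch_kg")


@dataclass
class ModelData:
    """Index-mapped observation table ready for likelihood evaluation."""

    c: np.ndarray
    t: np.ndarray
    v: np.ndarray
    k: np.ndarray
    a: np.ndarray
    b: np.ndarray
    gear01: np.ndarray
    B: np.ndarray               # covariate basis columns (n, P)
    species: list
    years: list
    vessels: list
    basis: CovariateBasis
    n_knots: int

    @property
    def n(self) -> int:
        return self.b.shape[0]

    @property
    def C(self) -> int:
        return len(self.species)

    @property
    def T(self) -> int:
        return len(self.years)

    @property
    def V(self) -> int:
        return len(self.vessels)

    @property
    def P(self) -> int:
        return self.B.shape[1]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.b).tobytes())
        h.update(np.ascontiguousarray(self.a).tobytes())
        h.update(np.ascontiguousarray(self.c).tobytes())
        return h.hexdigest()[:16]

    @classmethod
    def from_table(cls, obs: pd.DataFrame, mesh: SpatialMesh,
                   X_obs: np.ndarray | None, basis: CovariateBasis | None = None,
                   covariate_names=None, require_mixed: bool = True) -> "ModelData":
        missing = [c for c in REQUIRED_COLUMNS if c not in obs.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        species = sorted(obs["species"].unique().tolist())
        years = sorted(obs["year"].unique().tolist())
        vessels = sorted(obs["vessel"].unique().tolist())
        c = obs["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
        t = obs["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
        v = obs["vessel"].map({w: i for i, w in enumerate(vessels)}).to_numpy()
        k = mesh.assign_knot(obs["lon"].to_numpy(), obs["lat"].to_numpy())
        a = obs["area_swept_km2"].to_numpy(float)
        b = obs["catch_kg"].to_numpy(float)
        if np.any(b < 0):
            raise ValueError("negative catch in observation table")
        if np.any(a <= 0):
            raise ValueError("non-positive area swept in observation table")
        gears = sorted(obs["gear"].unique().tolist())
        gear01 = obs["gear"].map({g: i for i, g in enumerate(gears)}).to_numpy(float)
        if require_mixed:
            for i, s in enumerate(species):
                bs = b[c == i]
                if not np.any(bs > 0):
                    raise ValueError(f"species {s!r} has no encounters")
                if not np.any(bs == 0):
                    raise ValueError(f"species {s!r} has no zero catches")
        if X_obs is None:
            B = np.zeros((len(b), 0))
            basis = basis or CovariateBasis()
        else:
            X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
            if basis is None:
                basis = CovariateBasis().fit(X_obs, names=covariate_names)
            B = basis.expand(X_obs)
        return cls(c=c, t=t, v=v, k=k, a=a, b=b, gear01=gear01, B=B,
                   species=species, years=years, vessels=vessels,
                   basis=basis, n_knots=mesh.n_knots)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _tril_indices(C, F):
    rows, cols = np.tril_indices(C, k=0)
    keep = cols < F
    return rows[keep], cols[keep]


class _Layout:
    """Index bookkeeping for the inner vector z and outer vector theta."""

    def __init__(self, data: ModelData, config: ModelConfig):
        C, T, K, V, P = data.C, data.T, data.n_knots, data.V, data.P
        self.C, self.T, self.K, self.V, self.P = C, T, K, V, P
        self.F = 0 if not config.spatiotemporal else (config.n_factors or C)
        self.Fo = 0 if not config.spatial else (config.n_factors or C)
        self.svc = config.spatially_varying_coef and P > 0
        self.vessel = config.vessel and V > 0
        self.gear = config.gear

        # The spatio-temporal factor fields are laid out year-major:
        # z[t*2FK + (comp-1)*FK + f*K + k].  With no time-constant fields
        # (omega/xi off) the random-effect Hessian block is then
        # block-diagonal by year apart from the vessel border, which the
        # log-determinant computation exploits.
        self.n_field = 2 * self.F * T * K
        sizes = {}
        off = self.n_field
        for name, size in (
            ("om1", self.Fo * K), ("om2", self.Fo * K),
            ("xi1", C * P * K if self.svc else 0),
            ("xi2", C * P * K if self.svc else 0),
            ("eta1", V * C if self.vessel else 0),
            ("eta2", V * C if self.vessel else 0),
            ("beta1", C * T), ("beta2", C * T),
            ("gamma1", C * P), ("gamma2", C * P),
            ("gear", 1 if self.gear else 0),
        ):
            sizes[name] = (off, off + size)
            off += size
        self.z_slices = {k: slice(a, b) for k, (a, b) in sizes.items()}
        self.n_z = off
        self.n_random = sizes["eta2"][1]
        self.n_profiled = self.n_z - self.n_random
        # GRF blocks: contiguous K-sized slices with an iid standard prior
        self.grf_blocks = []
        for t in range(T):
            for comp in range(2):
                for f in range(self.F):
                    start = (t * 2 + comp) * self.F * K + f * K
                    self.grf_blocks.append(slice(start, start + K))
        for name in ("om1", "om2", "xi1", "xi2"):
            s = self.z_slices[name]
            for start in range(s.start, s.stop, K):
                self.grf_blocks.append(slice(start, start + K))
        self.any_grf = len(self.grf_blocks) > 0
        # year blocks for the fast log-determinant (fields only)
        self.year_blocks = [slice(t * 2 * self.F * K, (t + 1) * 2 * self.F * K)
                            for t in range(T)] if self.F else []
        self.fast_logdet = self.F > 0 and self.Fo == 0 and not self.svc

        # outer theta layout
        self.tril = _tril_indices(C, self.F) if self.F else (np.array([], int),) * 2
        self.tril_o = _tril_indices(C, self.Fo) if self.Fo else (np.array([], int),) * 2
        n_load = len(self.tril[0])
        n_load_o = len(self.tril_o[0])
        t_off, t_sizes = 0, {}
        for name, size in (
            ("L1", n_load), ("L2", n_load),
            ("Lom1", n_load_o), ("Lom2", n_load_o),
            ("log_sxi1", C * P if self.svc else 0),
            ("log_sxi2", C * P if self.svc else 0),
            ("log_range", 1 if (self.any_grf and config.estimate_range) else 0),
            ("log_sdv1", 1 if self.vessel else 0),
            ("log_sdv2", 1 if self.vessel else 0),
            ("log_sigma2", C),
        ):
            t_sizes[name] = (t_off, t_off + size)
            t_off += size
        self.theta_slices = {k: slice(a, b) for k, (a, b) in t_sizes.items()}
        self.n_theta = t_off
        # which theta entries change the design values / the kernel prior
        self.theta_affects_J = np.zeros(t_off, dtype=bool)
        for name in ("L1", "L2", "Lom1", "Lom2", "log_sxi1", "log_sxi2"):
            self.theta_affects_J[self.theta_slices[name]] = True
        self.theta_affects_R = np.zeros(t_off, dtype=bool)
        self.theta_affects_R[self.theta_slices["log_range"]] = True

    def u_cols(self, comp: int, t: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Columns of the factor-field entries for records (t, k): (n, F)."""
        FK = self.F * self.K
        base = (t * 2 + (comp - 1)) * FK + k
        return base[:, None] + np.arange(self.F)[None, :] * self.K


@dataclass
class _Theta:
    L1: np.ndarray
    L2: np.ndarray
    Lom1: np.ndarray
    Lom2: np.ndarray
    sxi1: np.ndarray
    sxi2: np.ndarray
    range_km: float
    sdv1: float
    sdv2: float
    sigma2: np.ndarray


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DeltaGLMM:
    """Poisson-link delta-GLMM bound to one data set and one mesh."""

    def __init__(self, data: ModelData, mesh: SpatialMesh, config: ModelConfig):
        if config.spatiotemporal or config.spatial or config.spatially_varying_coef:
            if mesh.n_knots != data.n_knots:
                raise ValueError("data was indexed against a different mesh")
        self.data = data
        self.mesh = mesh
        self.config = config
        self.layout = _Layout(data, config)
        self._knot_dist = mesh.knot_distances() if self.layout.any_grf else None
        self._build_structure()
        self._z_warm = np.zeros(self.layout.n_z)

    # -- sparse design structure (fixed sparsity, theta-dependent values) ---
    def _build_structure(self):
        d, lay = self.data, self.layout
        n = d.n
        self._structures = {}
        for comp in (1, 2):
            comp_rows, comp_cols, comp_builders = [], [], []

            def addc(cols, builder):
                comp_rows.append(np.repeat(np.arange(n), cols.shape[1])
                                 if cols.ndim == 2 else np.arange(n))
                comp_cols.append(cols.ravel())
                comp_builders.append(builder)

            K, T, C, P = lay.K, lay.T, lay.C, lay.P
            if lay.F:
                addc(lay.u_cols(comp, d.t, d.k), ("load", comp))
            if lay.Fo:
                s = lay.z_slices[f"om{comp}"]
                cols = s.start + (np.arange(lay.Fo)[None, :] * K + d.k[:, None])
                addc(cols, ("load_om", comp))
            if lay.svc:
                s = lay.z_slices[f"xi{comp}"]
                cols = (s.start + ((d.c[:, None] * P + np.arange(P)[None, :]) * K
                                   + d.k[:, None]))
                addc(cols, ("xi", comp))
            if lay.vessel:
                s = lay.z_slices[f"eta{comp}"]
                addc((s.start + d.v * C + d.c)[:, None], ("one", comp))
            s = lay.z_slices[f"beta{comp}"]
            addc((s.start + d.c * T + d.t)[:, None], ("one", comp))
            if P:
                s = lay.z_slices[f"gamma{comp}"]
                cols = s.start + (d.c[:, None] * P + np.arange(P)[None, :])
                addc(cols, ("B", comp))
            if lay.gear and comp == 2:
                s = lay.z_slices["gear"]
                addc(np.full((n, 1), s.start), ("gear", comp))

            rows = np.concatenate(comp_rows)
            cols = np.concatenate(comp_cols)
            nvals = rows.shape[0]
            # template csr built once; a permutation maps builder order -> data
            template = sp.csr_matrix(
                (np.arange(nvals, dtype=float), (rows, cols)),
                shape=(n, lay.n_z))
            perm = template.data.astype(np.intp)
            rowidx = np.repeat(np.arange(n), np.diff(template.indptr))
            # restriction to the random-effect columns (for H_uu assembly)
            umask = cols < lay.n_random
            template_u = sp.csr_matrix(
                (np.arange(nvals, dtype=float)[umask],
                 (rows[umask], cols[umask])), shape=(n, lay.n_random))
            perm_u = template_u.data.astype(np.intp)
            rowidx_u = np.repeat(np.arange(n), np.diff(template_u.indptr))
            self._structures[comp] = {
                "template": template, "perm": perm, "rowidx": rowidx,
                "template_u": template_u, "perm_u": perm_u,
                "rowidx_u": rowidx_u, "builders": comp_builders}

    def _values_for(self, comp: int, th: _Theta) -> np.ndarray:
        d, lay = self.data, self.layout
        n = d.n
        parts = []
        for kind, _ in self._structures[comp]["builders"]:
            if kind == "load":
                L = th.L1 if comp == 1 else th.L2
                parts.append(L[d.c, :])
            elif kind == "load_om":
                L = th.Lom1 if comp == 1 else th.Lom2
                parts.append(L[d.c, :])
            elif kind == "xi":
                sx = th.sxi1 if comp == 1 else th.sxi2
                parts.append(sx[d.c, :] * d.B)
            elif kind == "one":
                parts.append(np.ones((n, 1)))
            elif kind == "B":
                parts.append(d.B)
            elif kind == "gear":
                parts.append(d.gear01[:, None])
        return np.concatenate([p.ravel() for p in parts])

    def _design(self, th: _Theta):
        """CSR design matrices J1, J2 with values for the given theta."""
        out = []
        for comp in (1, 2):
            st = self._structures[comp]
            J = st["template"].copy()
            vals = self._values_for(comp, th)
            J.data = vals[st["perm"]]
            out.append(J)
        return out

    # -- theta packing ------------------------------------------------------
    def unpack_theta(self, theta: np.ndarray) -> _Theta:
        lay, cfg = self.layout, self.config
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)):
            bad = [n for n, s in lay.theta_slices.items()
                   if not np.all(np.isfinite(theta[s]))]
            raise FloatingPointError(f"non-finite parameter(s): {bad}")
        C, P = lay.C, lay.P

        def mat(name, shape, tril):
            L = np.zeros(shape)
            if tril[0].size:
                L[tril] = theta[lay.theta_slices[name]]
            return L

        L1 = mat("L1", (C, lay.F), lay.tril) if lay.F else np.zeros((C, 0))
        L2 = mat("L2", (C, lay.F), lay.tril) if lay.F else np.zeros((C, 0))
        Lom1 = mat("Lom1", (C, lay.Fo), lay.tril_o) if lay.Fo else np.zeros((C, 0))
        Lom2 = mat("Lom2", (C, lay.Fo), lay.tril_o) if lay.Fo else np.zeros((C, 0))
        if lay.svc:
            sxi1 = np.exp(theta[lay.theta_slices["log_sxi1"]]).reshape(C, P)
            sxi2 = np.exp(theta[lay.theta_slices["log_sxi2"]]).reshape(C, P)
        else:
            sxi1 = np.zeros((C, P))
            sxi2 = np.zeros((C, P))
        if lay.any_grf and cfg.estimate_range:
            range_km = float(np.exp(theta[lay.theta_slices["log_range"]][0]))
        else:
            range_km = cfg.range_init_km
        sdv1 = float(np.exp(theta[lay.theta_slices["log_sdv1"]][0])) if lay.vessel else 0.0
        sdv2 = float(np.exp(theta[lay.theta_slices["log_sdv2"]][0])) if lay.vessel else 0.0
        sigma2 = np.exp(theta[lay.theta_slices["log_sigma2"]])
        return _Theta(L1, L2, Lom1, Lom2, sxi1, sxi2, range_km, sdv1, sdv2, sigma2)

    def pack_theta(self, params: ParameterSet) -> np.ndarray:
        lay = self.layout
        theta = np.zeros(lay.n_theta)
        if lay.F:
            theta[lay.theta_slices["L1"]] = params.L1_eps[lay.tril]
            theta[lay.theta_slices["L2"]] = params.L2_eps[lay.tril]
        if lay.Fo:
            theta[lay.theta_slices["Lom1"]] = params.L1_omega[lay.tril_o]
            theta[lay.theta_slices["Lom2"]] = params.L2_omega[lay.tril_o]
        if lay.svc:
            theta[lay.theta_slices["log_sxi1"]] = np.log(params.sigma_xi1).ravel()
            theta[lay.theta_slices["log_sxi2"]] = np.log(params.sigma_xi2).ravel()
        if lay.any_grf and self.config.estimate_range:
            theta[lay.theta_slices["log_range"]] = np.log(params.kernel.range_km)
        if lay.vessel:
            theta[lay.theta_slices["log_sdv1"]] = np.log(max(params.vessel_sd1, 1e-8))
            theta[lay.theta_slices["log_sdv2"]] = np.log(max(params.vessel_sd2, 1e-8))
        theta[lay.theta_slices["log_sigma2"]] = np.log(params.sigma2)
        return theta

    # -- prior pieces -------------------------------------------------------
    def _prior_setup(self, th: _Theta):
        """Inverse correlation and log-determinant of the knot GRF prior."""
        if not self.layout.any_grf:
            return None, 0.0
        R = matern_covariance(self._knot_dist, KernelParams(th.range_km, 1.0))
        jitter = 0.0
        K = R.shape[0]
        while True:
            try:
                cF = sla.cho_factor(R + jitter * np.eye(K), lower=True)
                break
            except sla.LinAlgError:
                jitter = 1e-8 if jitter == 0 else jitter * 10
                if jitter > 1e-4:
                    raise
        logdetR = 2.0 * np.log(np.diag(cF[0])).sum()
        Rinv = sla.cho_solve(cF, np.eye(K))
        return Rinv, logdetR

    def _prior_nll_grad(self, z, th, Rinv, logdetR, want_grad=True):
        lay = self.layout
        nll = 0.0
        grad = np.zeros_like(z) if want_grad else None
        if lay.any_grf:
            K = lay.K
            nb = len(lay.grf_blocks)
            U = np.vstack([z[s] for s in lay.grf_blocks])
            RU = U @ Rinv
            nll += 0.5 * float((U * RU).sum()) + nb * 0.5 * (logdetR + K * _LOG2PI)
            if want_grad:
                for i, s in enumerate(lay.grf_blocks):
                    grad[s] = RU[i]
        for name, sd in (("eta1", th.sdv1), ("eta2", th.sdv2)):
            if not lay.vessel:
                continue
            s = lay.z_slices[name]
            m = s.stop - s.start
            if sd <= 0:
                raise ValueError("vessel SD must be positive when vessel effects on")
            nll += 0.5 * float(z[s] @ z[s]) / sd ** 2 + m * (np.log(sd) + 0.5 * _LOG2PI)
            if want_grad:
                grad[s] = z[s] / sd ** 2
        return nll, grad

    def _prior_hess_diag_blocks(self, H, th, Rinv):
        """Add prior precision into the dense Hessian in place."""
        lay = self.layout
        if lay.any_grf:
            for s in lay.grf_blocks:
                H[s, s] += Rinv
        if lay.vessel:
            for name, sd in (("eta1", th.sdv1), ("eta2", th.sdv2)):
                s = lay.z_slices[name]
                idx = np.arange(s.start, s.stop)
                H[idx, idx] += 1.0 / sd ** 2
        return H

    # -- joint likelihood pieces -------------------------------------------
    def _predictors(self, J1, J2, z):
        p1 = J1 @ z
        p2 = J2 @ z
        if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
            raise FloatingPointError(
                "non-finite linear predictor; check intercepts/loadings")
        return p1, p2

    def _joint_nll(self, J1, J2, z, th, Rinv, logdetR):
        p1, p2 = self._predictors(J1, J2, z)
        nll = delta_gamma_nll(self.data.b, p1, p2, self.data.a,
                              th.sigma2[self.data.c])
        pr, _ = self._prior_nll_grad(z, th, Rinv, logdetR, want_grad=False)
        return float(nll.sum()) + pr

    def _joint_grad_hess(self, J1, J2, z, th, Rinv, logdetR, want_hess=True):
        d = self.data
        p1, p2 = self._predictors(J1, J2, z)
        nll, d1, d2, h11, h12, h22 = delta_gamma_nll(
            d.b, p1, p2, d.a, th.sigma2[d.c], derivatives=True)
        pr, prg = self._prior_nll_grad(z, th, Rinv, logdetR)
        f = float(nll.sum()) + pr
        g = J1.T @ d1 + J2.T @ d2 + prg
        if not want_hess:
            return f, g, None
        st1, st2 = self._structures[1], self._structures[2]
        J1s = J1.copy(); J1s.data = J1.data * h11[st1["rowidx"]]
        J2s = J2.copy(); J2s.data = J2.data * h22[st2["rowidx"]]
        J2x = J2.copy(); J2x.data = J2.data * h12[st2["rowidx"]]
        H = (J1.T @ J1s + J2.T @ J2s).toarray()
        Hx = (J1.T @ J2x).toarray()
        H += Hx + Hx.T
        self._prior_hess_diag_blocks(H, th, Rinv)
        return f, g, H

    # -- inner optimization -------------------------------------------------
    def _inner_newton(self, th, z0, Rinv, logdetR, tol=1e-8, max_iter=60):
        J1, J2 = self._design(th)
        z = z0.copy()
        f, g, H = self._joint_grad_hess(J1, J2, z, th, Rinv, logdetR)
        for _ in range(max_iter):
            if np.max(np.abs(g)) < tol:
                break
            cF = _chol_ridge(H)
            dz = -sla.cho_solve(cF, g, check_finite=False)
            step = 1.0
            for _ in range(30):
                f_new = self._joint_nll(J1, J2, z + step * dz, th, Rinv, logdetR)
                if f_new <= f + 1e-10 * abs(f):
                    break
                step *= 0.5
            else:
                raise RuntimeError(
                    "inner Newton line search failed; "
                    f"gradient max {np.max(np.abs(g)):.3g}, joint {f:.6g}")
            z = z + step * dz
            f, g, H = self._joint_grad_hess(J1, J2, z, th, Rinv, logdetR)
        else:
            raise RuntimeError(
                "inner Newton did not converge: "
                f"max|grad| = {np.max(np.abs(g)):.3g} after {max_iter} iterations")
        return z, f, g, H, (J1, J2)

    def _logdet_uu(self, Huu):
        """log det of the random-effect Hessian block.

        Fast path: with only spatio-temporal fields plus vessel effects,
        the field block is block-diagonal by year; the vessel border is
        eliminated by a Schur complement.  Falls back to a dense Cholesky.
        """
        lay = self.layout
        if lay.fast_logdet:
            try:
                nf = lay.n_field
                m = Huu.shape[0] - nf
                logdet = 0.0
                S = Huu[nf:, nf:].copy() if m else None
                for sl in lay.year_blocks:
                    cF = sla.cho_factor(Huu[sl, sl], lower=True,
                                        check_finite=False)
                    logdet += 2.0 * np.log(np.diag(cF[0])).sum()
                    if m:
                        Bb = Huu[sl, nf:]
                        S -= Bb.T @ sla.cho_solve(cF, Bb, check_finite=False)
                if m:
                    cS = sla.cho_factor(S, lower=True, check_finite=False)
                    logdet += 2.0 * np.log(np.diag(cS[0])).sum()
                return logdet
            except sla.LinAlgError:
                pass
        cF = _chol_ridge(Huu)
        return 2.0 * np.log(np.diag(cF[0])).sum()

    def _laplace_value(self, f, H):
        """Profiled Laplace objective: joint nll at mode + 0.5 logdet H_uu."""
        nu = self.layout.n_random
        if nu == 0:
            return f
        logdet = self._logdet_uu(H[:nu, :nu])
        return f + 0.5 * logdet - 0.5 * nu * _LOG2PI

    # public: Laplace-approximated marginal log-likelihood -------------------
    def marginal_loglik(self, theta: np.ndarray, z0: np.ndarray | None = None):
        """Marginal log-likelihood of the variance parameters ``theta`` with
        the linear fixed effects profiled at their conditional optimum."""
        th = self.unpack_theta(theta)
        Rinv, logdetR = self._prior_setup(th)
        z0 = z0 if z0 is not None else self._z_warm
        z, f, g, H, _ = self._inner_newton(th, z0, Rinv, logdetR)
        self._z_warm = z
        return -self._laplace_value(f, H), z

    # -- fast perturbed evaluation for finite differences --------------------
    def _group_indices(self):
        """Flat group indices for the structured H_uu assembly."""
        if not hasattr(self, "_giA"):
            d, lay = self.data, self.layout
            K, C, V = lay.K, lay.C, lay.V
            self._giA = (d.t * K + d.k) * C + d.c
            self._giV = ((d.t * K + d.k) * C + d.c) * V + d.v if lay.vessel else None
            self._giD = d.v * C + d.c if lay.vessel else None
        return self._giA, self._giV, self._giD

    def _logdet_uu_weights(self, th, Rinv, h11, h12, h22):
        """log det H_uu from per-(year,knot,species[,vessel]) weight sums.

        Exploits that observations couple factor fields only within one
        (year, knot) and vessel effects only within one (vessel, species):
        the field block is year-block-diagonal with knot-diagonal
        observation contributions, and the vessel border is eliminated by a
        Schur complement.
        """
        lay = self.layout
        F, K, T, C, V = lay.F, lay.K, lay.T, lay.C, lay.V
        L1, L2 = th.L1, th.L2
        giA, giV, giD = self._group_indices()
        S11 = np.bincount(giA, weights=h11, minlength=T * K * C).reshape(T, K, C)
        S12 = np.bincount(giA, weights=h12, minlength=T * K * C).reshape(T, K, C)
        S22 = np.bincount(giA, weights=h22, minlength=T * K * C).reshape(T, K, C)
        vessel = lay.vessel
        if vessel:
            VC = V * C
            S11v = np.bincount(giV, weights=h11,
                               minlength=T * K * C * V).reshape(T, K, C, V)
            S12v = np.bincount(giV, weights=h12,
                               minlength=T * K * C * V).reshape(T, K, C, V)
            S22v = np.bincount(giV, weights=h22,
                               minlength=T * K * C * V).reshape(T, K, C, V)
            S = np.zeros((2 * VC, 2 * VC))
            ii = np.arange(VC)
            S[ii, ii] = np.bincount(giD, weights=h11, minlength=VC) \
                + 1.0 / th.sdv1 ** 2
            S[VC + ii, VC + ii] = np.bincount(giD, weights=h22, minlength=VC) \
                + 1.0 / th.sdv2 ** 2
            d12 = np.bincount(giD, weights=h12, minlength=VC)
            S[ii, VC + ii] = d12
            S[VC + ii, ii] = d12
        logdet = 0.0
        FF = 2 * F
        idx = np.arange(K)
        for t in range(T):
            Mk = np.empty((K, FF, FF))
            Mk[:, :F, :F] = np.einsum("kc,cf,cg->kfg", S11[t], L1, L1)
            Mk[:, :F, F:] = np.einsum("kc,cf,cg->kfg", S12[t], L1, L2)
            Mk[:, F:, :F] = Mk[:, :F, F:].transpose(0, 2, 1)
            Mk[:, F:, F:] = np.einsum("kc,cf,cg->kfg", S22[t], L2, L2)
            A4 = np.zeros((FF, K, FF, K))
            for a in range(FF):
                A4[a, :, a, :] = Rinv
            A4[:, idx, :, idx] += Mk
            A = A4.reshape(FF * K, FF * K)
            cF = sla.cho_factor(A, lower=True, check_finite=False)
            logdet += 2.0 * np.log(np.diag(cF[0])).sum()
            if vessel:
                B = np.empty((FF * K, 2 * VC))
                B[:F * K, :VC] = np.einsum("kcv,cf->fkvc", S11v[t], L1
                                           ).reshape(F * K, VC)
                B[:F * K, VC:] = np.einsum("kcv,cf->fkvc", S12v[t], L1
                                           ).reshape(F * K, VC)
                B[F * K:, :VC] = np.einsum("kcv,cf->fkvc", S12v[t], L2
                                           ).reshape(F * K, VC)
                B[F * K:, VC:] = np.einsum("kcv,cf->fkvc", S22v[t], L2
                                           ).reshape(F * K, VC)
                S -= B.T @ sla.cho_solve(cF, B, check_finite=False)
        if vessel:
            cS = sla.cho_factor(S, lower=True, check_finite=False)
            logdet += 2.0 * np.log(np.diag(cS[0])).sum()
        return logdet

    def _huu(self, th, h11, h12, h22):
        """Random-effect block of the joint Hessian (dense)."""
        nu = self.layout.n_random
        Ju = []
        for comp in (1, 2):
            st = self._structures[comp]
            J = st["template_u"].copy()
            J.data = self._values_for(comp, th)[st["perm_u"]]
            Ju.append((J, st["rowidx_u"]))
        (J1, r1), (J2, r2) = Ju
        J1s = J1.copy(); J1s.data = J1.data * h11[r1]
        J2s = J2.copy(); J2s.data = J2.data * h22[r2]
        J2x = J2.copy(); J2x.data = J2.data * h12[r2]
        H = (J1.T @ J1s + J2.T @ J2s).toarray()
        Hx = (J1.T @ J2x).toarray()
        H += Hx + Hx.T
        return H[:nu, :nu]

    def _value_perturbed(self, theta, z_base, base_chol, prior_cache=None,
                         design_cache=None):
        th = self.unpack_theta(theta)
        Rinv, logdetR = prior_cache if prior_cache else self._prior_setup(th)
        J1, J2 = design_cache if design_cache else self._design(th)
        _, g, _ = self._joint_grad_hess(J1, J2, z_base, th, Rinv, logdetR,
                                        want_hess=False)
        z = z_base - sla.cho_solve(base_chol, g, check_finite=False)
        d = self.data
        p1, p2 = self._predictors(J1, J2, z)
        nll, d1, d2, h11, h12, h22 = delta_gamma_nll(
            d.b, p1, p2, d.a, th.sigma2[d.c], derivatives=True)
        pr, _ = self._prior_nll_grad(z, th, Rinv, logdetR, want_grad=False)
        f = float(nll.sum()) + pr
        nu = self.layout.n_random
        if nu == 0:
            return f
        if self.layout.fast_logdet:
            try:
                logdet = self._logdet_uu_weights(th, Rinv, h11, h12, h22)
                return f + 0.5 * logdet - 0.5 * nu * _LOG2PI
            except sla.LinAlgError:
                pass
        Huu = self._huu(th, h11, h12, h22)
        self._prior_hess_diag_blocks(Huu, th, Rinv)
        return f + 0.5 * self._logdet_uu(Huu) - 0.5 * nu * _LOG2PI

    def value_and_grad(self, theta, h=1e-4, scheme="central"):
        """Profiled Laplace objective and finite-difference gradient.

        Each perturbed evaluation reuses the inner mode through one
        warm-started Newton correction with the base Hessian factor, which
        keeps the O(h) dependence of the mode on theta out of the
        difference quotient.  ``scheme`` is "central" (accurate) or
        "forward" (half the cost, used far from the optimum).
        """
        lay = self.layout
        th = self.unpack_theta(theta)
        Rinv, logdetR = self._prior_setup(th)
        z, f, g_in, H, (J1, J2) = self._inner_newton(th, self._z_warm, Rinv,
                                                     logdetR)
        self._z_warm = z
        val = self._laplace_value(f, H)
        base_chol = _chol_ridge(H)
        grad = np.zeros_like(theta)
        for j in range(theta.size):
            hj = h * max(1.0, abs(theta[j]))
            pc = None if lay.theta_affects_R[j] else (Rinv, logdetR)
            dc = None if lay.theta_affects_J[j] else (J1, J2)
            tp = theta.copy(); tp[j] += hj
            vp = self._value_perturbed(tp, z, base_chol, pc, dc)
            if scheme == "forward":
                grad[j] = (vp - val) / hj
            else:
                tm = theta.copy(); tm[j] -= hj
                vm = self._value_perturbed(tm, z, base_chol, pc, dc)
                grad[j] = (vp - vm) / (2.0 * hj)
        return val, grad

    # -- parameter reporting -------------------------------------------------
    def _to_parameter_set(self, th: _Theta, z: np.ndarray) -> ParameterSet:
        lay = self.layout
        d = self.data

        def sign_fix(L):
            if L.size == 0:
                return L
            L = L.copy()
            for f in range(L.shape[1]):
                if f < L.shape[0] and L[f, f] < 0:
                    L[:, f] *= -1.0
            return L

        beta1 = z[lay.z_slices["beta1"]].reshape(lay.C, lay.T)
        beta2 = z[lay.z_slices["beta2"]].reshape(lay.C, lay.T)
        gamma1 = z[lay.z_slices["gamma1"]].reshape(lay.C, lay.P) if lay.P else None
        gamma2 = z[lay.z_slices["gamma2"]].reshape(lay.C, lay.P) if lay.P else None
        gear2 = float(z[lay.z_slices["gear"]][0]) if lay.gear else 0.0
        kernel = (KernelParams(th.range_km, 1.0) if lay.any_grf else None)
        return ParameterSet(
            beta1=beta1, beta2=beta2,
            L1_eps=sign_fix(th.L1) if lay.F else None,
            L2_eps=sign_fix(th.L2) if lay.F else None,
            L1_omega=sign_fix(th.Lom1) if lay.Fo else None,
            L2_omega=sign_fix(th.Lom2) if lay.Fo else None,
            kernel=kernel, gamma1=gamma1, gamma2=gamma2,
            sigma_xi1=th.sxi1 if lay.svc else None,
            sigma_xi2=th.sxi2 if lay.svc else None,
            vessel_sd1=th.sdv1, vessel_sd2=th.sdv2,
            sigma2=th.sigma2, gear2=gear2, basis_spec=d.basis)

    def _random_effects(self, z: np.ndarray) -> RandomEffects:
        lay = self.layout

        def get(name, shape):
            s = lay.z_slices[name]
            if s.stop == s.start:
                return None
            return z[s].reshape(shape)

        u1 = u2 = None
        if lay.F:
            fields = z[:lay.n_field].reshape(lay.T, 2, lay.F, lay.K)
            u1 = np.ascontiguousarray(fields[:, 0].transpose(1, 0, 2))
            u2 = np.ascontiguousarray(fields[:, 1].transpose(1, 0, 2))
        return RandomEffects(
            u1=u1, u2=u2,
            omega1=get("om1", (lay.Fo, lay.K)) if lay.Fo else None,
            omega2=get("om2", (lay.Fo, lay.K)) if lay.Fo else None,
            xi1=get("xi1", (lay.C, lay.P, lay.K)) if lay.svc else None,
            xi2=get("xi2", (lay.C, lay.P, lay.K)) if lay.svc else None,
            eta1=get("eta1", (lay.V, lay.C)) if lay.vessel else None,
            eta2=get("eta2", (lay.V, lay.C)) if lay.vessel else None)

    # -- initial values ------------------------------------------------------
    def _init_theta(self) -> np.ndarray:
        lay, d = self.layout, self.data
        theta = np.zeros(lay.n_theta)
        for name, tril in (("L1", lay.tril), ("L2", lay.tril)):
            if tril[0].size:
                v = np.zeros(len(tril[0]))
                v[tril[0] == tril[1]] = 0.3
                theta[lay.theta_slices[name]] = v
        for name, tril in (("Lom1", lay.tril_o), ("Lom2", lay.tril_o)):
            if tril[0].size:
                v = np.zeros(len(tril[0]))
                v[tril[0] == tril[1]] = 0.3
                theta[lay.theta_slices[name]] = v
        if lay.svc:
            theta[lay.theta_slices["log_sxi1"]] = np.log(0.1)
            theta[lay.theta_slices["log_sxi2"]] = np.log(0.1)
        if lay.any_grf and self.config.estimate_range:
            theta[lay.theta_slices["log_range"]] = np.log(self.config.range_init_km)
        if lay.vessel:
            theta[lay.theta_slices["log_sdv1"]] = np.log(0.2)
            theta[lay.theta_slices["log_sdv2"]] = np.log(0.2)
        s2 = np.ones(lay.C)
        for i in range(lay.C):
            bp = d.b[(d.c == i) & (d.b > 0)]
            if bp.size > 3:
                s2[i] = np.clip((bp.std() / bp.mean()) ** 2, 0.05, 20.0)
        theta[lay.theta_slices["log_sigma2"]] = np.log(s2)
        return theta

    def _init_z(self) -> np.ndarray:
        lay, d = self.layout, self.data
        z = np.zeros(lay.n_z)
        abar = float(d.a.mean())
        for i in range(lay.C):
            for t in range(lay.T):
                m = (d.c == i) & (d.t == t)
                rate = np.clip(np.mean(d.b[m] > 0) if m.any() else 0.3, 0.02, 0.98)
                lam = -np.log1p(-rate)
                b1 = np.log(lam / abar)
                bp = d.b[m & (d.b > 0)]
                r2 = bp.mean() if bp.size else 1.0
                b2 = np.log(max(r2, 1e-3)) - np.log(abar * lam / rate)
                z[lay.z_slices["beta1"]][i * lay.T + t] = b1
                z[lay.z_slices["beta2"]][i * lay.T + t] = b2
        return z


def _chol_ridge(H):
    """Dense Cholesky with escalating diagonal ridge repair."""
    scale = max(np.max(np.abs(np.diag(H))), 1.0)
    ridge = 0.0
    while True:
        try:
            return sla.cho_factor(H + ridge * np.eye(H.shape[0]), lower=True,
                                  check_finite=False)
        except sla.LinAlgError:
            # escalate; a large ridge degrades the step toward gradient
            # descent but keeps the line-searched inner loop moving
            ridge = 1e-8 * scale if ridge == 0 else ridge * 10
            if ridge > 1e6 * scale:
                raise


# ---------------------------------------------------------------------------
# fitted-model container and the public fit()
# ---------------------------------------------------------------------------

@dataclass
class ModelSummary:
    """Lightweight record for model comparison tables."""

    label: str
    loglik: float
    k: int
    fingerprint: str = ""
    effects: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


@dataclass
class FittedModel:
    params: ParameterSet
    random_effects: RandomEffects
    loglik: float
    k: int
    max_abs_gradient: float
    hessian_pd: bool | None
    label: str = "model"
    effects: str = ""
    fingerprint: str = ""
    se: dict = field(default_factory=dict)
    theta: np.ndarray | None = None
    config: ModelConfig | None = None
    n_obs: int = 0
    outer_hessian: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def converged(self) -> bool:
        return bool(self.max_abs_gradient < 1e-4 and self.hessian_pd is True)

    def summary(self) -> ModelSummary:
        return ModelSummary(label=self.label, loglik=self.loglik, k=self.k,
                            fingerprint=self.fingerprint, effects=self.effects)


def fit(data, mesh: SpatialMesh, X_obs=None, config: ModelConfig | None = None,
        init_theta=None, check_hessian: bool = True, gtol: float = 2e-5,
        maxiter: int = 300, outer_hessian=None, basis: CovariateBasis | None = None,
        verbose: bool = False) -> FittedModel:
    """Fit the delta-GLMM by maximizing the Laplace-approximated marginal
    likelihood.

    Parameters
    ----------
    data : pandas.DataFrame or ModelData
        Per-record catch table (one row per haul x species, zeros included).
    X_obs : (n, n_cov) raw covariate values per record, or None.
    config : structural switches; defaults to ModelConfig().
    init_theta : optional warm start for the variance parameters.
    check_hessian : compute the finite-difference Hessian over the variance
        parameters to verify positive-definiteness (costs ~2*n_theta extra
        gradient evaluations).  Without it ``hessian_pd`` is None and the fit
        is never reported as converged.
    """
    config = config or ModelConfig()
    if isinstance(data, pd.DataFrame):
        data = ModelData.from_table(data, mesh, X_obs, basis=basis)
    model = DeltaGLMM(data, mesh, config)
    lay = model.layout
    theta0 = np.asarray(init_theta, dtype=float) if init_theta is not None \
        else model._init_theta()
    model._z_warm = model._init_z()

    state = {"last_gmax": np.inf}

    def objective(theta):
        # forward differences far from the optimum, central near it
        scheme = "forward" if state["last_gmax"] > 0.5 else "central"
        val, grad = model.value_and_grad(theta, scheme=scheme)
        state["last_gmax"] = float(np.max(np.abs(grad))) if grad.size else 0.0
        if verbose:
            print(f"  nll={val:.4f} max|g|={state['last_gmax']:.2e} [{scheme}]")
        return val, grad

    hessian_pd = None
    H_out = None if outer_hessian is None else np.asarray(outer_hessian)
    if lay.n_theta:
        polish = check_hessian or H_out is not None
        if H_out is not None:
            # warm start with cached curvature: go straight to Newton
            theta_hat = theta0
            val, grad = model.value_and_grad(theta_hat)
        else:
            res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter,
                                    "gtol": max(gtol, 3e-4) if polish else gtol,
                                    "ftol": 1e-12, "maxcor": 30})
            theta_hat = res.x
            val, grad = model.value_and_grad(theta_hat)
        max_grad_outer = float(np.max(np.abs(grad)))
        if polish:
            # Newton polish on the FD outer Hessian (cached from a previous
            # fit when supplied); with check_hessian the Hessian is
            # recomputed at the final point and provides the
            # positive-definiteness convergence check
            theta_hat, val, grad, H_out = _newton_polish(
                model, theta_hat, val, grad, H=H_out, gtol=gtol,
                refresh=check_hessian, verbose=verbose)
            max_grad_outer = float(np.max(np.abs(grad)))
            if check_hessian:
                hessian_pd = bool(np.all(np.linalg.eigvalsh(H_out) > 0))
    else:
        theta_hat = theta0
        val, _ = model.marginal_loglik(theta_hat)
        val = -val
        max_grad_outer = 0.0
        hessian_pd = True if check_hessian else None

    th = model.unpack_theta(theta_hat)
    Rinv, logdetR = model._prior_setup(th)
    z, f, g_in, H, _ = model._inner_newton(th, model._z_warm, Rinv, logdetR)
    model._z_warm = z
    value = model._laplace_value(f, H)
    max_grad = max(max_grad_outer, float(np.max(np.abs(g_in))))

    # Wald SEs of profiled fixed effects from the joint Hessian
    se = {}
    nu = lay.n_random
    if lay.n_profiled:
        cF = _chol_ridge(H)
        prof_idx = np.arange(nu, lay.n_z)
        rhs = np.zeros((lay.n_z, prof_idx.size))
        rhs[prof_idx, np.arange(prof_idx.size)] = 1.0
        cov = sla.cho_solve(cF, rhs)[prof_idx]
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        off = 0
        for name in ("beta1", "beta2", "gamma1", "gamma2", "gear"):
            s = lay.z_slices[name]
            m = s.stop - s.start
            if m:
                se[name] = sd[off:off + m].reshape(
                    (lay.C, lay.T) if name.startswith("beta")
                    else (lay.C, lay.P) if name.startswith("gamma") else (m,))
            off += m

    params = model._to_parameter_set(th, z)
    return FittedModel(
        params=params, random_effects=model._random_effects(z),
        loglik=-value, k=lay.n_theta + lay.n_profiled,
        max_abs_gradient=max_grad, hessian_pd=hessian_pd,
        label=config.label, effects=_effects_string(config, data),
        fingerprint=data.fingerprint(), se=se, theta=theta_hat,
        config=config, n_obs=data.n, outer_hessian=H_out)


def _outer_fd_hessian(model: DeltaGLMM, theta: np.ndarray, h: float = 1e-3,
                      scheme: str = "central") -> np.ndarray:
    """FD Hessian of the profiled Laplace objective over theta.

    ``scheme="forward"`` differences forward-scheme gradients (half the
    cost; adequate as a Newton preconditioner), ``"central"`` is used for
    the positive-definiteness convergence check.
    """
    n = theta.size
    H = np.zeros((n, n))
    if scheme == "forward":
        _, g0 = model.value_and_grad(theta, scheme="forward")
        for j in range(n):
            hj = h * max(1.0, abs(theta[j]))
            tp = theta.copy(); tp[j] += hj
            _, gp = model.value_and_grad(tp, scheme="forward")
            H[j] = (gp - g0) / hj
    else:
        for j in range(n):
            hj = h * max(1.0, abs(theta[j]))
            tp = theta.copy(); tp[j] += hj
            tm = theta.copy(); tm[j] -= hj
            _, gp = model.value_and_grad(tp)
            _, gm = model.value_and_grad(tm)
            H[j] = (gp - gm) / (2.0 * hj)
    return 0.5 * (H + H.T)


def _newton_polish(model: DeltaGLMM, theta, val, grad, H=None, gtol=2e-5,
                   max_steps=10, refresh=True, verbose=False):
    """Drive the outer gradient below the convergence criterion with damped
    Newton steps on the FD outer Hessian (optionally a cached one)."""
    if H is None:
        H = _outer_fd_hessian(model, theta, scheme="forward")
    steps = 0
    gmax = np.max(np.abs(grad))
    while gmax > gtol and steps < max_steps:
        Hr = H.copy()
        w = np.linalg.eigvalsh(Hr)
        if w.min() <= 0:
            Hr += (abs(w.min()) + 1e-4 * max(abs(w.max()), 1.0)) * np.eye(len(theta))
        dt = -np.linalg.solve(Hr, grad)
        step = 1.0
        for _ in range(10):
            v_new, g_new = model.value_and_grad(theta + step * dt)
            if v_new <= val + 1e-9 * abs(val):
                break
            step *= 0.5
        else:
            # cached curvature too stale to make progress: recompute
            H = _outer_fd_hessian(model, theta, scheme="forward")
            steps += 1
            continue
        new_gmax = np.max(np.abs(g_new))
        theta, val, grad = theta + step * dt, v_new, g_new
        if new_gmax > 0.8 * gmax and new_gmax > gtol:
            H = _outer_fd_hessian(model, theta, scheme="forward")
        gmax = new_gmax
        steps += 1
        if verbose:
            print(f"  polish: nll={val:.6f} max|g|={gmax:.2e}")
    if refresh:
        H = _outer_fd_hessian(model, theta, scheme="central")
    return theta, val, grad, H


def _effects_string(config: ModelConfig, data: ModelData) -> str:
    parts = ["Temporal"]
    if config.spatial:
        parts.append("spatial")
    if config.spatiotemporal:
        parts.append("spatio-temporal")
    if config.vessel:
        parts.append("vessel")
    if config.gear:
        parts.append("gear")
    parts.extend(data.basis.names or [])
    return " + ".join(parts)


# ---------------------------------------------------------------------------
# linear predictors from explicit parameters (simulation / prediction path)
# ---------------------------------------------------------------------------

def linear_predictors(params: ParameterSet, random_effects: RandomEffects,
                      mesh: SpatialMesh, X_obs, obs: pd.DataFrame):
    """Evaluate (p1, p2) for every record of an observation table.

    Any component whose parameters or random effects are absent contributes
    exactly zero.  Species/year/vessel levels of ``obs`` must be covered by
    the shapes of ``params``/``random_effects``.
    """
    species = sorted(obs["species"].unique().tolist())
    years = sorted(obs["year"].unique().tolist())
    vessels = sorted(obs["vessel"].unique().tolist())
    c = obs["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    t = obs["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
    v = obs["vessel"].map({w: i for i, w in enumerate(vessels)}).to_numpy()
    C, T = params.beta1.shape
    if len(species) > C or len(years) > T:
        raise KeyError("observation table has species/year levels beyond the "
                       "parameter arrays")
    re = random_effects or RandomEffects()
    if re.eta1 is not None and len(vessels) > re.eta1.shape[0]:
        raise KeyError("observation table has vessel levels beyond eta arrays")
    k = mesh.assign_knot(obs["lon"].to_numpy(), obs["lat"].to_numpy())

    p1 = params.beta1[c, t].copy()
    p2 = params.beta2[c, t].copy()
    for comp, (L, u, om_L, om, xi, sxi, eta, gamma) in {
        1: (params.L1_eps, re.u1, params.L1_omega, re.omega1, re.xi1,
            params.sigma_xi1, re.eta1, params.gamma1),
        2: (params.L2_eps, re.u2, params.L2_omega, re.omega2, re.xi2,
            params.sigma_xi2, re.eta2, params.gamma2),
    }.items():
        p = p1 if comp == 1 else p2
        if L is not None and u is not None:
            # eps(s,c,t) = sum_f L[c,f] u[f,t,s]
            p += np.einsum("if,fi->i", L[c, :], u[:, t, k])
        if om_L is not None and om is not None:
            p += np.einsum("if,fi->i", om_L[c, :], om[:, k])
        if eta is not None:
            p += eta[v, c]
        if gamma is not None and X_obs is not None:
            B = params.basis_spec.expand(X_obs)
            p += (gamma[c, :] * B).sum(axis=1)
            if xi is not None and sxi is not None:
                p += ((sxi[c, :] * B) * xi[c, :, :][np.arange(len(c)), :, k]).sum(axis=1)
    if params.gear2 and "gear" in obs.columns:
        gears = sorted(obs["gear"].unique().tolist())
        g01 = obs["gear"].map({g: i for i, g in enumerate(gears)}).to_numpy(float)
        p2 = p2 + params.gear2 * g01
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise FloatingPointError("non-finite linear predictor")
    return p1, p2


# ---------------------------------------------------------------------------
# species correlations, model selection, VIF screen
# ---------------------------------------------------------------------------

def species_correlations(loadings: np.ndarray) -> np.ndarray:
    """Interspecies correlation implied by a species x factor loading matrix.

    Sigma = L L^T scaled to unit diagonal.  A species with a zero loading row
    has no variance: its correlations are undefined and returned as NaN.
    """
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[1] < 1:
        raise ValueError("need at least one factor")
    cov = L @ L.T
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return np.clip(corr, -1.0, 1.0, out=corr, where=np.isfinite(corr))


def model_selection(models, null_model=None) -> pd.DataFrame:
    """AIC comparison table for models fitted to the same data.

    AIC = 2k - 2*loglik; delta AIC relative to the best model; deviance is
    -2*loglik; percent deviance explained is relative to a
    temporal-intercept-only null model when one is supplied.
    """
    summaries = [m.summary() if hasattr(m, "summary") else m for m in models]
    prints = {s.fingerprint for s in summaries if s.fingerprint}
    if len(prints) > 1:
        raise ValueError("models were fitted on different data sets")
    null = None
    if null_model is not None:
        null = null_model.summary() if hasattr(null_model, "summary") else null_model
        if null.fingerprint and prints and null.fingerprint not in prints:
            raise ValueError("null model was fitted on different data")
    aics = np.array([s.aic for s in summaries])
    best = aics.min()
    rows = []
    for s, aic in zip(summaries, aics):
        dev = -2.0 * s.loglik
        pct = np.nan
        if null is not None:
            dev_null = -2.0 * null.loglik
            pct = 100.0 * (1.0 - dev / dev_null)
        rows.append({"model": s.label, "effects": s.effects, "k": s.k,
                     "AIC": aic, "dAIC": aic - best, "deviance": dev,
                     "pct_deviance_explained": pct})
    return pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)


@dataclass
class VifResult:
    retained: list
    dropped: list
    vif: dict


def vif_screen(X, names=None, threshold: float = 10.0) -> VifResult:
    """Iterative variance-inflation-factor screen of covariate columns.

    Drops the largest-VIF column until all remaining VIFs are below the
    threshold.  VIF_p = 1/(1 - R^2_p) from regressing column p on the others
    (with intercept).
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need at least two covariates for a VIF screen")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate column")
    names = list(names) if names is not None else [f"cov{j}" for j in range(X.shape[1])]
    keep = list(range(X.shape[1]))
    dropped = []
    while True:
        Xc = np.column_stack([np.ones(X.shape[0]), X[:, keep]])
        with np.errstate(divide="ignore"):  # exact collinearity -> inf VIF
            vifs = np.array([variance_inflation_factor(Xc, j + 1)
                             for j in range(len(keep))])
        if np.all(vifs < threshold) or len(keep) == 1:
            return VifResult(retained=[names[j] for j in keep],
                             dropped=dropped,
                             vif={names[j]: float(v) for j, v in zip(keep, vifs)})
        worst = int(np.argmax(vifs))
        dropped.append(names[keep[worst]])
        keep.pop(worst)
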