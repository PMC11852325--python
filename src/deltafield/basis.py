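"""Covariate response bases for density covariates.

Covariates enter the linear predictors through a fixed basis expansion of the
standardized covariate value.  The default is a quadratic polynomial (linear +
squared term), which can represent the smooth unimodal or monotone response
shapes typical of thermal/productivity niches; a linear basis and a cubic
B-spline basis (df = 4) are available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

_KIND_NBASIS = {"linear": 1, "quadratic": 2, "bspline": 3}


@dataclass
class CovariateBasis:
    kind: str = "quadratic"
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    names: list | None = None

    def __post_init__(self):
        if self.kind not in _KIND_NBASIS:
            raise ValueError(f"unknown basis kind {self.kind!r}")

    @property
    def n_basis(self) -> int:
        """Basis columns per covariate."""
        return _KIND_NBASIS[self.kind]

    @property
    def n_cov(self) -> int:
        return 0 if self.means is None else len(self.means)

    @property
    def n_columns(self) -> int:
        return self.n_cov * self.n_basis

    def fit(self, X: np.ndarray, names=None) -> "CovariateBasis":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.means = X.mean(axis=0)
        self.sds = X.std(axis=0)
        if np.any(self.sds == 0):
            raise ValueError("constant covariate column cannot be standardized")
        self.names = list(names) if names is not None else [
            f"cov{j}" for j in range(X.shape[1])]
        return self

    def expand(self, X: np.ndarray) -> np.ndarray:
        """Expand raw covariate values (n, n_cov) to basis columns (n, P).

        Columns are ordered covariate-major: all basis terms of covariate 0,
        then covariate 1, etc.
        """
        if self.means is None:
            raise RuntimeError("basis must be fit before expand")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_cov:
            raise ValueError(
                f"expected {self.n_cov} covariates, got {X.shape[1]}")
        z = (X - self.means) / self.sds
        cols = []
        for j in range(self.n_cov):
            zj = z[:, j]
            if self.kind == "linear":
                cols.append(zj[:, None])
            elif self.kind == "quadratic":
                cols.append(np.column_stack([zj, zj ** 2]))
            else:  # cubic B-spline, df = 4, no interior knots, intercept dropped
                zc = np.clip(zj, -3.0, 3.0)
                t = np.r_[[-3.0] * 4, [3.0] * 4]
                dm = BSpline.design_matrix(zc, t, 3).toarray()
                cols.append(dm[:, 1:])
        return np.hstack(cols)

    def column_names(self) -> list:
        out = []
        for j, nm in enumerate(self.names or []):
            for b in range(self.n_basis):
                out.append(f"{nm}^{b + 1}" if self.n_basis > 1 else nm)
        return out

    def to_dict(self) -> dict:
        return {"kind": self.kind, "means": np.asarray(self.means).tolist(),
                "sds": np.asarray(self.sds).tolist(), "names": self.names}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateBasis":
        return cls(kind=d["kind"], means=np.asarray(d["means"], dtype=float),
                   sds=np.asarray(d["sds"], dtype=float), names=d["names"])
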