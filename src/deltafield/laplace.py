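"""Generic Laplace approximation of a marginal log-likelihood.

Small-scale utility for integrating a handful of latent effects out of an
arbitrary joint negative log-likelihood:

    log L = -f(u*) - 0.5 log det H(u*) + (n/2) log(2 pi),

where u* minimizes the joint negative log-likelihood f and H is its Hessian
at the mode.  The approximation is exact whenever f is quadratic in u (the
all-Gaussian case).  The delta-GLMM uses its own structured implementation
(see ``model``); this module serves low-dimensional models and oracle
cross-checks, with derivatives obtained by finite differences when not
supplied.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_LOG2PI = float(np.log(2.0 * np.pi))


def _fd_hessian(f, u, h=1e-3):
    n = u.size
    H = np.empty((n, n))
    f0 = f(u)
    for i in range(n):
        up = u.copy(); up[i] += h
        um = u.copy(); um[i] -= h
        H[i, i] = (f(up) - 2.0 * f0 + f(um)) / (h * h)
        for j in range(i + 1, n):
            upp = u.copy(); upp[i] += h; upp[j] += h
            upm = u.copy(); upm[i] += h; upm[j] -= h
            ump = u.copy(); ump[i] -= h; ump[j] += h
            umm = u.copy(); umm[i] -= h; umm[j] -= h
            H[i, j] = H[j, i] = (f(upp) - f(upm) - f(ump) + f(umm)) / (4 * h * h)
    return H


def laplace_marginal_loglik(joint_nll, u0, hess=None, tol=1e-12) -> float:
    """Laplace-approximated marginal log-likelihood for latent vector u.

    Parameters
    ----------
    joint_nll : callable(u) -> float
        Joint negative log-likelihood (observations + latent prior),
        including all normalization constants.
    u0 : initial latent values; an empty array means no latent effects, in
        which case the result is exactly -joint_nll([]).
    hess : optional callable(u) -> (n, n) Hessian; finite differences
        otherwise.
    """
    u0 = np.atleast_1d(np.asarray(u0, dtype=float))
    if u0.size == 0:
        return -float(joint_nll(u0))
    res = minimize(joint_nll, u0, method="BFGS",
                   options={"gtol": tol ** 0.5, "maxiter": 500})
    u = res.x
    H = hess(u) if hess is not None else _fd_hessian(joint_nll, u)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise np.linalg.LinAlgError("joint Hessian not positive definite at mode")
    return -(float(res.fun) + 0.5 * logdet - 0.5 * u.size * _LOG2PI)
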