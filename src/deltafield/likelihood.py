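"""Poisson-link delta observation model for zero-inflated catch biomass.

The two linear predictors p1 (log expected numbers density) and p2 (log
average weight) map to the encounter probability r1 and the positive catch
rate r2 through the Poisson-link transform

    r1 = 1 - exp(-a * exp(p1)),      r2 = a * exp(p1) / r1 * exp(p2),

where ``a`` is the area swept of the haul.  A catch of zero contributes
log(1 - r1); a positive catch b contributes log r1 plus the log density of a
gamma distribution with mean r2 and dispersion sigma2 (the squared
coefficient of variation: shape = 1/sigma2, scale = r2*sigma2).

The module also supplies the first and second derivatives of the per-record
negative log-likelihood with respect to (p1, p2), which drive the inner
Newton optimization of the Laplace approximation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def poisson_link(p1, p2, area):
    """Transform linear predictors to (encounter probability, positive rate).

    Numerically stable for a*exp(p1) near zero: r1 is computed with expm1 and
    r2 with a series for the ratio lam/(1-exp(-lam)).
    Satisfies r1*r2 = area*exp(p1+p2) identically.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area swept must be strictly positive")
    lam = area * np.exp(p1)
    r1 = -np.expm1(-lam)
    # ratio = lam / r1 -> 1 + lam/2 + lam^2/12 as lam -> 0
    small = lam < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(small, 1.0 + lam / 2.0 + lam ** 2 / 12.0, lam / np.where(r1 > 0, r1, 1.0))
    r2 = ratio * np.exp(p2)
    return r1, r2


def _link_internals(p1, area):
    """lam, r1, log r1, and q = d log r1 / d p1 with stable small-lam limits."""
    with np.errstate(over="ignore", invalid="ignore"):
        lam = area * np.exp(p1)
        r1 = -np.expm1(-lam)
        # r1 underflows to 0 for lam below ~1e-300; floor keeps the log finite
        log_r1 = np.log(np.maximum(r1, 1e-300))
        s = np.exp(-lam)
        small = lam < 1e-8
        q = np.where(small, 1.0 - lam / 2.0 + np.minimum(lam, 1.0) ** 2 / 12.0,
                     lam * s / np.where(r1 > 0, r1, 1.0))
    return lam, r1, log_r1, q


def delta_gamma_nll(b, p1, p2, area, sigma2, derivatives: bool = False):
    """Per-record negative log-likelihood of the Poisson-link delta-gamma model.

    Parameters are broadcast elementwise.  With ``derivatives=True`` returns
    (nll, d1, d2, h11, h12, h22): gradient and Hessian entries with respect
    to (p1, p2) per record.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    area = np.asarray(area, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area swept must be strictly positive")
    if np.any(sigma2 <= 0):
        raise ValueError("gamma dispersion sigma2 must be strictly positive")

    lam, r1, log_r1, q = _link_internals(p1, area)
    pos = b > 0
    alpha = 1.0 / sigma2

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        # log mu = log lam + p2 - log r1 (mu = r2, the conditional mean)
        log_mu = np.log(lam) + p2 - log_r1
        bsafe = np.where(pos, b, 1.0)
        # m = b / (sigma2 * mu)
        m = bsafe * np.exp(-log_mu) * alpha

        nll_pos = (-log_r1 + m + alpha * log_mu + alpha * np.log(sigma2)
                   + gammaln(alpha) - (alpha - 1.0) * np.log(bsafe))
        nll = np.where(pos, nll_pos, lam)
        if not derivatives:
            return nll

        one_q = 1.0 - q
        d1 = np.where(pos, -q + (alpha - m) * one_q, lam)
        d2 = np.where(pos, alpha - m, 0.0)
        qp = q * (1.0 - lam) - q ** 2  # d q / d p1
        h11 = np.where(pos, m * one_q ** 2 - qp * (1.0 + alpha - m), lam)
        h12 = np.where(pos, m * one_q, 0.0)
        h22 = np.where(pos, m, 0.0)
    return nll, d1, d2, h11, h12, h22


def observation_loglik(b, r1, r2, sigma2) -> float:
    """Total log-likelihood of independent catch records given (r1, r2).

    b = 0 contributes log(1 - r1); b > 0 contributes log r1 plus the log
    gamma density with mean r2 and dispersion sigma2 (squared CV).
    """
    b = np.asarray(b, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    if np.any((r1 <= 0) | (r1 >= 1)):
        raise ValueError("encounter probability must lie strictly in (0, 1)")
    if np.any(r2 <= 0) or np.any(sigma2 <= 0):
        raise ValueError("r2 and sigma2 must be strictly positive")
    b, r1, r2, sigma2 = np.broadcast_arrays(b, r1, r2, sigma2)
    out = np.where(b > 0, 0.0, np.log1p(-r1))
    pos = b > 0
    if np.any(pos):
        alpha = 1.0 / sigma2[pos]
        theta = r2[pos] * sigma2[pos]
        bp = b[pos]
        logg = ((alpha - 1.0) * np.log(bp) - bp / theta
                - alpha * np.log(theta) - gammaln(alpha))
        out[pos] = np.log(r1[pos]) + logg
    return float(out.sum())
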