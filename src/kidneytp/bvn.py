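"""Bivariate standard-normal CDF and density via Owen's T function.

The joint likelihood of the endogenous-treatment probit evaluates
``P(X1 <= h, X2 <= k)`` for correlated standard normals tens of thousands of
times per optimizer step, so the implementation uses the vectorized
``scipy.special.owens_t`` identity rather than generic multivariate-normal
quadrature:

    Phi2(h, k, rho) = (Phi(h) + Phi(k)) / 2
                      - T(h, (k - rho h) / (h sqrt(1 - rho^2)))
                      - T(k, (h - rho k) / (k sqrt(1 - rho^2)))
                      - [hk < 0 or (hk = 0 and h + k < 0)] / 2

Arguments at exactly h = 0 or k = 0 are nudged by 1e-12 (the CDF is
continuous, the perturbation is far below statistical resolution) and
|rho| is clamped away from 1.
"""

from __future__ import annotations

import numpy as np
from scipy.special import owens_t
from scipy.stats import norm

_EPS = 1e-12
_RHO_CAP = 1.0 - 1e-10


def bvn_cdf(h, k, rho):
    """P(X1 <= h, X2 <= k) for standard bivariate normal with correlation rho.

    Broadcasts over array inputs; ``rho`` may be scalar or array.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    rho = np.clip(rho, -_RHO_CAP, _RHO_CAP)
    h = np.where(np.abs(h) < _EPS, _EPS, h)
    k = np.where(np.abs(k) < _EPS, _EPS, k)
    s = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    delta = np.where(h * k < 0, 0.5, 0.0)
    out = 0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(h, ah) - owens_t(k, ak) - delta
    return np.clip(out, 0.0, 1.0)


def bvn_pdf(h, k, rho):
    """Standard bivariate normal density at (h, k) with correlation rho."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -_RHO_CAP, _RHO_CAP)
    om = 1.0 - rho * rho
    z = (h * h - 2.0 * rho * h * k + k * k) / om
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(om))
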