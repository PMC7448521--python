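"""Tail probabilities of positively weighted sums of chi-square(1) variables.

P(Q > q) for Q = sum_k lambda_k * chi2_1,k is computed by numerical
inversion of the characteristic function (the Davies/Imhof approach):

    P(Q > q) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du,
    theta(u) = 0.5 * sum_k arctan(lambda_k u) - 0.5 * q * u,
    rho(u)   = prod_k (1 + lambda_k^2 u^2)^(1/4).

When the inversion fails or returns a value outside (0, 1], the
Liu-Tang-Zhang four-moment match to a noncentral chi-square is used as a
fallback.  The moment approximation is also exposed as a fast vectorised
path for Monte-Carlo resampling, where millions of evaluations with the
same weights are needed and bulk (not extreme-tail) accuracy suffices.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import integrate
from scipy.stats import chi2, ncx2

logger = logging.getLogger("protscan")

__all__ = ["mixture_chi2_sf", "liu_sf", "liu_params", "saddlepoint_sf"]

_EPS_LAMBDA = 1e-10
_P_FLOOR = 1e-300


def _clean_lambdas(lambdas) -> np.ndarray:
    lam = np.asarray(lambdas, dtype=float).ravel()
    if lam.size == 0 or np.all(lam <= 0):
        raise ValueError("need at least one positive eigenvalue")
    if np.any(lam < -1e-8 * lam.max()):
        raise ValueError("negative eigenvalues in mixture")
    lam = lam[lam > _EPS_LAMBDA * lam.max()]
    return lam


def liu_params(lambdas: np.ndarray) -> tuple[float, float, float, float]:
    """(mu_Q, sigma_Q, df l, noncentrality delta) of the matched ncx2."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        l = a**2 - 2.0 * delta
    else:
        delta = 0.0
        l = 1.0 / s2
    return c1, np.sqrt(2.0 * c2), l, delta


def liu_sf(q, lambdas) -> np.ndarray:
    """Vectorised moment-matching survival function (ncx2 approximation)."""
    lam = _clean_lambdas(lambdas)
    q = np.asarray(q, dtype=float)
    mu_q, sigma_q, l, delta = liu_params(lam)
    mu_x = l + delta
    sigma_x = np.sqrt(2.0 * (l + 2.0 * delta))
    t = (q - mu_q) / sigma_q
    x = t * sigma_x + mu_x
    p = ncx2.sf(np.maximum(x, 0.0), df=l, nc=delta)
    return np.clip(p, _P_FLOOR, 1.0)


def saddlepoint_sf(q: float, lambdas) -> float:
    """Lugannani–Rice saddlepoint tail approximation for the mixture.

    Relative accuracy is around a percent uniformly into the far tail, at
    a tiny fraction of the cost of the characteristic-function inversion.
    Near the mean of the distribution (where the saddlepoint degenerates)
    the moment approximation is returned instead.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    lam = _clean_lambdas(lambdas)
    q = float(q)
    if q <= 0.0:
        return 1.0
    mean = lam.sum()
    if abs(q - mean) < 1e-8 * mean:
        return float(liu_sf(q, lam))

    def kprime(t):
        return float(np.sum(lam / (1.0 - 2.0 * lam * t))) - q

    upper = 1.0 / (2.0 * lam.max())
    if q > mean:
        lo, hi = 0.0, upper * (1.0 - 1e-12)
        while kprime(hi) < 0.0:  # pragma: no cover - K' -> inf at the pole
            hi = upper - (upper - hi) * 0.1
    else:
        lo = -1.0
        while kprime(lo) > 0.0:
            lo *= 2.0
        hi = 0.0
    that = brentq(kprime, lo, hi, xtol=1e-14)
    u = 1.0 - 2.0 * lam * that
    K = -0.5 * float(np.sum(np.log(u)))
    K2 = 2.0 * float(np.sum(lam**2 / u**2))
    arg = 2.0 * (that * q - K)
    if arg <= 0.0 or K2 <= 0.0:
        return float(liu_sf(q, lam))
    w = np.sign(that) * np.sqrt(arg)
    v = that * np.sqrt(K2)
    if abs(w) < 1e-6:
        return float(liu_sf(q, lam))
    p = norm.sf(w + np.log(v / w) / w)
    return float(np.clip(p, _P_FLOOR, 1.0))


def _imhof_sf(q: float, lam: np.ndarray) -> float:
    # sin(theta(u)) = sin(phi)cos(qu/2) - cos(phi)sin(qu/2): the full
    # integrand is handled adaptively near zero, then the oscillation is
    # integrated explicitly with QUADPACK's Fourier weights
    def phi(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def rho_inv(u):
        return np.exp(-0.25 * np.sum(np.log1p((lam * u) ** 2)))

    def full(u):
        return np.sin(phi(u) - 0.5 * q * u) * rho_inv(u) / u

    a = 1.0 / max(float(lam.max()), q, 1.0)
    i1, e1 = integrate.quad(full, 0.0, a, epsabs=1e-12, epsrel=1e-10, limit=200)
    i2, e2 = integrate.quad(
        lambda u: np.sin(phi(u)) * rho_inv(u) / u,
        a, np.inf, weight="cos", wvar=0.5 * q, limlst=400, limit=400,
    )
    i3, e3 = integrate.quad(
        lambda u: np.cos(phi(u)) * rho_inv(u) / u,
        a, np.inf, weight="sin", wvar=0.5 * q, limlst=400, limit=400,
    )
    if e1 + e2 + e3 > 1e-6:
        raise RuntimeError("characteristic-function inversion did not converge")
    return 0.5 + (i1 + i2 - i3) / np.pi


def mixture_chi2_sf(q: float, lambdas) -> float:
    """P(sum_k lambda_k chi2_1 > q), clamped to (1e-300, 1].

    Exact chi-square tail when all weights are equal; otherwise CF
    inversion with moment-matching fallback (fallback use is logged).
    """
    lam = _clean_lambdas(lambdas)
    q = float(q)
    if q <= 0.0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(np.clip(chi2.sf(q / lam[0], df=lam.size), _P_FLOOR, 1.0))
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            p = _imhof_sf(q, lam)
        if not (0.0 < p <= 1.0) or p < 1e-9:
            # the inversion carries ~1e-10 absolute error: deep tails are
            # delegated to the moment approximation
            raise RuntimeError("inversion outside usable range")
        return float(np.clip(p, _P_FLOOR, 1.0))
    except Exception:
        logger.debug("CF inversion fell back to moment matching at q=%.3g", q)
        return float(liu_sf(q, lam))
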