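"""Per-window set-based association tests from score summary statistics.

Two tests are provided for a window W with score subvector U_W and
covariance submatrix V_W:

* mean (burden) test:      Q = (S'U_W)^2 / (S'V_W S), chi2_1 null;
* variance (SKAT-type):    Q = U_W' Omega U_W, mixture-chi2_1 null with
  weights the eigenvalues of V_W^{1/2} Omega V_W^{1/2}.

S holds per-variant weights (Madsen-Browning 1/sqrt(MAF(1-MAF)) by
default); Omega is diagonal with squared Beta(MAF; 1, 25) density weights,
the SKAT kernel convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .qfchi2 import mixture_chi2_sf
from .windows import Window

__all__ = [
    "WeightScheme",
    "variant_weights",
    "burden_test",
    "variance_test",
    "WindowTestResult",
    "MEAN",
    "VARIANCE",
    "DEFAULT_WEIGHTS",
]

MEAN = "mean"
VARIANCE = "variance"

ONES = "ones"
MADSEN_BROWNING = "madsen_browning"
BETA_DENSITY = "beta"

#: default weighting per test kind, matching standard burden/SKAT practice
DEFAULT_WEIGHTS = {MEAN: MADSEN_BROWNING, VARIANCE: BETA_DENSITY}

WeightScheme = str  # one of ONES / MADSEN_BROWNING / BETA_DENSITY


def variant_weights(maf, scheme: WeightScheme, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Per-variant weights from MAF.

    ``ones`` -> 1; ``madsen_browning`` -> 1/sqrt(MAF(1-MAF));
    ``beta`` -> Beta(a, b) density at the MAF (default Beta(1,25):
    25(1-MAF)^24, strongly up-weighting rare variants).
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    if scheme == ONES:
        return np.ones_like(maf)
    if scheme == MADSEN_BROWNING:
        return 1.0 / np.sqrt(maf * (1.0 - maf))
    if scheme == BETA_DENSITY:
        from scipy.stats import beta as beta_dist

        return beta_dist.pdf(maf, a, b)
    raise ValueError(f"unknown weight scheme {scheme!r}")


@dataclass(frozen=True)
class WindowTestResult:
    window: Window
    Q: float
    p: float
    test_kind: str

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        if self.Q < 0:
            raise ValueError("test statistic must be non-negative")


class DegenerateWindowError(ValueError):
    """The window's quadratic form has no variance under the null."""


def burden_test(U_w: np.ndarray, V_w: np.ndarray, S_w: np.ndarray) -> tuple[float, float]:
    """Weighted-sum (mean effect) test. Returns (Q, p) with chi2_1 null."""
    U_w = np.asarray(U_w, dtype=float).ravel()
    S_w = np.asarray(S_w, dtype=float).ravel()
    V_w = np.atleast_2d(V_w)
    denom = float(S_w @ V_w @ S_w)
    if denom <= 0.0:
        raise DegenerateWindowError("S'VS <= 0: degenerate window")
    Q = float(S_w @ U_w) ** 2 / denom
    return Q, float(max(chi2.sf(Q, df=1), 1e-300))


def variance_eigenvalues(V_w: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Eigenvalues of V^{1/2} Omega V^{1/2} with Omega = diag(w^2).

    Computed as the (identical) spectrum of diag(w) V diag(w); negative
    eigenvalues from numerical error are clipped at zero.
    """
    V_w = np.atleast_2d(V_w)
    A = V_w * np.outer(w, w)
    lam = np.linalg.eigvalsh(0.5 * (A + A.T))
    return np.clip(lam, 0.0, None)


def variance_test(U_w: np.ndarray, V_w: np.ndarray, omega_w: np.ndarray) -> tuple[float, float]:
    """Quadratic-form (variance component) test.

    ``omega_w`` holds the diagonal of Omega (already squared weights).
    Returns (Q, p); the null is the mixture chi2_1 distribution with
    eigenvalue weights of V^{1/2} Omega V^{1/2}.
    """
    U_w = np.asarray(U_w, dtype=float).ravel()
    omega_w = np.asarray(omega_w, dtype=float).ravel()
    if np.any(omega_w < 0):
        raise ValueError("Omega diagonal must be non-negative")
    lam = variance_eigenvalues(V_w, np.sqrt(omega_w))
    if np.all(lam <= 1e-12 * max(1.0, lam.max(initial=0.0))):
        raise DegenerateWindowError("all eigenvalues ~ 0: degenerate window")
    Q = float(U_w @ (omega_w * U_w))
    if Q <= 0.0:
        return max(Q, 0.0), 1.0
    return Q, mixture_chi2_sf(Q, lam)
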