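"""Skew-normal distribution machinery.

The skew-normal family in its *direct parametrization* (DP) has density

    f(x; xi, omega, lambda) = (2/omega) * phi((x-xi)/omega) * Phi(lambda*(x-xi)/omega)

with ``phi``/``Phi`` the standard normal pdf/cdf, location ``xi`` (years),
scale ``omega > 0`` (years) and shape ``lambda`` (unbounded).  The *centered
parametrization* (CP) re-expresses the same distribution through its first
three moments: mean ``mu``, standard deviation ``sigma`` and (moment)
skewness ``gamma``.  The CP is the natural scale for demographic modelling
because the parameters are directly interpretable (mean age at death,
spread, asymmetry) and because the skewness is bounded:

    |gamma| < ((4-pi)/2) * b^3 / (1-b^2)^(3/2),   b = sqrt(2/pi)  ~= 0.9953.

Both parametrizations, the exact closed-form conversion between them,
sampling, and mass-preserving discretization to single-year age bins are
provided here.  Densities, CDFs and random variates are delegated to
:mod:`scipy.stats.skewnorm`; the batched CDF used by the MCMC hot path goes
through Owen's T directly, which is algebraically identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "SkewNormalDP",
    "SkewNormalCP",
    "max_abs_skewness",
    "pdf_dp",
    "cdf_dp",
    "cp_to_dp",
    "dp_to_cp",
    "sample",
    "discretize",
]

_B = math.sqrt(2.0 / math.pi)
_MAX_ABS_GAMMA = 0.5 * (4.0 - math.pi) * _B**3 / (1.0 - _B**2) ** 1.5
# Strictness tolerance at the truncation points +-0.995 used by the priors.
_GAMMA_TOL = 1e-6


@dataclass(frozen=True)
class SkewNormalDP:
    """Direct parametrization: location ``xi``, scale ``omega``, shape ``lam``."""

    xi: float
    omega: float
    lam: float

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")


@dataclass(frozen=True)
class SkewNormalCP:
    """Centered parametrization: mean ``mu``, sd ``sigma``, skewness ``gamma``."""

    mu: float
    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        # equality is allowed (it arises as the numerical limit of extreme
        # shapes) but such a boundary value cannot be converted back to DP
        if abs(self.gamma) > _MAX_ABS_GAMMA:
            raise ValueError(
                f"|gamma| must not exceed {_MAX_ABS_GAMMA:.6f}, got {self.gamma}"
            )


def max_abs_skewness() -> float:
    """Supremum of |skewness| attainable by a skew-normal distribution.

    Equals ``((4-pi)/2) * b^3 / (1-b^2)^(3/2)`` with ``b = sqrt(2/pi)``;
    0.995 when rounded to three decimals.
    """
    return _MAX_ABS_GAMMA


def pdf_dp(x, p: SkewNormalDP) -> np.ndarray:
    """Skew-normal density ``(2/omega) phi(z) Phi(lam*z)`` at ages ``x``."""
    return stats.skewnorm.pdf(np.asarray(x, dtype=float), p.lam, loc=p.xi, scale=p.omega)


def cdf_dp(x, p: SkewNormalDP) -> np.ndarray:
    """Skew-normal cumulative distribution function at ``x``."""
    return stats.skewnorm.cdf(np.asarray(x, dtype=float), p.lam, loc=p.xi, scale=p.omega)


def _cdf_owens(x, xi, omega, lam):
    """Batched skew-normal CDF, ``Phi(z) - 2*T(z, lam)`` with Owen's T.

    Broadcasts over array-valued parameters; identical to
    ``scipy.stats.skewnorm.cdf`` but much faster for many parameter sets.
    """
    z = (x - xi) / omega
    return special.ndtr(z) - 2.0 * special.owens_t(z, lam)


def cp_to_dp(p: SkewNormalCP) -> SkewNormalDP:
    """Exact centered -> direct conversion.

    Inverts the moment map: with ``r = (2*gamma/(4-pi))^(1/3)`` (signed cube
    root), ``mu_z = r/sqrt(1+r^2)`` is the standardized mean ``delta*sqrt(2/pi)``,
    whence ``omega = sigma/sqrt(1-mu_z^2)``, ``xi = mu - omega*mu_z`` and
    ``lam = delta/sqrt(1-delta^2)``.
    """
    if abs(p.gamma) >= _MAX_ABS_GAMMA - _GAMMA_TOL:
        raise ValueError(
            f"|gamma| must be below {_MAX_ABS_GAMMA - _GAMMA_TOL:.6f} for conversion"
        )
    xi, omega, lam = _cp_to_dp_arrays(p.mu, p.sigma, p.gamma)
    return SkewNormalDP(float(xi), float(omega), float(lam))


def _cp_to_dp_arrays(mu, sigma, gamma):
    """Vectorized CP -> DP over numpy arrays (no bound checks)."""
    r = np.cbrt(2.0 * np.asarray(gamma, dtype=float) / (4.0 - np.pi))
    mu_z = r / np.sqrt(1.0 + r * r)
    delta = mu_z / _B
    omega = sigma / np.sqrt(1.0 - mu_z * mu_z)
    xi = mu - omega * mu_z
    lam = delta / np.sqrt(1.0 - delta * delta)
    return xi, omega, lam


def dp_to_cp(p: SkewNormalDP) -> SkewNormalCP:
    """Exact direct -> centered conversion via the moment formulas."""
    delta = p.lam / math.sqrt(1.0 + p.lam * p.lam)
    mu_z = delta * _B
    mu = p.xi + p.omega * mu_z
    sigma = p.omega * math.sqrt(1.0 - mu_z * mu_z)
    gamma = 0.5 * (4.0 - math.pi) * mu_z**3 / (1.0 - mu_z * mu_z) ** 1.5
    return SkewNormalCP(mu, sigma, gamma)


def sample(p: SkewNormalDP, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. skew-normal variates, reproducibly for a given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return stats.skewnorm.rvs(p.lam, loc=p.xi, scale=p.omega, size=n, random_state=rng)


def discretize(p: SkewNormalDP, ages: np.ndarray) -> np.ndarray:
    """Cell probabilities on unit age bins ``[a, a+1)``, renormalized.

    Mass-preserving on the grid: each cell gets ``CDF(a+1) - CDF(a)``; the
    vector is renormalized so it sums to one over the supplied grid.
    """
    ages = np.asarray(ages)
    edges = np.append(ages, ages[-1] + 1).astype(float)
    cells = np.diff(cdf_dp(edges, p))
    total = cells.sum()
    if total < 1e-6:
        raise ValueError(
            f"grid {ages[0]}..{ages[-1]} carries negligible mass ({total:.2e}) "
            "for the given skew-normal"
        )
    return cells / total
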