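"""Relative measurement of premature mortality for a single population.

The age-at-death distribution d(x) is modeled as a three-component mixture

    d(x) = eta * f_I(x)
           + (1 - eta) * alpha * f_m(x; xi_m, omega_m, lambda_m)
           + (1 - eta) * (1 - alpha) * f_M(x; xi_M, omega_M, lambda_M)

with f_I an infant-mortality kernel concentrated near age 0 and f_m, f_M
skew-normal premature and senescent components.  The share of premature
mortality is the mixture weight ``alpha`` — a *relative* measure, defined
by the shape of the whole distribution rather than by an age threshold.

Fitting maximizes the multinomial log likelihood of the discretized
mixture against the observed death-density weights, with multi-start
local optimization; when the density starts at age 5 or above (infant and
child mortality excluded) ``eta`` is fixed at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .lifetable import DeathDensity
from .skewnormal import SkewNormalDP, _cdf_owens, _cp_to_dp_arrays, dp_to_cp

__all__ = [
    "RelativeMixture",
    "FitConfig",
    "FitResult",
    "FitError",
    "infant_density",
    "mixture_density",
    "fit_relative",
    "premature_share",
]


@dataclass(frozen=True)
class RelativeMixture:
    """Fitted three-component mixture (components in direct parametrization)."""

    eta: float
    alpha: float
    premature: SkewNormalDP
    senescent: SkewNormalDP
    infant_scale: float = 1.0
    infant_form: str = "halfnorm"

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must be in [0, 1)")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if dp_to_cp(self.premature).mu >= dp_to_cp(self.senescent).mu:
            raise ValueError("premature component must have the smaller mean")


@dataclass
class FitConfig:
    """Multi-start maximum-likelihood settings for the relative fit."""

    alpha_inits: tuple[float, ...] = (0.1, 0.25, 0.4)
    extra_starts: int = 2
    seed: int = 0
    maxiter: int = 500
    mu_m_max: float = 75.0
    infant_form: str = "halfnorm"
    infant_scale: float = 1.0


@dataclass
class FitResult:
    mixture: RelativeMixture
    log_likelihood: float
    dissimilarity: float
    n_starts: int
    converged: bool
    config: FitConfig = field(repr=False, default_factory=FitConfig)

    def params_frame(self) -> pd.DataFrame:
        cp_m = dp_to_cp(self.mixture.premature)
        cp_M = dp_to_cp(self.mixture.senescent)
        rows = [
            ("eta", self.mixture.eta),
            ("alpha", self.mixture.alpha),
            ("mu_m", cp_m.mu),
            ("sigma_m", cp_m.sigma),
            ("gamma_m", cp_m.gamma),
            ("mu_M", cp_M.mu),
            ("sigma_M", cp_M.sigma),
            ("gamma_M", cp_M.gamma),
            ("log_likelihood", self.log_likelihood),
            ("dissimilarity", self.dissimilarity),
        ]
        return pd.DataFrame(rows, columns=["parameter", "estimate"])

    def to_json(self) -> str:
        return json.dumps(
            {p: v for p, v in self.params_frame().itertuples(index=False)},
            indent=2,
        )


class FitError(RuntimeError):
    """Raised when no optimization start converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def infant_density(x, form: str = "halfnorm", scale: float = 1.0) -> np.ndarray:
    """Infant-mortality kernel on ages x >= 0.

    The default is the unit-mass half-normal ``sqrt(2/pi)/s * exp(-x^2/(2 s^2))``
    with age scale ``s`` (years).  ``form="literal"`` gives the historical
    unnormalized kernel ``(sqrt(2)/pi) * exp(-x^2)``, kept for comparison.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("infant density defined on nonnegative ages")
    if form == "halfnorm":
        return stats.halfnorm.pdf(x, scale=scale)
    if form == "literal":
        return math.sqrt(2.0) / math.pi * np.exp(-(x**2))
    raise ValueError(f"unknown infant form: {form!r}")


def _infant_cells(edges, form, scale):
    if form == "halfnorm":
        return np.diff(stats.halfnorm.cdf(edges, scale=scale))
    # literal kernel: integral of exp(-x^2) is sqrt(pi)/2 * erf(x)
    cells = math.sqrt(2.0) / math.pi * math.sqrt(math.pi) / 2.0 * np.diff(
        special.erf(edges)
    )
    return cells


def mixture_density(x, m: RelativeMixture) -> np.ndarray:
    """Pointwise density of the full three-component mixture."""
    x = np.asarray(x, dtype=float)
    out = (1.0 - m.eta) * (
        m.alpha * stats.skewnorm.pdf(x, m.premature.lam, m.premature.xi, m.premature.omega)
        + (1.0 - m.alpha)
        * stats.skewnorm.pdf(x, m.senescent.lam, m.senescent.xi, m.senescent.omega)
    )
    if m.eta > 0:
        out = out + m.eta * infant_density(x, m.infant_form, m.infant_scale)
    return out


def premature_share(m: RelativeMixture) -> float:
    """Share of premature deaths among deaths above the infant range.

    This is the mixture weight ``alpha`` itself; the share among *all*
    deaths would be ``(1 - eta) * alpha``.
    """
    return m.alpha


def _model_cells(theta, edges, estimate_eta, form, scale):
    if estimate_eta:
        eta, alpha, mu_m, sg_m, g_m, mu_M, sg_M, g_M = theta
    else:
        eta = 0.0
        alpha, mu_m, sg_m, g_m, mu_M, sg_M, g_M = theta
    xm, om, lm = _cp_to_dp_arrays(mu_m, sg_m, g_m)
    xM, oM, lM = _cp_to_dp_arrays(mu_M, sg_M, g_M)
    cells = (1.0 - eta) * (
        alpha * np.diff(_cdf_owens(edges, xm, om, lm))
        + (1.0 - alpha) * np.diff(_cdf_owens(edges, xM, oM, lM))
    )
    if estimate_eta:
        cells = cells + eta * _infant_cells(edges, form, scale)
    total = cells.sum()
    return cells / total if total > 0 else cells


def fit_relative(density: DeathDensity, config: FitConfig | None = None) -> FitResult:
    """Maximum-likelihood fit of the relative mixture to one death density.

    The multinomial log likelihood ``effective_n * sum w(x) log p(x)`` is
    maximized over the centered-parametrization mixture parameters with
    L-BFGS-B from several starts (senescent mean at the empirical mode,
    premature mean 20 years below it, several alpha values plus seeded
    jittered starts).  The premature mean is constrained below
    ``config.mu_m_max`` and the senescent mean above it, which pins the
    component labels.  ``eta`` is estimated only when the density includes
    ages below 5.
    """
    config = config or FitConfig()
    estimate_eta = density.min_age < 5
    ages = density.ages
    w = density.weights
    edges = np.append(ages, ages[-1] + 1).astype(float)
    obs = w > 0

    def nll(theta):
        p = _model_cells(
            theta, edges, estimate_eta, config.infant_form, config.infant_scale
        )
        if np.any(p[obs] <= 0) or not np.all(np.isfinite(p)):
            return 1e12
        return -density.effective_n * float(w[obs] @ np.log(p[obs]))

    mode = float(ages[np.argmax(w)])
    mu_M0 = float(np.clip(mode, config.mu_m_max + 1.0, 100.0))
    mu_m0 = float(np.clip(mode - 20.0, ages[0] + 2.0, config.mu_m_max - 2.0))
    bounds = [
        (1e-6, 0.899),
        (ages[0] + 1.0, config.mu_m_max),
        (1.0, 20.0),
        (-0.79, 0.95),
        (config.mu_m_max + 0.5, 105.0),
        (1.0, 15.0),
        (-0.95, 0.95),
    ]
    if estimate_eta:
        bounds = [(0.0, 0.5)] + bounds
    rng = np.random.default_rng(config.seed)
    starts = []
    for a0 in config.alpha_inits:
        base = [a0, mu_m0, 10.0, 0.0, mu_M0, 6.0, -0.3]
        starts.append(([0.02] if estimate_eta else []) + base)
    mu_m_lo, mu_m_hi = ages[0] + 2.0, config.mu_m_max - 1.0
    for _ in range(config.extra_starts):
        base = [
            rng.uniform(0.05, 0.5),
            rng.uniform(mu_m_lo, mu_m_hi),
            rng.uniform(4, 15),
            rng.uniform(-0.5, 0.5),
            rng.uniform(config.mu_m_max + 1, 95),
            rng.uniform(3, 10),
            rng.uniform(-0.7, 0.3),
        ]
        starts.append(([rng.uniform(0, 0.1)] if estimate_eta else []) + base)

    best = None
    any_success = False
    for s in starts:
        res = optimize.minimize(
            nll, np.asarray(s), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        raise FitError(
            "no optimization start converged",
            {"best_nll": float(best.fun), "best_theta": best.x.tolist()},
        )

    theta = best.x
    if estimate_eta:
        eta, rest = float(theta[0]), theta[1:]
    else:
        eta, rest = 0.0, theta
    alpha, mu_m, sg_m, g_m, mu_M, sg_M, g_M = (float(v) for v in rest)
    xm, om, lm = _cp_to_dp_arrays(mu_m, sg_m, g_m)
    xM, oM, lM = _cp_to_dp_arrays(mu_M, sg_M, g_M)
    mixture = RelativeMixture(
        eta=eta,
        alpha=alpha,
        premature=SkewNormalDP(float(xm), float(om), float(lm)),
        senescent=SkewNormalDP(float(xM), float(oM), float(lM)),
        infant_scale=config.infant_scale,
        infant_form=config.infant_form,
    )
    p = _model_cells(theta, edges, estimate_eta, config.infant_form, config.infant_scale)
    return FitResult(
        mixture=mixture,
        log_likelihood=-float(best.fun),
        dissimilarity=0.5 * float(np.abs(p - w).sum()),
        n_starts=len(starts),
        converged=True,
        config=config,
    )
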