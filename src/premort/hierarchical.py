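"""Hierarchical Bayesian measurement of premature mortality.

A group of populations is assumed to share one *senescent* age-at-death
component while each population j keeps its own *premature* component and
mixture weight:

    d_j(x) = alpha_j * f_m(x; mu^m_j, sigma^m_j, gamma^m_j)
             + (1 - alpha_j) * f_M(x; mu^M, sigma^M, gamma^M)

Both components are skew-normal in centered parametrization and ``d_j`` is
the life-table distribution of deaths above age 5.  ``alpha_j`` — the share
of deaths attributed to the premature component — is the quantity of
interest: because every country in the group is measured against the same
senescent benchmark, the alphas are directly comparable within the group.

Priors
------
Country-level parameters are partially pooled through hyper-priors::

    alpha_j     ~ U(0, 0.9)
    mu^m_j      ~ N(60, sigma_{mu^m}^2)    truncated above at 75
    sigma^m_j   ~ U(0, 20)
    gamma^m_j   ~ N(0, sigma_{gamma^m}^2)  truncated to [-0.8, 0.995]
    mu^M        ~ N(87, 4)                 (variance 4, i.e. sd 2)
    sigma^M     ~ U(0, 9)
    gamma^M     ~ SN(-1, 0.5, 1)           truncated to [-0.995, 0.995]
    sigma_{mu^m}    ~ U(0, 2.5)
    sigma_{gamma^m} ~ U(0, 0.2)

The truncations (premature mean below 75, senescent mean centered at 87)
separate the two components structurally, so no post-hoc relabeling is
needed.  The observation model is multinomial over the single-year age
cells with a per-country pseudo-count ``effective_n`` — it respects the
compositional nature of d(x) and makes posterior width shrink as 1/sqrt(n).

Sampling uses the affine-invariant ensemble sampler (emcee) on an
unconstrained reparametrization with Jacobian corrections, initialized
with a jittered posterior-mode ball; several independent ensembles play
the role of chains for the split-R-hat diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .lifetable import DeathDensity
from .skewnormal import SkewNormalCP, _cdf_owens, _cp_to_dp_arrays, max_abs_skewness

__all__ = [
    "GroupData",
    "PriorSpec",
    "McmcConfig",
    "GroupPosterior",
    "log_prior",
    "log_likelihood",
    "sample_posterior",
    "compute_rhat",
    "premature_prevalence",
    "assess_group_fit",
]

_LOG_2PI = math.log(2.0 * math.pi)

COUNTRY_PARAMS = ("alpha", "mu_m", "sigma_m", "gamma_m")
SHARED_PARAMS = ("mu_M", "sigma_M", "gamma_M")
HYPER_PARAMS = ("sigma_mu_m", "sigma_gamma_m")


@dataclass
class GroupData:
    """Age-at-death distributions of the populations forming one group."""

    labels: list[str]
    densities: list[DeathDensity]
    group_name: str = "group"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.densities):
            raise ValueError("labels and densities must have equal length")
        if len(self.densities) < 2:
            raise ValueError("a group needs at least 2 populations")
        ref = self.densities[0]
        for d in self.densities[1:]:
            if not np.array_equal(d.ages, ref.ages) or d.min_age != ref.min_age:
                raise ValueError("all densities must share one age grid")

    @property
    def n_countries(self) -> int:
        return len(self.labels)

    @property
    def ages(self) -> np.ndarray:
        return self.densities[0].ages


@dataclass
class PriorSpec:
    """Constants of the prior and hyper-prior layer (defaults as above)."""

    alpha_low: float = 0.0
    alpha_high: float = 0.9
    mu_m_center: float = 60.0
    mu_m_upper_trunc: float = 75.0
    sigma_m_low: float = 0.0
    sigma_m_high: float = 20.0
    gamma_m_low: float = -0.8
    gamma_m_high: float = 0.995
    mu_M_mean: float = 87.0
    # N(87, 4) read as variance 4; set mu_M_sd=4.0 to read it as sd instead.
    mu_M_sd: float = 2.0
    sigma_M_low: float = 0.0
    sigma_M_high: float = 9.0
    gamma_M_xi: float = -1.0
    gamma_M_omega: float = 0.5
    gamma_M_lam: float = 1.0
    gamma_M_low: float = -0.995
    gamma_M_high: float = 0.995
    hyper_sd_mu_m_high: float = 2.5
    hyper_sd_gamma_m_high: float = 0.2

    def __post_init__(self) -> None:
        pairs = [
            (self.alpha_low, self.alpha_high),
            (self.sigma_m_low, self.sigma_m_high),
            (self.gamma_m_low, self.gamma_m_high),
            (self.sigma_M_low, self.sigma_M_high),
            (self.gamma_M_low, self.gamma_M_high),
            (0.0, self.hyper_sd_mu_m_high),
            (0.0, self.hyper_sd_gamma_m_high),
        ]
        if any(not (lo < hi) or not np.isfinite([lo, hi]).all() for lo, hi in pairs):
            raise ValueError("prior bounds must be finite and ordered")
        if not (self.mu_M_sd > 0 and self.gamma_M_omega > 0):
            raise ValueError("prior scales must be positive")
        cap = max_abs_skewness()
        if max(abs(self.gamma_m_low), abs(self.gamma_m_high)) > cap + 1e-9:
            raise ValueError("gamma_m truncation outside the skew-normal bound")


@dataclass
class McmcConfig:
    """Ensemble-MCMC settings.

    ``chains`` independent ensembles are run; each contributes one chain of
    iteration-major flattened walker draws.  ``walkers`` defaults to
    ``2*ndim + 2``.  All randomness derives from ``seed``.
    """

    chains: int = 4
    warmup: int = 600
    iterations: int = 400
    seed: int = 0
    walkers: int | None = None
    init_jitter: float = 0.05
    map_maxiter: int = 600
    rhat_threshold: float = 1.1
    #: "map" initializes walkers near the posterior mode; "prior-extremes"
    #: starts alternate chains at opposite extremes of the alpha support,
    #: useful for demonstrating what the R-hat diagnostic detects.
    init_mode: str = "map"


@dataclass
class GroupPosterior:
    """MCMC draws, split-R-hat and summaries for one group fit."""

    group_name: str
    labels: list[str]
    param_names: list[str]
    draws: dict[str, np.ndarray]  # name -> (chains, draws_per_chain)
    rhat: dict[str, float]
    summary: pd.DataFrame
    converged: bool
    fixed_senescent: SkewNormalCP | None = None
    map_estimate: dict[str, float] = field(default_factory=dict)

    def posterior_mean(self, name: str) -> float:
        return float(self.draws[name].mean())


# ---------------------------------------------------------------------------
# parameter layout and unconstrained reparametrization
# ---------------------------------------------------------------------------


class _Layout:
    """Maps the flat parameter vector to named blocks and transforms.

    Country blocks come first (alpha, mu_m, sigma_m, gamma_m per country),
    then the shared senescent block (unless a fixed benchmark curve is
    supplied) and the two hyper standard deviations.
    """

    def __init__(self, labels, spec: PriorSpec, fixed_senescent=None):
        self.labels = list(labels)
        self.spec = spec
        self.fixed_senescent = fixed_senescent
        self.names: list[str] = []
        kinds: list[tuple] = []
        for lab in self.labels:
            self.names += [f"{p}[{lab}]" for p in COUNTRY_PARAMS]
            kinds += [
                ("interval", spec.alpha_low, spec.alpha_high),
                ("upper", spec.mu_m_upper_trunc),
                ("interval", spec.sigma_m_low, spec.sigma_m_high),
                ("interval", spec.gamma_m_low, spec.gamma_m_high),
            ]
        if fixed_senescent is None:
            self.names += list(SHARED_PARAMS)
            kinds += [
                ("identity",),
                ("interval", spec.sigma_M_low, spec.sigma_M_high),
                ("interval", spec.gamma_M_low, spec.gamma_M_high),
            ]
        self.names += list(HYPER_PARAMS)
        kinds += [
            ("interval", 0.0, spec.hyper_sd_mu_m_high),
            ("interval", 0.0, spec.hyper_sd_gamma_m_high),
        ]
        self.kinds = kinds
        self.ndim = len(self.names)
        self.J = len(self.labels)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def constrain(self, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unconstrained -> constrained, returning (X, log|Jacobian|)."""
        U = np.atleast_2d(U)
        X = np.empty_like(U)
        logjac = np.zeros(U.shape[0])
        for d, kind in enumerate(self.kinds):
            u = U[:, d]
            if kind[0] == "interval":
                a, b = kind[1], kind[2]
                s = special.expit(u)
                X[:, d] = a + (b - a) * s
                logjac += math.log(b - a) + special.log_expit(u) + special.log_expit(-u)
            elif kind[0] == "upper":
                # cap the exponent: overflow here only means "far out of
                # support", which the prior maps to -inf anyway
                X[:, d] = kind[1] - np.exp(np.minimum(u, 50.0))
                logjac += u
            else:
                X[:, d] = u
        return X, logjac

    def unconstrain(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = np.empty_like(x)
        for d, kind in enumerate(self.kinds):
            if kind[0] == "interval":
                a, b = kind[1], kind[2]
                u[d] = special.logit((x[d] - a) / (b - a))
            elif kind[0] == "upper":
                u[d] = math.log(kind[1] - x[d])
            else:
                u[d] = x[d]
        return u

    def senescent(self, X: np.ndarray):
        """Senescent CP parameters per row of constrained matrix X."""
        if self.fixed_senescent is not None:
            fs = self.fixed_senescent
            W = X.shape[0]
            return (np.full(W, fs.mu), np.full(W, fs.sigma), np.full(W, fs.gamma))
        base = 4 * self.J
        return X[:, base], X[:, base + 1], X[:, base + 2]

    def hyper(self, X: np.ndarray):
        return X[:, -2], X[:, -1]


def _norm_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _log_prior_matrix(X: np.ndarray, layout: _Layout) -> np.ndarray:
    """Vectorized log prior density over rows of the constrained matrix."""
    spec = layout.spec
    W = X.shape[0]
    lp = np.zeros(W)
    ok = np.ones(W, dtype=bool)
    s_mu, s_g = layout.hyper(X)
    ok &= (s_mu > 0) & (s_mu < spec.hyper_sd_mu_m_high)
    ok &= (s_g > 0) & (s_g < spec.hyper_sd_gamma_m_high)
    lp -= math.log(spec.hyper_sd_mu_m_high) + math.log(spec.hyper_sd_gamma_m_high)
    s_mu_safe = np.where(ok, s_mu, 1.0)
    s_g_safe = np.where(ok, s_g, 1.0)
    # normalization of the truncated hierarchical normals depends on the
    # sampled hyper sds, so it cannot be dropped as a constant
    log_z_mu = special.log_ndtr((spec.mu_m_upper_trunc - spec.mu_m_center) / s_mu_safe)
    z_g = special.ndtr(spec.gamma_m_high / s_g_safe) - special.ndtr(
        spec.gamma_m_low / s_g_safe
    )
    log_z_g = np.log(np.maximum(z_g, 1e-300))
    for j in range(layout.J):
        a, mu_m, sg_m, g_m = (X[:, 4 * j + k] for k in range(4))
        ok &= (a > spec.alpha_low) & (a < spec.alpha_high)
        ok &= mu_m < spec.mu_m_upper_trunc
        ok &= (sg_m > spec.sigma_m_low) & (sg_m < spec.sigma_m_high)
        ok &= (g_m > spec.gamma_m_low) & (g_m < spec.gamma_m_high)
        lp -= math.log(spec.alpha_high - spec.alpha_low)
        lp -= math.log(spec.sigma_m_high - spec.sigma_m_low)
        lp += _norm_logpdf(mu_m, spec.mu_m_center, s_mu_safe) - log_z_mu
        lp += _norm_logpdf(g_m, 0.0, s_g_safe) - log_z_g
    if layout.fixed_senescent is None:
        mu_M, sg_M, g_M = layout.senescent(X)
        ok &= (sg_M > spec.sigma_M_low) & (sg_M < spec.sigma_M_high)
        ok &= (g_M > spec.gamma_M_low) & (g_M < spec.gamma_M_high)
        lp += _norm_logpdf(mu_M, spec.mu_M_mean, spec.mu_M_sd)
        lp -= math.log(spec.sigma_M_high - spec.sigma_M_low)
        z_gM = stats.skewnorm.cdf(
            [spec.gamma_M_low, spec.gamma_M_high],
            spec.gamma_M_lam,
            loc=spec.gamma_M_xi,
            scale=spec.gamma_M_omega,
        )
        lp += stats.skewnorm.logpdf(
            np.where(ok, g_M, 0.0),
            spec.gamma_M_lam,
            loc=spec.gamma_M_xi,
            scale=spec.gamma_M_omega,
        ) - math.log(z_gM[1] - z_gM[0])
    return np.where(ok, lp, -np.inf)


def log_prior(params: np.ndarray, spec: PriorSpec, labels=None, fixed_senescent=None):
    """Log prior density of the full parameter vector; -inf off support.

    ``params`` is laid out country-block-first: for each population
    (alpha, mu_m, sigma_m, gamma_m), then (mu_M, sigma_M, gamma_M) unless a
    fixed senescent benchmark is given, then the two hyper sds.
    """
    params = np.asarray(params, dtype=float)
    if labels is None:
        n_shared = 2 if fixed_senescent is not None else 5
        J, rem = divmod(params.size - n_shared, 4)
        if rem or J < 1:
            raise ValueError("parameter vector length does not match any layout")
        labels = [str(j) for j in range(J)]
    layout = _Layout(labels, spec, fixed_senescent)
    return float(_log_prior_matrix(params[None, :], layout)[0])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _mixture_cells(edges, alpha, prem_cp, sen_cp):
    """Model cell probabilities of the two-component mixture on unit bins.

    ``alpha``/CP parameters may be 1-D arrays (batch); ``edges`` is the
    1-D vector of bin edges.  Unnormalized component masses from CDF
    differences are mixed and the mixture renormalized over the grid.
    """
    xm, om, lm = _cp_to_dp_arrays(*prem_cp)
    xM, oM, lM = _cp_to_dp_arrays(*sen_cp)
    e = edges[None, :]
    cm = np.diff(_cdf_owens(e, xm[:, None], om[:, None], lm[:, None]), axis=1)
    cM = np.diff(_cdf_owens(e, xM[:, None], oM[:, None], lM[:, None]), axis=1)
    p = alpha[:, None] * cm + (1.0 - alpha[:, None]) * cM
    total = p.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, p / total, 0.0)


def _log_likelihood_matrix(X: np.ndarray, layout: _Layout, edges, Wmat, n_eff):
    """Vectorized multinomial log likelihood over rows of X (up to a constant)."""
    W = X.shape[0]
    ll = np.zeros(W)
    mu_M, sg_M, g_M = layout.senescent(X)
    for j in range(layout.J):
        a = X[:, 4 * j]
        prem = (X[:, 4 * j + 1], X[:, 4 * j + 2], X[:, 4 * j + 3])
        p = _mixture_cells(edges, a, prem, (mu_M, sg_M, g_M))
        w = Wmat[j]
        obs = w > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(p[:, obs])
        contrib = n_eff[j] * (w[obs][None, :] * logp).sum(axis=1)
        ll += np.where(np.isfinite(contrib), contrib, -np.inf)
    return ll


def log_likelihood(
    params: np.ndarray, data: GroupData, spec: PriorSpec | None = None, fixed_senescent=None
) -> float:
    """Multinomial log likelihood of the hierarchical mixture (up to a constant).

    For each country j the model cell probabilities on the common grid are
    the discretized mixture ``alpha_j*SN_j^m + (1-alpha_j)*SN^M`` and the
    contribution is ``effective_n_j * sum_x w_j(x) log p_j(x)``.  A model
    cell with zero probability where the data carry weight yields -inf.
    """
    spec = spec or PriorSpec()
    layout = _Layout(data.labels, spec, fixed_senescent)
    params = np.asarray(params, dtype=float)
    if params.size != layout.ndim:
        raise ValueError(f"expected {layout.ndim} parameters, got {params.size}")
    edges = np.append(data.ages, data.ages[-1] + 1).astype(float)
    Wmat = np.array([d.weights for d in data.densities])
    n_eff = np.array([d.effective_n for d in data.densities])
    return float(_log_likelihood_matrix(params[None, :], layout, edges, Wmat, n_eff)[0])


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------


def _initial_point(layout: _Layout, data: GroupData) -> np.ndarray:
    """Heuristic in-support starting point from the empirical densities."""
    spec = layout.spec
    modes = [float(d.ages[np.argmax(d.weights)]) for d in data.densities]
    x = []
    for mode in modes:
        mu_m0 = float(np.clip(mode - 20.0, data.ages[0] + 5.0, spec.mu_m_upper_trunc - 3.0))
        x += [0.2, mu_m0, 10.0, 0.05]
    if layout.fixed_senescent is None:
        mu_M0 = float(np.clip(np.mean(modes), 70.0, 100.0))
        x += [mu_M0, 6.0, -0.4]
    x += [spec.hyper_sd_mu_m_high / 2.0, spec.hyper_sd_gamma_m_high / 2.0]
    return np.asarray(x)


def _find_map(logpost_u, u0: np.ndarray, maxiter: int) -> np.ndarray:
    def objective(u):
        v = -logpost_u(u[None, :])[0]
        # large finite penalty keeps finite-difference gradients defined
        return v if np.isfinite(v) else 1e300

    res = optimize.minimize(
        objective,
        u0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 40 * maxiter},
    )
    return res.x


def sample_posterior(
    data: GroupData,
    spec: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    fixed_senescent: SkewNormalCP | None = None,
) -> GroupPosterior:
    """Draw from the posterior of the hierarchical mixture for one group.

    Runs ``mcmc.chains`` independent affine-invariant ensembles on the
    unconstrained scale (with Jacobian corrections), each initialized in a
    jittered ball around the posterior mode.  Per parameter, each ensemble's
    post-warmup draws (iteration-major over walkers) form one chain of the
    split-R-hat diagnostic.  If any ``alpha_j`` has R-hat above
    ``mcmc.rhat_threshold`` the result is returned flagged non-converged.

    ``fixed_senescent`` switches from joint estimation of the shared
    senescent curve to a fixed benchmark (e.g. a designated reference
    country's fitted curve).
    """
    spec = spec or PriorSpec()
    mcmc = mcmc or McmcConfig()
    layout = _Layout(data.labels, spec, fixed_senescent)
    edges = np.append(data.ages, data.ages[-1] + 1).astype(float)
    Wmat = np.array([d.weights for d in data.densities])
    n_eff = np.array([d.effective_n for d in data.densities])

    def logpost_u(U):
        U = np.atleast_2d(U)
        X, logjac = layout.constrain(U)
        lp = _log_prior_matrix(X, layout)
        out = np.full(U.shape[0], -np.inf)
        okm = np.isfinite(lp)
        if okm.any():
            ll = _log_likelihood_matrix(X[okm], layout, edges, Wmat, n_eff)
            out[okm] = lp[okm] + ll + logjac[okm]
        return out

    u0 = layout.unconstrain(_initial_point(layout, data))
    u_map = _find_map(logpost_u, u0, mcmc.map_maxiter)
    x_map, _ = layout.constrain(u_map[None, :])
    map_estimate = dict(zip(layout.names, x_map[0]))

    ndim = layout.ndim
    nwalkers = mcmc.walkers or (2 * ndim + 2)
    if nwalkers < 2 * ndim:
        raise ValueError("need at least 2*ndim walkers")
    n_keep = mcmc.iterations
    chains_u = np.empty((mcmc.chains, n_keep, nwalkers, ndim))
    for c in range(mcmc.chains):
        chain_seed = (mcmc.seed + 1000003 * (c + 1)) % (2**31 - 1)
        rng = np.random.default_rng(chain_seed)
        u_center = u_map
        if mcmc.init_mode == "prior-extremes":
            u_center = u_map.copy()
            for j in range(layout.J):
                u_center[layout.index(f"alpha[{layout.labels[j]}]")] = (
                    3.0 if c % 2 == 0 else -3.0
                )
        elif mcmc.init_mode != "map":
            raise ValueError(f"unknown init_mode: {mcmc.init_mode!r}")
        p0 = _init_walkers(logpost_u, u_center, nwalkers, mcmc.init_jitter, rng)
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost_u, vectorize=True)
        sampler.random_state = np.random.mtrand.RandomState(chain_seed).get_state()
        sampler.run_mcmc(p0, mcmc.warmup + n_keep, skip_initial_state_check=True)
        chains_u[c] = sampler.get_chain(discard=mcmc.warmup)

    draws: dict[str, np.ndarray] = {}
    rhat: dict[str, float] = {}
    rows = []
    for d, name in enumerate(layout.names):
        # constrain each draw; iteration-major flatten of walkers per chain
        flat = np.empty((mcmc.chains, n_keep * nwalkers))
        for c in range(mcmc.chains):
            X, _ = layout.constrain(chains_u[c, :, :, :].reshape(-1, ndim))
            flat[c] = X[:, d]
        draws[name] = flat
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat[name] = compute_rhat(flat)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": rhat[name],
            }
        )
    summary = pd.DataFrame(rows)
    converged = all(
        rhat[f"alpha[{lab}]"] <= mcmc.rhat_threshold for lab in data.labels
    )
    return GroupPosterior(
        group_name=data.group_name,
        labels=list(data.labels),
        param_names=layout.names,
        draws=draws,
        rhat=rhat,
        summary=summary,
        converged=converged,
        fixed_senescent=fixed_senescent,
        map_estimate=map_estimate,
    )


def _init_walkers(logpost_u, u_map, nwalkers, jitter, rng, max_tries=50):
    p0 = u_map[None, :] + jitter * rng.standard_normal((nwalkers, u_map.size))
    lp = logpost_u(p0)
    for _ in range(max_tries):
        bad = ~np.isfinite(lp)
        if not bad.any():
            return p0
        p0[bad] = u_map[None, :] + jitter * rng.standard_normal((bad.sum(), u_map.size))
        lp[bad] = logpost_u(p0[bad])
    raise RuntimeError("could not find finite-posterior walker initializations")


# ---------------------------------------------------------------------------
# diagnostics and reporting
# ---------------------------------------------------------------------------


def compute_rhat(chains: np.ndarray) -> float:
    """Split potential-scale-reduction factor R-hat.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    and R-hat = sqrt(V-hat / W) with W the mean within-chain variance and
    V-hat the weighted total-variance estimate.  Degenerate constant chains
    give R-hat = 1 by convention, with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    if chains.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within < 1e-300:
        warnings.warn("constant chains: R-hat undefined, reported as 1")
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def premature_prevalence(post: GroupPosterior) -> pd.DataFrame:
    """Per-country premature-mortality table: posterior mean alpha, 95% CI,
    R-hat and within-group rank (1 = lowest alpha)."""
    rows = []
    for lab in post.labels:
        a = post.draws[f"alpha[{lab}]"]
        lo, hi = np.quantile(a, [0.025, 0.975])
        rows.append(
            {
                "country": lab,
                "alpha_mean": float(a.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "rhat": post.rhat[f"alpha[{lab}]"],
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["alpha_mean"].rank(method="first").astype(int)
    return df


def assess_group_fit(
    post: GroupPosterior,
    data: GroupData,
    dissimilarity_threshold: float = 0.05,
    n_replicates: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-country goodness of grouping.

    Reports the dissimilarity index (total-variation distance between the
    posterior-mean model cell probabilities and the data weights) and a
    posterior-predictive p-value from multinomial replicates of the same
    statistic.  A country whose mortality profile differs too much from the
    rest of its group fits poorly and is flagged.
    """
    edges = np.append(data.ages, data.ages[-1] + 1).astype(float)
    rng = np.random.default_rng(seed)
    n_total = next(iter(post.draws.values())).size
    idx = rng.integers(0, n_total, size=min(n_replicates, n_total))
    rows = []
    for lab, dens in zip(post.labels, data.densities):
        mean = {p: post.posterior_mean(f"{p}[{lab}]") for p in COUNTRY_PARAMS}
        sen_mean = _posterior_senescent_mean(post)
        p_mean = _mixture_cells(
            edges,
            np.array([mean["alpha"]]),
            tuple(np.array([mean[k]]) for k in ("mu_m", "sigma_m", "gamma_m")),
            tuple(np.array([v]) for v in sen_mean),
        )[0]
        dissim = 0.5 * np.abs(p_mean - dens.weights).sum()
        n_draw = int(round(dens.effective_n))
        exceed = 0
        for i in idx:
            theta = {
                p: post.draws[f"{p}[{lab}]"].ravel()[i] for p in COUNTRY_PARAMS
            }
            sen_i = _posterior_senescent_at(post, i)
            p_i = _mixture_cells(
                edges,
                np.array([theta["alpha"]]),
                tuple(np.array([theta[k]]) for k in ("mu_m", "sigma_m", "gamma_m")),
                tuple(np.array([v]) for v in sen_i),
            )[0]
            rep = rng.multinomial(n_draw, p_i) / n_draw
            t_rep = 0.5 * np.abs(rep - p_i).sum()
            t_obs = 0.5 * np.abs(dens.weights - p_i).sum()
            exceed += t_rep >= t_obs
        rows.append(
            {
                "country": lab,
                "dissimilarity": float(dissim),
                "ppp": exceed / len(idx),
                "flagged": bool(dissim > dissimilarity_threshold),
            }
        )
    return pd.DataFrame(rows)


def _posterior_senescent_mean(post: GroupPosterior):
    if post.fixed_senescent is not None:
        fs = post.fixed_senescent
        return fs.mu, fs.sigma, fs.gamma
    return tuple(post.posterior_mean(p) for p in SHARED_PARAMS)


def _posterior_senescent_at(post: GroupPosterior, i: int):
    if post.fixed_senescent is not None:
        fs = post.fixed_senescent
        return fs.mu, fs.sigma, fs.gamma
    return tuple(post.draws[p].ravel()[i] for p in SHARED_PARAMS)
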