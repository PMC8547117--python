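# Methods

## Data model

The unit of analysis is one population-year's period life table in HMD
1×1 layout. Only the deaths column d(x) is used for the mixture models:
it is the age-at-death distribution of a synthetic cohort and therefore
already standardized for population age structure, which is what makes
cross-country comparison meaningful without an external standard
population. For the mixture analyses, deaths below age 5 are discarded
and the remainder renormalized (`to_death_density(min_age=5)`): infant
and child mortality is a separate epidemiological regime and would
otherwise absorb a third mixture component with very different scale.
The open age interval ("110+") is carried on the single terminal age;
its mass is negligible for the fitted components and every model density
is renormalized on the same grid.

Each density carries an `effective_n`, the pseudo-count used as the
multinomial sample size. It defaults to the radix-scaled death count
above the minimum age (so ~100 000 for an HMD table with the conventional
radix) and is configurable, because posterior width scales as
1/sqrt(effective_n) and users may want to encode the real death count of
a small population instead.

## Skew-normal machinery

Both adult components are skew-normal. The direct parametrization (DP:
location ξ, scale ω, shape λ) is what scipy evaluates; the centered
parametrization (CP: mean μ, sd σ, moment skewness γ) is what the priors
and all reported estimates use, because its parameters are interpretable
demographic quantities. The conversion is the exact closed form obtained
by inverting the moment map; its skewness is bounded,
|γ| < ((4−π)/2)·b³/(1−b²)^{3/2} with b = √(2/π) ≈ 0.9953 (0.995 at three
decimals). The bound is enforced at the type level; the CP→DP conversion
additionally refuses values within 1e-6 of the bound, where ω and λ
diverge.

Discretization to single-year age cells uses CDF differences on [a, a+1)
rather than midpoint evaluation — mass-preserving on a coarse grid — and
renormalizes over the grid. Mixtures are discretized by mixing the raw
(unnormalized) component cell masses and renormalizing the mixture, and
the synthetic generator uses the identical recipe, so generative truth
and likelihood agree exactly. In the MCMC hot path the skew-normal CDF
is evaluated as Φ(z) − 2·T(z, λ) via Owen's T, which is algebraically
identical to the scipy distribution call but vectorizes cheaply over
walker batches.

## Relative fit

The single-population three-component fit maximizes the multinomial
log likelihood `effective_n · Σ_x w(x) log p(x)` over CP parameters with
L-BFGS-B under box constraints. Mixture likelihoods are multimodal, so
the optimizer is multi-started: the senescent mean initialized at the
empirical modal age at death, the premature mean 20 years below it,
premature weights 0.1/0.25/0.4, plus seeded random starts. Label
switching is excluded structurally: the premature mean is constrained
below 75 years and the senescent mean above it, mirroring the
hierarchical prior truncation. When the density starts at age 5 the
infant weight η is fixed at 0; for full-age densities η is estimated.

The infant kernel is a unit-mass half-normal with a configurable age
scale (default 1 year). A historical unnormalized variant of the kernel,
(√2/π)·exp(−x²), is kept behind `form="literal"` for comparison only; it
is not a probability density and is never used in fitting.

## Hierarchical model and priors

See the README for the model statement. Priors (defaults in
`PriorSpec`):

| parameter | prior | notes |
|---|---|---|
| α_j | U(0, 0.9) | premature share, the estimand |
| μ^m_j | N(60, σ²_{μ^m}) T(−∞, 75] | partial pooling across countries |
| σ^m_j | U(0, 20) | years |
| γ^m_j | N(0, σ²_{γ^m}) T[−0.8, 0.995] | |
| μ^M | N(87, 4) | variance 4, i.e. sd 2 (`mu_M_sd` knob; set 4.0 to read "sd 4") |
| σ^M | U(0, 9) | years |
| γ^M | SN(−1, 0.5, 1) T[−0.995, 0.995] | skew-normal read in DP (ξ, ω, λ) |
| σ_{μ^m} | U(0, 2.5) | hyper sd, years |
| σ_{γ^m} | U(0, 0.2) | hyper sd |

Two notational ambiguities are resolved as package defaults and exposed
as knobs: N(87, 4) is read as *variance* 4 (a sd of 4 years would make
the senescent benchmark too vague to anchor the mixture), and the
skew-normal prior on γ^M is read in direct parametrization. The
hyper-centers (60 years, 0) are fixed constants, not hyper-parameters.
The truncation normalizing constants of the hierarchical normals are
included in the log prior — they depend on the sampled hyper sds and are
not constants. The truncations themselves (premature mean ≤ 75 vs
senescent mean centered at 87, γ^m ≥ −0.8) separate the components and
prevent label switching without post-hoc relabeling.

The observation model is multinomial over the discretized cells with the
per-country `effective_n` as sample size. Up to a constant, each
country contributes `effective_n_j · Σ_x w_j(x) log p_j(x)`; a model
cell with zero probability where the data carry weight yields −∞.

A *fixed benchmark* mode replaces joint estimation of (μ^M, σ^M, γ^M)
with a supplied reference curve — e.g. the fitted senescent curve of a
designated reference country, or of the pooled "super-country" built by
`pool_group` (equal country weights: the life tables are already
standardized, so pooling is an average of distributions, not of
populations).

## Sampling and diagnostics

The posterior is sampled with the affine-invariant stretch-move ensemble
sampler (emcee) on an unconstrained scale: interval-bounded parameters
via scaled logit, the upper-truncated premature means via log(75 − μ),
with the corresponding Jacobian terms added to the log density. A
posterior-mode search (L-BFGS-B from a data-driven heuristic start)
precedes sampling; walkers start in a jittered ball around the mode
(jitter 0.05 on the unconstrained scale), and invalid starts are
resampled. Defaults: 4 independent ensembles ("chains") of 2·ndim + 2
walkers, 600 warmup + 400 kept iterations each. With ~44 walkers this
keeps ~17 600 draws per chain — a larger kept sample than typical
gradient-sampler defaults — and the central recovery experiment mixes to
R-hat < 1.05 in under a minute on one CPU. Everything is deterministic
given the seed; chain c uses seed + 1000003·(c+1) (mod 2³¹−1).

Convergence is summarized by plain split-R-hat per parameter: each
chain's kept draws (iteration-major over walkers) are split in half and
R̂ = √(V̂/W) computed from within- and between-half variances. Constant
chains return 1 by convention with a warning. If any α_j exceeds the
threshold (default 1.1) the posterior is returned flagged
`converged=False`, and the CLI exits nonzero. Walkers within one
ensemble are not independent chains, so the between-chain variance is
driven by the independent ensembles; the diagnostic's i.i.d. and
separated-chain behavior is verified against arviz's split R-hat in the
test suite.

Goodness of grouping (`assess_group_fit`) reports, per country, the
total-variation distance between the data weights and the
posterior-mean model cells (flagged above 0.05 — a visible distortion of
the death distribution) plus a posterior-predictive p-value of the same
statistic under multinomial replicates. A country whose profile departs
from its group (e.g. a death distribution shifted 15 years) is flagged;
the p-value is auxiliary, and with 100k deaths it is sensitive to even
small residual misfit.

## Synthetic data

The generator emulates exactly the generative structure the hierarchical
model assumes: two-component mixtures on ages 5–110, shared senescent
curve per group, multinomial sampling at a configurable number of deaths
(default 100 000, the order of an HMD life-table death count), written
out as fully consistent HMD-layout tables (dx integer-rounded by largest
remainder so columns sum exactly to the radix; lx by cumulative
subtraction; Lx = lx − dx/2; mx = dx/Lx). Presets cover a
high-longevity group (senescent mean 87, sd 6, skewness −0.5, premature
shares 0.05–0.30), a medium-longevity group (mean 80), and a contrast
pair with a compressed right-shifted versus dispersed left-shifted
senescent curve.

What passing recovery tests show — and what they do not: the data are
drawn from the model's own family, so recovery validates the estimator,
identifiability, and the diagnostics, not the adequacy of the
skew-normal mixture for any real population. Real life tables carry
cohort effects, wars and epidemics, age heaping and smoothing artifacts
that the generator does not emulate. True premature means are kept in
57–63 years, consistent with the hyper-prior's center; truths far from
60 would put prior and likelihood in conflict and is the situation the
grouping diagnostic, not the estimator, is meant to catch.

## Numerical choices and limitations

* Problem sizes: the central recovery study uses 4 countries × 100 000
  deaths with the default 4-ensemble sampler; secondary experiments
  (group-dependence, calibration over 10 groups, exchangeability) use 2
  ensembles of 400 warmup + 300 kept iterations, which reproduce the
  4-ensemble means and intervals to well within Monte-Carlo error.
* Calibration: across 10 independent 3-country groups the 95% intervals
  for α_j cover the truth in ~93% of country-instances.
* Ranks use first-occurrence tie-breaking (`rank(method="first")`); rank
  1 is the lowest premature share.
* The mode-ball initialization is chosen for speed; it underexplores
  multimodal posteriors by construction. The prior truncations remove
  the label-switching modes, and the deliberately overdispersed
  `init_mode="prior-extremes"` exists to demonstrate that R-hat detects
  failures when chains do start apart.
* Parameters at prior bounds (α near 0 or 0.9) compress against the
  logit transform; estimates there are prior-sensitive, as in any
  bounded-support Bayesian model.
* Group composition is an input, not an inference: the package measures
  how a country fares *given* a group and flags poor grouping, but does
  not cluster countries into groups.
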