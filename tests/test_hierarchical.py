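"""Hierarchical model: priors, likelihood, sampling, diagnostics, fit checks."""

import math

import numpy as np
import pytest
from scipy import stats

import premort as pm
from premort.hierarchical import _Layout

from conftest import FAST_MCMC


def truth_vector(scenario):
    """Full parameter vector at the generative truth."""
    x = []
    for c in scenario.countries:
        x += [c.alpha, c.premature.mu, c.premature.sigma, c.premature.gamma]
    sen = scenario.senescent
    x += [sen.mu, sen.sigma, sen.gamma, 1.5, 0.1]
    return np.asarray(x)


def small_group(seed=11, n=20_000):
    scen = pm.SyntheticScenario(
        group_name="small",
        seed=seed,
        countries=(
            pm.CountrySpec("P", 0.15, pm.SkewNormalCP(59.0, 12.0, 0.05), n=n),
            pm.CountrySpec("Q", 0.30, pm.SkewNormalCP(60.0, 12.0, 0.10), n=n),
        ),
        senescent=pm.SkewNormalCP(86.0, 6.0, -0.5),
    )
    return scen, pm.generate_group(scen)


class TestLogPrior:
    spec = pm.PriorSpec()

    def test_out_of_support_alpha(self, recovery_scenario):
        x = truth_vector(recovery_scenario)
        x[0] = 0.95
        assert pm.log_prior(x, self.spec) == -np.inf

    def test_out_of_support_premature_mean(self, recovery_scenario):
        x = truth_vector(recovery_scenario)
        x[1] = 80.0
        assert pm.log_prior(x, self.spec) == -np.inf

    def test_matches_term_by_term_oracle(self, recovery_scenario):
        """Independently coded sum of the stated prior log densities."""
        x = truth_vector(recovery_scenario)
        s = self.spec
        s_mu, s_g = x[-2], x[-1]
        expected = -math.log(2.5) - math.log(0.2)
        for j in range(4):
            a, mu_m, sg_m, g_m = x[4 * j : 4 * j + 4]
            expected += math.log(1.0 / 0.9) + math.log(1.0 / 20.0)
            expected += stats.truncnorm.logpdf(
                mu_m, -np.inf, (75.0 - 60.0) / s_mu, loc=60.0, scale=s_mu
            )
            expected += stats.truncnorm.logpdf(
                g_m, -0.8 / s_g, 0.995 / s_g, loc=0.0, scale=s_g
            )
        mu_M, sg_M, g_M = x[16], x[17], x[18]
        expected += stats.norm.logpdf(mu_M, 87.0, 2.0)
        expected += math.log(1.0 / 9.0)
        z = stats.skewnorm.cdf([-0.995, 0.995], 1.0, -1.0, 0.5)
        expected += stats.skewnorm.logpdf(g_M, 1.0, -1.0, 0.5) - math.log(z[1] - z[0])
        assert pm.log_prior(x, self.spec) == pytest.approx(expected, abs=1e-9)

    def test_invalid_prior_spec_rejected(self):
        with pytest.raises(ValueError):
            pm.PriorSpec(alpha_low=0.5, alpha_high=0.2)


class TestLogLikelihood:
    def test_duplicating_country_adds_its_contribution(self, recovery_group, recovery_scenario):
        x = truth_vector(recovery_scenario)
        ll_full = pm.log_likelihood(x, recovery_group)
        labels = recovery_group.labels
        dens = recovery_group.densities
        g_abb = pm.GroupData(labels + ["B2"], dens + [dens[1]], "dup")
        x_dup = np.concatenate([x[:16], x[4:8], x[16:]])
        ll_dup = pm.log_likelihood(x_dup, g_abb)
        g_bb = pm.GroupData(["B", "B2"], [dens[1], dens[1]], "bb")
        x_bb = np.concatenate([x[4:8], x[4:8], x[16:]])
        ll_bb = pm.log_likelihood(x_bb, g_bb)
        assert ll_dup - ll_full == pytest.approx(ll_bb / 2.0, rel=1e-9)

    def test_alpha_sweep_peaks_at_truth(self):
        """Exact-probability data: the likelihood over a 1-D alpha grid is
        maximized at the generative alpha."""
        scen = pm.SyntheticScenario(
            group_name="exact",
            seed=1,
            countries=(
                pm.CountrySpec("P", 0.25, pm.SkewNormalCP(59.0, 12.0, 0.05), n=None),
                pm.CountrySpec("Q", 0.25, pm.SkewNormalCP(59.0, 12.0, 0.05), n=None),
            ),
            senescent=pm.SkewNormalCP(86.0, 6.0, -0.5),
        )
        g = pm.generate_group(scen)
        grid = np.round(np.arange(0.05, 0.81, 0.05), 2)
        lls = []
        for a in grid:
            x = truth_vector(scen)
            x[0] = a
            lls.append(pm.log_likelihood(x, g))
        assert grid[int(np.argmax(lls))] == pytest.approx(0.25)

    def test_unexplained_mass_collapses_likelihood(self):
        """alpha ~ 0 with data mass far below the senescent support."""
        ages = np.arange(5, 111)
        w = np.zeros(len(ages))
        w[ages == 40] = 0.05
        sen = pm.discretize(pm.cp_to_dp(pm.SkewNormalCP(87.0, 4.0, -0.3)), ages)
        w += 0.95 * sen
        w /= w.sum()
        d = pm.DeathDensity(ages=ages, weights=w, min_age=5, effective_n=1e5)
        g = pm.GroupData(["A", "B"], [d, d], "bad")
        x = np.array(
            [1e-9, 60, 12, 0.0, 1e-9, 60, 12, 0.0, 87.0, 4.0, -0.3, 1.5, 0.1]
        )
        ll = pm.log_likelihood(x, g)
        assert ll == -np.inf or ll < -1e5

    def test_wrong_length_rejected(self, recovery_group):
        with pytest.raises(ValueError):
            pm.log_likelihood(np.zeros(7), recovery_group)


class TestComputeRhat:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            pm.compute_rhat(np.random.default_rng(0).normal(size=(1, 100)))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            pm.compute_rhat(np.zeros((4, 3)))

    def test_constant_chains_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            assert pm.compute_rhat(np.ones((4, 100))) == 1.0

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(5)
        chains = rng.standard_normal((4, 1000))
        assert 0.99 <= pm.compute_rhat(chains) <= 1.01

    def test_separated_chains_large(self):
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert pm.compute_rhat(chains) > 3.0

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((4, 500)) + np.linspace(0, 0.5, 4)[:, None]
        mine = pm.compute_rhat(chains)
        theirs = float(az.rhat(chains, method="split"))
        assert mine == pytest.approx(theirs, abs=0.01)


class TestSamplePosterior:
    def test_draws_respect_truncations(self, recovery_posterior):
        post = recovery_posterior
        for lab in post.labels:
            a = post.draws[f"alpha[{lab}]"]
            assert np.all((a > 0) & (a < 0.9))
            assert np.all(post.draws[f"mu_m[{lab}]"] < 75.0)
            g = post.draws[f"gamma_m[{lab}]"]
            assert np.all((g > -0.8) & (g < 0.995))
        g = post.draws["gamma_M"]
        assert np.all((g > -0.995) & (g < 0.995))
        assert np.all(post.draws["sigma_M"] < 9.0)

    def test_rhat_defined_for_every_parameter(self, recovery_posterior):
        assert set(recovery_posterior.rhat) == set(recovery_posterior.param_names)
        assert all(np.isfinite(v) for v in recovery_posterior.rhat.values())

    def test_deterministic_given_seed(self):
        _, g = small_group()
        cfg = pm.McmcConfig(chains=2, warmup=60, iterations=40, seed=17)
        p1 = pm.sample_posterior(g, mcmc=cfg)
        p2 = pm.sample_posterior(g, mcmc=cfg)
        assert p1.summary.equals(p2.summary)
        for k in p1.draws:
            assert np.array_equal(p1.draws[k], p2.draws[k])

    def test_deliberate_nonconvergence_flagged(self):
        _, g = small_group()
        cfg = pm.McmcConfig(
            chains=2, warmup=0, iterations=10, seed=3, init_mode="prior-extremes"
        )
        post = pm.sample_posterior(g, mcmc=cfg)
        assert any(post.rhat[f"alpha[{lab}]"] > 1.1 for lab in g.labels)
        assert not post.converged

    def test_exchangeable_countries_agree(self):
        scen, _ = small_group()
        d = pm.generate_density(scen, "P")
        g = pm.GroupData(["L", "R"], [d, d], "twin")
        post = pm.sample_posterior(g, mcmc=pm.McmcConfig(seed=21, **FAST_MCMC))
        assert abs(
            post.posterior_mean("alpha[L]") - post.posterior_mean("alpha[R]")
        ) < 0.02

    def test_credible_interval_coverage(self):
        """Calibration: over 10 independent 3-country groups with 100k
        deaths each, the 95% intervals for alpha must cover the truth in at
        least 85% of country-instances."""
        rng = np.random.default_rng(123)
        hits = total = 0
        for rep in range(10):
            alphas = rng.uniform(0.05, 0.45, 3)
            countries = tuple(
                pm.CountrySpec(
                    f"C{k}",
                    float(alphas[k]),
                    pm.SkewNormalCP(
                        float(rng.uniform(57, 63)),
                        float(rng.uniform(10, 14)),
                        float(rng.uniform(-0.1, 0.2)),
                    ),
                )
                for k in range(3)
            )
            scen = pm.SyntheticScenario(
                group_name=f"g{rep}",
                countries=countries,
                senescent=pm.SkewNormalCP(87.0, 6.0, -0.5),
                seed=2000 + rep,
            )
            post = pm.sample_posterior(
                pm.generate_group(scen),
                mcmc=pm.McmcConfig(seed=3000 + rep, **FAST_MCMC),
            )
            prev = pm.premature_prevalence(post)
            for k in range(3):
                lo = prev.loc[k, "ci_low"]
                hi = prev.loc[k, "ci_high"]
                hits += lo <= alphas[k] <= hi
                total += 1
        assert hits / total >= 0.85

    def test_fixed_benchmark_mode(self):
        _, g = small_group()
        bench = pm.SkewNormalCP(86.0, 6.0, -0.5)
        post = pm.sample_posterior(
            g,
            mcmc=pm.McmcConfig(chains=2, warmup=150, iterations=100, seed=9),
            fixed_senescent=bench,
        )
        assert "mu_M" not in post.param_names
        assert post.fixed_senescent == bench
        assert 0.05 < post.posterior_mean("alpha[P]") < 0.35


class TestPrematurePrevalence:
    def test_ranks_are_permutation(self, recovery_posterior):
        prev = pm.premature_prevalence(recovery_posterior)
        assert sorted(prev["rank"]) == [1, 2, 3, 4]

    def test_ranks_match_truth(self, recovery_posterior, recovery_scenario):
        prev = pm.premature_prevalence(recovery_posterior).set_index("country")
        true_alpha = {c.label: c.alpha for c in recovery_scenario.countries}
        true_rank = {
            lab: r + 1
            for r, lab in enumerate(sorted(true_alpha, key=true_alpha.get))
        }
        assert {lab: prev.loc[lab, "rank"] for lab in true_alpha} == true_rank


class TestAssessGroupFit:
    def test_well_grouped_countries_fit(self, recovery_posterior, recovery_group):
        fit = pm.assess_group_fit(recovery_posterior, recovery_group, seed=1)
        assert (fit["dissimilarity"] < 0.02).all()
        assert not fit["flagged"].any()
        assert ((fit["dissimilarity"] >= 0) & (fit["dissimilarity"] <= 1)).all()

    def test_shifted_country_flagged(self):
        scen, g = small_group(n=50_000)
        shifted = np.roll(g.densities[1].weights, 15)
        shifted[:15] = 0.0
        bad = pm.DeathDensity(
            ages=g.densities[1].ages,
            weights=shifted / shifted.sum(),
            min_age=5,
            effective_n=g.densities[1].effective_n,
        )
        g2 = pm.GroupData(["P", "SHIFTED"], [g.densities[0], bad], "mixed")
        post = pm.sample_posterior(g2, mcmc=pm.McmcConfig(seed=31, **FAST_MCMC))
        fit = pm.assess_group_fit(post, g2, seed=2).set_index("country")
        assert fit.loc["SHIFTED", "flagged"]


class TestLayout:
    def test_constrain_unconstrain_roundtrip(self, recovery_scenario):
        layout = _Layout(["A", "B", "C", "D"], pm.PriorSpec())
        x = truth_vector(recovery_scenario)
        u = layout.unconstrain(x)
        back, _ = layout.constrain(u[None, :])
        assert np.allclose(back[0], x, atol=1e-9)
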