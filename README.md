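# premort

Measuring **premature mortality** from life-table age-at-death
distributions — for demographers, epidemiologists and health-systems
researchers comparing countries or regions.

## The problem

How many deaths in a population are "too early"? The classical *absolute*
answer fixes an age threshold (65, 70 or 75 years) and counts deaths below
it, or weights them by the years lost to a standard life expectancy
(PYLL). But the threshold is arbitrary, and changing it can reverse
country rankings. The *relative* answer instead fits the life-table
distribution of deaths d(x) as a mixture

&nbsp;&nbsp;&nbsp;&nbsp;d(x) = η·f_I(x) + (1−η)·α·f_m(x) + (1−η)(1−α)·f_M(x)

of infant (f_I), premature (f_m) and senescent (f_M) components — the two
adult components skew-normal — and reads the premature share off the
mixture weight α. That makes the measure country-specific, but each
country is then judged against its *own* senescent curve, so a
long-lived country can paradoxically look worse than a short-lived one.

The package's core is a **hierarchical** compromise: a group of comparable
populations is assumed to share a single senescent curve while each keeps
its own premature component and weight,

&nbsp;&nbsp;&nbsp;&nbsp;d_j(x) = α_j·f_m(x; μ^m_j, σ^m_j, γ^m_j) + (1−α_j)·f_M(x; μ^M, σ^M, γ^M),&nbsp;&nbsp;&nbsp;&nbsp;x ≥ 5,

with skew-normal components in centered parametrization (mean, sd,
skewness; |γ| < 0.995). The model is Bayesian: α_j ~ U(0, 0.9), the
premature means and skewnesses are partially pooled through hyper-priors
(μ^m_j ~ N(60, σ²_{μ^m}) truncated above 75; γ^m_j ~ N(0, σ²_{γ^m})
truncated to [−0.8, 0.995]), and the shared senescent curve has informative
priors (μ^M ~ N(87, 4), σ^M ~ U(0, 9), γ^M a truncated skew-normal).
Because all countries in a group face the same senescent benchmark, their
α_j are directly comparable — premature mortality is measured *relative*
to a benchmark, but *absolutely* among countries sharing it.

All three measure families are implemented (`measures`, `relative`,
`hierarchical`), plus an HMD 1×1 life-table reader/writer
(`lifetable`), a synthetic-data generator with known truth (`synthetic`),
and a CLI (`premort simulate / fit-relative / fit-hierarchical /
measures`). Posterior sampling uses an affine-invariant ensemble sampler
on an unconstrained reparametrization; convergence is monitored with
split-R-hat.

## Worked example

Fit the bundled high-longevity scenario (four synthetic countries sharing
a senescent curve with mean 87, sd 6, skewness −0.5; true premature shares
0.05 / 0.12 / 0.20 / 0.30, 100 000 deaths each):

```python
import premort as pm

scenario = next(s for s in pm.preset_scenarios() if s.group_name == "high-longevity")
group = pm.generate_group(scenario)

post = pm.sample_posterior(
    group, mcmc=pm.McmcConfig(chains=2, warmup=400, iterations=300, seed=1)
)
print(pm.premature_prevalence(post).round(4).to_string(index=False))
```

```
country  alpha_mean  ci_low  ci_high   rhat  rank
   HL-A      0.0484  0.0452   0.0515 1.0051     1
   HL-B      0.1166  0.1125   0.1208 1.0023     2
   HL-C      0.1978  0.1932   0.2026 1.0134     3
   HL-D      0.2942  0.2889   0.2991 1.0061     4
```

`alpha_mean` is each country's posterior mean premature share — HL-D has
29.4% of adult deaths attributed to the premature component, and all four
estimates sit within a point of their generative truths. `rhat` near 1
indicates the chains mixed; `rank` orders countries from lowest premature
mortality (1) upward. Whether each country belongs in the group can be
checked with `pm.assess_group_fit(post, group)`, which reports a
total-variation dissimilarity between data and fitted model (here
0.009–0.011, far below the 0.05 flagging threshold).

The same workflow from the shell:

```sh
premort simulate --out data/
premort fit-hierarchical --config group.yaml --out results/ --seed 1
```

writes a comparison table (relative α, hierarchical α, m30–64 rate, the
three within-group rankings and R-hat), full posterior draws, and a
provenance record.

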