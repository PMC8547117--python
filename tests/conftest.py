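"""Shared fixtures: the central synthetic recovery study and fast MCMC settings.

The expensive hierarchical fits are session-scoped so several tests can
interrogate the same posterior.
"""

import numpy as np
import pytest

import premort as pm

#: Light MCMC settings for secondary fits (2 ensembles are enough to
#: diagnose mixing; the criterion-level recovery fit uses the defaults).
FAST_MCMC = dict(chains=2, warmup=400, iterations=300)


@pytest.fixture(scope="session")
def recovery_scenario():
    """Four countries sharing senescent CP(87, 6, -0.5), true alpha 0.1..0.4,
    100k deaths each — the package's central parameter-recovery study."""
    return pm.SyntheticScenario(
        group_name="recovery",
        countries=(
            pm.CountrySpec("A", 0.10, pm.SkewNormalCP(60.0, 11.0, 0.05)),
            pm.CountrySpec("B", 0.20, pm.SkewNormalCP(59.0, 12.0, 0.10)),
            pm.CountrySpec("C", 0.30, pm.SkewNormalCP(61.0, 12.0, 0.00)),
            pm.CountrySpec("D", 0.40, pm.SkewNormalCP(58.0, 13.0, 0.15)),
        ),
        senescent=pm.SkewNormalCP(87.0, 6.0, -0.5),
        seed=42,
    )


@pytest.fixture(scope="session")
def recovery_group(recovery_scenario):
    return pm.generate_group(recovery_scenario)


@pytest.fixture(scope="session")
def recovery_posterior(recovery_group):
    return pm.sample_posterior(recovery_group, mcmc=pm.McmcConfig(seed=7))


def _member_densities(name, senescent, seed):
    scen = pm.SyntheticScenario(
        group_name=name,
        seed=seed,
        countries=(
            pm.CountrySpec("X1", 0.12, pm.SkewNormalCP(59.0, 12.0, 0.05)),
            pm.CountrySpec("X2", 0.22, pm.SkewNormalCP(60.0, 12.0, 0.10)),
        ),
        senescent=senescent,
    )
    return [pm.generate_density(scen, lab) for lab in ("X1", "X2")]


@pytest.fixture(scope="session")
def group_dependence_posteriors():
    """One fixed synthetic country fitted inside a high-longevity group
    (shared senescent mean 87) and inside a medium-longevity group (mean
    80).  Against the right-shifted benchmark more of its deaths count as
    premature, so its alpha must come out larger in the first fit."""
    target = pm.SyntheticScenario(
        group_name="target",
        seed=99,
        countries=(pm.CountrySpec("TGT", 0.15, pm.SkewNormalCP(58.0, 12.0, 0.05)),),
        senescent=pm.SkewNormalCP(84.0, 6.5, -0.4),
    )
    tgt = pm.generate_density(target, "TGT")
    high = pm.GroupData(
        ["TGT", "X1", "X2"],
        [tgt] + _member_densities("h", pm.SkewNormalCP(87.0, 6.0, -0.5), 7),
        "high-longevity",
    )
    med = pm.GroupData(
        ["TGT", "X1", "X2"],
        [tgt] + _member_densities("m", pm.SkewNormalCP(80.0, 7.0, -0.4), 8),
        "medium-longevity",
    )
    cfg = pm.McmcConfig(seed=5, **FAST_MCMC)
    return (
        pm.sample_posterior(high, mcmc=cfg),
        pm.sample_posterior(med, mcmc=cfg),
    )


@pytest.fixture(scope="session")
def hmd_file(tmp_path_factory, recovery_scenario):
    """A synthetic two-year HMD-layout file plus its source tables."""
    path = tmp_path_factory.mktemp("hmd") / "SYN.lt_1x1.txt"
    tables = []
    for year in (2010, 2011):
        dens = pm.generate_density(recovery_scenario, "B")
        tables.append(pm.density_to_lifetable(dens, "SYN", year))
    pm.write_hmd_file(tables, path)
    return path, tables
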