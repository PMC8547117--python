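"""Absolute (threshold-based) measures of premature mortality.

These are the classical measures the mixture approaches are compared
against: death rates in an age band (e.g. m30-64), the fraction of deaths
below a fixed age threshold, and potential years of life lost (PYLL)
against a standard life expectancy (SLE).  All are computed within the
life table itself — dx over Lx — so no external standard population is
needed: the life table is already standardized for age structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import DeathDensity, LifeTable, to_death_density

__all__ = [
    "ThresholdMeasureConfig",
    "banded_death_rate",
    "premature_fraction_below",
    "pyll",
    "measures_table",
]

#: GBD 2010 standard life expectancy at birth (years); the WHO Global
#: Health Estimates alternative is 91.93.
SLE_GBD_2010 = 86.01
SLE_WHO_GHE = 91.93


@dataclass
class ThresholdMeasureConfig:
    threshold_age: int = 70
    sle: float = SLE_GBD_2010
    lower_age: int = 30
    upper_age: int = 64

    def __post_init__(self) -> None:
        if not self.lower_age < self.upper_age:
            raise ValueError("lower_age must be below upper_age")
        if not self.sle > 0:
            raise ValueError("sle must be positive")


def banded_death_rate(table: LifeTable, lower: int, upper: int) -> float:
    """Life-table death rate in the inclusive age band [lower, upper].

    Sum of dx over the band divided by the person-years Lx lived in it —
    the stationary-population analogue of an age-standardized rate.
    """
    if lower < table.ages[0] or upper > table.ages[-1]:
        raise ValueError("band outside table age range")
    band = (table.ages >= lower) & (table.ages <= upper)
    py = table.Lx[band].sum()
    if py <= 0:
        raise ValueError("zero person-years in band")
    return float(table.dx[band].sum() / py)


def premature_fraction_below(density: DeathDensity, threshold: int) -> float:
    """Fraction of deaths occurring below the threshold age."""
    return float(density.weights[density.ages < threshold].sum())


def pyll(table: LifeTable, sle: float, ax_offset: float = 0.5) -> float:
    """Potential years of life lost against a standard life expectancy.

    Each death at age x contributes max(0, sle - (x + ax_offset)) years,
    with deaths placed mid-interval by default; deaths above the SLE
    contribute nothing.  Units: years per life-table cohort (radix deaths).
    """
    if sle <= 0:
        raise ValueError("sle must be positive")
    remaining = np.maximum(0.0, sle - (table.ages + ax_offset))
    return float(table.dx @ remaining)


def measures_table(
    tables: list[LifeTable], config: ThresholdMeasureConfig | None = None
) -> pd.DataFrame:
    """Absolute measures for several life tables, in long (tidy) form."""
    config = config or ThresholdMeasureConfig()
    rows = []
    for t in tables:
        dens = to_death_density(t, min_age=0)
        items = {
            f"m{config.lower_age}-{config.upper_age}": banded_death_rate(
                t, config.lower_age, config.upper_age
            ),
            f"frac_below_{config.threshold_age}": premature_fraction_below(
                dens, config.threshold_age
            ),
            "frac_below_65": premature_fraction_below(dens, 65),
            "frac_below_75": premature_fraction_below(dens, 75),
            f"pyll_sle_{config.sle:g}": pyll(t, config.sle),
        }
        for measure, value in items.items():
            rows.append(
                {
                    "population": t.population_id,
                    "year": t.year,
                    "measure": measure,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
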