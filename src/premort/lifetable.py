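"""Life-table input/output and age-at-death distributions.

Reads period life tables in the Human Mortality Database (HMD) 1x1 text
layout, turns their ``dx`` column into a normalized age-at-death
distribution ``d(x)`` and pools several populations into a group-level
"super-country" distribution.  ``d(x)`` is used instead of observed death
counts because the life table is already standardized with respect to the
population age structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "DeathDensity",
    "read_hmd_lifetable",
    "to_death_density",
    "pool_group",
]

HMD_COLUMNS = ["Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"]


@dataclass
class LifeTable:
    """One population-year of an HMD-style period life table.

    ``dx`` is the life-table deaths column (radix-scaled), ``lx`` the
    survivors, ``Lx`` person-years lived and ``mx`` the central death rate.
    ``open_age`` is the terminal age of the open interval (e.g. 110 for
    "110+"); its deaths are carried on the single terminal age.
    """

    population_id: str
    year: int
    ages: np.ndarray
    dx: np.ndarray
    lx: np.ndarray
    Lx: np.ndarray
    mx: np.ndarray
    radix: float = 100_000.0
    open_age: int = 110

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        for name in ("dx", "lx", "Lx", "mx"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.ages[0] != 0 or not np.all(np.diff(self.ages) == 1):
            raise ValueError("ages must be 0..open_age in single-year steps")
        n = len(self.ages)
        if any(len(getattr(self, c)) != n for c in ("dx", "lx", "Lx", "mx")):
            raise ValueError("all columns must have the same length as ages")
        if abs(self.dx.sum() - self.radix) > 0.5:
            raise ValueError(
                f"sum(dx)={self.dx.sum():.2f} differs from radix {self.radix} by more "
                "than the 0.5 rounding slack of published tables"
            )
        if abs(self.lx[0] - self.radix) > 0.5:
            raise ValueError("lx[0] must equal the radix")
        if np.any(np.diff(self.lx) > 1e-9):
            raise ValueError("lx must be non-increasing in age")


@dataclass
class DeathDensity:
    """Normalized age-at-death distribution on a discrete age grid.

    ``weights`` are nonnegative proportions summing to one over
    ``ages = min_age..open_age``.  ``effective_n`` is the pseudo-count used
    as the multinomial sample size by the fitting likelihoods; it defaults
    to the radix-scaled death count above ``min_age``.
    """

    ages: np.ndarray
    weights: np.ndarray
    min_age: int = 5
    effective_n: float = 100_000.0
    label: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.ages) != len(self.weights):
            raise ValueError("ages and weights must have equal length")
        if self.ages[0] != self.min_age:
            raise ValueError(f"ages must start at min_age={self.min_age}")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")
        if not self.effective_n > 0:
            raise ValueError("effective_n must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "weight": self.weights})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_hmd_lifetable(path, year: int, population_id: str | None = None) -> LifeTable:
    """Read one year's table from an HMD 1x1 period life-table text file.

    The layout is a title line and a blank line followed by a header row
    (``Year Age mx qx ax lx dx Lx Tx ex``) and whitespace-separated data
    rows; the open age interval is written "110+".
    """
    path = str(path)
    rows: list[list[str]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if not header_seen:
                if toks[0] == "Year":
                    header_seen = True
                continue
            if len(toks) != len(HMD_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(HMD_COLUMNS)} columns, "
                    f"got {len(toks)}"
                )
            rows.append(toks)
    if not header_seen:
        raise ValueError(f"{path}: no HMD column header line found")
    df = pd.DataFrame(rows, columns=HMD_COLUMNS)
    df["Year"] = df["Year"].astype(int)
    sub = df[df["Year"] == year]
    if sub.empty:
        years = sorted(df["Year"].unique())
        raise ValueError(
            f"year not found: {year} (file covers {years[0]}..{years[-1]})"
        )
    open_mask = sub["Age"].str.endswith("+")
    ages = sub["Age"].str.rstrip("+").astype(int).to_numpy()
    open_age = int(ages[open_mask.to_numpy()][0]) if open_mask.any() else int(ages[-1])
    num = sub.drop(columns=["Year", "Age"]).apply(pd.to_numeric, errors="coerce")
    if population_id is None:
        population_id = _title_population(path)
    dx = num["dx"].to_numpy()
    return LifeTable(
        population_id=population_id,
        year=year,
        ages=ages,
        dx=dx,
        lx=num["lx"].to_numpy(),
        Lx=num["Lx"].to_numpy(),
        mx=num["mx"].to_numpy(),
        radix=float(num["lx"].iloc[0]),
        open_age=open_age,
    )


def _title_population(path: str) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    return first.split(",")[0] if first else path


def to_death_density(table: LifeTable, min_age: int = 5) -> DeathDensity:
    """Normalize the ``dx`` column above ``min_age`` into a DeathDensity.

    Infant and child deaths below ``min_age`` are discarded; the remaining
    deaths are renormalized to a probability vector.  ``effective_n`` is
    the retained death count.
    """
    if min_age < table.ages[0] or min_age > table.ages[-1]:
        raise ValueError(f"min_age {min_age} outside table range")
    keep = table.ages >= min_age
    dx = table.dx[keep]
    total = dx.sum()
    if total <= 0:
        raise ValueError(f"no deaths above age {min_age}")
    return DeathDensity(
        ages=table.ages[keep],
        weights=dx / total,
        min_age=min_age,
        effective_n=float(total),
        label=f"{table.population_id}:{table.year}",
    )


def pool_group(densities: list[DeathDensity], label: str = "pooled") -> DeathDensity:
    """Pool populations into a "super-country" age-at-death distribution.

    Countries enter with equal weight (each life table is already
    standardized), so the pooled distribution is the arithmetic mean of the
    member weight vectors, renormalized; ``effective_n`` adds up.
    """
    if not densities:
        raise ValueError("need at least one density to pool")
    ref = densities[0]
    for d in densities[1:]:
        if d.min_age != ref.min_age or not np.array_equal(d.ages, ref.ages):
            raise ValueError("all densities must share the same age grid and min_age")
    w = np.mean([d.weights for d in densities], axis=0)
    return DeathDensity(
        ages=ref.ages.copy(),
        weights=w / w.sum(),
        min_age=ref.min_age,
        effective_n=float(sum(d.effective_n for d in densities)),
        label=label,
    )
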