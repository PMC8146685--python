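"""Period life tables: background all-cause mortality for the cohort model.

A period life table gives, for each integer age ``x``, the probability
``q_x`` of dying within the year conditional on being alive at age ``x``.
The model uses these as the "other-cause" death hazard acting alongside
tumour-specific mortality; per the source data convention the rates are
used without subtracting neuroendocrine-tumour deaths (they are a
negligible share of national all-cause mortality).

Because a monthly-cycle model needs per-cycle probabilities, annual
``q_x`` values are converted with the constant-hazard-within-year rule
``1 - (1 - q)**(1/12)``.

The module also generates synthetic Gompertz-Makeham tables so that tests
and analyses never depend on an external download, and ships one such
table calibrated to the approximate level and slope of recent US all-cause
mortality (see :func:`load_bundled_life_table`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "read_life_table",
    "write_life_table",
    "synth_life_table",
    "annual_to_cycle_prob",
    "life_expectancy",
    "load_bundled_life_table",
    "US_LIKE_GOMPERTZ_MAKEHAM",
]

#: Gompertz-Makeham parameters used for the bundled synthetic table.
#: Hazard mu(x) = a*exp(b*x) + c, calibrated against the approximate
#: anchor values of recent US both-sex period tables: q(60) ~ 0.009,
#: q(70) ~ 0.021, q(80) ~ 0.055, q(90) ~ 0.158, with remaining life
#: expectancy at 60 of roughly 22-23 years and ~1.5% of 60-year-olds
#: surviving to 100.
US_LIKE_GOMPERTZ_MAKEHAM = {"a": 2.0e-5, "b": 0.10, "c": 6.0e-4}

_BUNDLED_NAME = "us_like_synthetic_lifetable.csv"


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities.

    Parameters
    ----------
    ages
        Contiguous integer ages, ascending with step 1.
    q_annual
        Probability of death within the year at each age; the terminal
        age must carry ``q = 1`` (the table closes out the cohort).
    """

    ages: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != q.shape:
            raise ValueError("ages and q_annual must be equal-length 1-D arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous and ascending with step 1")
        if np.any((q < 0.0) | (q > 1.0)):
            bad = int(ages[np.argmax((q < 0.0) | (q > 1.0))])
            raise ValueError(f"q_annual outside [0, 1] at age {bad}")
        if q[-1] != 1.0:
            raise ValueError("terminal age must have q_annual == 1")

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age: int | float) -> float:
        """Annual death probability at ``floor(age)``."""
        a = int(np.floor(age))
        if a < self.age_min or a > self.age_max:
            raise ValueError(f"age {age} outside table range "
                             f"[{self.age_min}, {self.age_max}]")
        return float(self.q_annual[a - self.age_min])

    def survival_curve(self, start_age: int) -> np.ndarray:
        """S(k): probability of surviving k whole years from ``start_age``.

        S(0) = 1; the curve reaches exactly 0 at the terminal age because
        the table closes with q = 1.
        """
        if start_age < self.age_min or start_age > self.age_max:
            raise ValueError(f"start_age {start_age} outside table range")
        q = self.q_annual[start_age - self.age_min:]
        return np.concatenate([[1.0], np.cumprod(1.0 - q)])


def read_life_table(source) -> LifeTable:
    """Read a two-column ``age,qx`` CSV (header optional) into a LifeTable.

    Duplicate or non-contiguous ages and out-of-range probabilities are
    rejected with an error naming the offending row.
    """
    df = pd.read_csv(source, header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] != 2:
        raise ValueError(f"expected 2 columns (age, qx), got {df.shape[1]}")
    # tolerate a header row: drop it if the first cell is not numeric
    first = df.iloc[0, 0]
    if not str(first).strip().lstrip("-").replace(".", "", 1).isdigit():
        df = df.iloc[1:]
    try:
        ages = df.iloc[:, 0].astype(float).to_numpy()
        q = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"malformed life-table row: {exc}") from exc
    if np.any(ages != np.round(ages)):
        bad = ages[np.argmax(ages != np.round(ages))]
        raise ValueError(f"non-integer age {bad}")
    order = np.argsort(ages)
    ages = ages[order].astype(int)
    q = q[order]
    if np.any(np.diff(ages) == 0):
        dup = int(ages[np.argmax(np.diff(ages) == 0)])
        raise ValueError(f"duplicate age {dup}")
    return LifeTable(ages=ages, q_annual=q)


def write_life_table(lt: LifeTable, dest) -> None:
    """Write ``age,qx`` CSV with header; inverse of :func:`read_life_table`."""
    pd.DataFrame({"age": lt.ages, "qx": lt.q_annual}).to_csv(dest, index=False)


def synth_life_table(a: float, b: float, c: float = 0.0,
                     age_min: int = 0, age_max: int = 100) -> LifeTable:
    """Generate a Gompertz-Makeham life table.

    The hazard is ``mu(x) = a*exp(b*x) + c``; integrating over one year of
    age gives the annual death probability

    ``q(x) = 1 - exp(-c - (a/b) * (exp(b*(x+1)) - exp(b*x)))``

    clamped to [0, 1], with the terminal age forced to ``q = 1``.

    Parameters
    ----------
    a : baseline (age-zero) Gompertz hazard, per year; must be > 0.
    b : Gompertz slope (log-hazard increase per year of age); must be > 0.
    c : Makeham age-independent hazard, per year; must be >= 0.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Gompertz parameters a and b must be positive")
    if c < 0:
        raise ValueError("Makeham constant c must be non-negative")
    if age_min >= age_max:
        raise ValueError("age_min must be < age_max")
    ages = np.arange(age_min, age_max + 1)
    cum_haz = c + (a / b) * (np.exp(b * (ages + 1.0)) - np.exp(b * ages))
    q = np.clip(1.0 - np.exp(-cum_haz), 0.0, 1.0)
    q[-1] = 1.0
    return LifeTable(ages=ages, q_annual=q)


def annual_to_cycle_prob(q_annual: float, cycles_per_year: int) -> float:
    """Convert an annual death probability to a per-cycle probability.

    Assumes a constant hazard within the year, so that compounding the
    per-cycle probability ``cycles_per_year`` times recovers ``q_annual``.
    """
    if not 0.0 <= q_annual <= 1.0:
        raise ValueError(f"q_annual must be in [0, 1], got {q_annual}")
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be a positive integer")
    if q_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - q_annual) ** (1.0 / cycles_per_year)


def life_expectancy(lt: LifeTable, start_age: int) -> float:
    """Expected remaining years at ``start_age``, trapezoid-corrected.

    Sums the annual survival curve with a within-year trapezoidal
    correction (deaths are credited half the year in which they occur).
    Serves as an independent oracle for the Markov engine in the
    no-disease limit.
    """
    s = lt.survival_curve(start_age)
    return float(np.sum(0.5 * (s[:-1] + s[1:])))


def load_bundled_life_table() -> LifeTable:
    """Load the synthetic US-like life table shipped with the package.

    The table is generated from :data:`US_LIKE_GOMPERTZ_MAKEHAM` (it is a
    synthetic stand-in at the approximate level of recent US all-cause
    mortality, not a published national table) and stored under version
    control so analyses are fully self-contained.
    """
    text = resources.files("gepnet_cea.data").joinpath(_BUNDLED_NAME).read_text()
    return read_life_table(io.StringIO(text))
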