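"""Age-specific non-stroke background mortality.

The cohort model removes members by background (non-stroke) mortality in
every monthly cycle. The inputs are an all-cause life table (annual death
probabilities ``qx`` by integer age), a ``stroke_fraction`` giving the
share of all-cause deaths attributed to stroke (removed, because stroke
deaths are modeled explicitly through recurrence), and an mRS-dependent
hazard ratio reflecting the excess mortality of disabled survivors.

Conversion chain for a member of age ``a`` in state ``mrs``::

    annual non-stroke hazard  h = -ln(1 - qx(floor(a))) * (1 - stroke_fraction)
    monthly death probability p = 1 - exp(-(h / 12) * hr(mrs))

The bundled default table is a Gompertz fixture (exponentially increasing
hazard) calibrated so that remaining life expectancy at age 65 is about
19 years, of the order of recent Chinese period life tables; any official
table can be substituted from CSV (columns ``age,qx``).
"""

from __future__ import annotations

import functools
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "load_life_table",
    "gompertz_life_table",
    "default_life_table",
    "calibrate_gompertz",
    "monthly_background_death",
    "DEFAULT_STROKE_FRACTION",
    "DEFAULT_GOMPERTZ_GROWTH",
]

#: share of all-cause deaths attributed to cerebrovascular disease and
#: removed from the background hazard. A calibration input: set it to the
#: stroke share of deaths in the population the life table describes.
DEFAULT_STROKE_FRACTION = 0.22

#: per-year log-hazard slope of the default Gompertz fixture
DEFAULT_GOMPERTZ_GROWTH = 0.09


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities over a contiguous span of integer ages."""

    ages: np.ndarray
    qx: np.ndarray
    stroke_fraction: float = DEFAULT_STROKE_FRACTION
    source: str = "in-memory"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != qx.shape:
            raise ValueError("life table needs matching 1-D age and qx columns")
        gaps = np.flatnonzero(np.diff(ages) != 1)
        if gaps.size:
            raise ValueError(f"life table ages not contiguous: gap after age {ages[gaps[0]]}")
        bad = np.flatnonzero((qx < 0) | (qx > 1))
        if bad.size:
            raise ValueError(f"qx out of [0, 1] at age {ages[bad[0]]}: {qx[bad[0]]}")
        if not 0.0 <= self.stroke_fraction < 1.0:
            raise ValueError("stroke_fraction must lie in [0, 1)")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def covers(self, low: float, high: float) -> bool:
        return self.min_age <= low and high <= self.max_age + 1

    def annual_qx(self, age: float) -> float:
        """All-cause annual death probability at the integer floor of ``age``."""
        ia = math.floor(age)
        if not self.min_age <= ia <= self.max_age:
            raise ValueError(f"age {age} outside life-table coverage "
                             f"[{self.min_age}, {self.max_age}]")
        return float(self.qx[ia - self.min_age])

    def life_expectancy(self, from_age: int | None = None) -> float:
        """Remaining life expectancy from ``from_age`` (default: first age).

        Curtate expectation from the tabulated span plus the customary
        half-year for the year of death; survival beyond the last
        tabulated age is ignored, so the table should extend well past
        the ages of interest.
        """
        start = self.min_age if from_age is None else int(from_age)
        if not self.min_age <= start <= self.max_age:
            raise ValueError(f"age {start} outside life-table coverage")
        surv = np.cumprod(1.0 - self.qx[start - self.min_age:])
        return float(surv.sum()) + 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def save(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(path: str | os.PathLike,
                    stroke_fraction: float = DEFAULT_STROKE_FRACTION) -> LifeTable:
    """Read a life table from CSV with columns ``age,qx``."""
    df = pd.read_csv(path)
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise ValueError(f"life-table CSV {path} lacks column(s): {sorted(missing)}")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy(),
                     stroke_fraction=stroke_fraction, source=str(path))


def gompertz_life_table(h0: float,
                        growth: float = DEFAULT_GOMPERTZ_GROWTH,
                        age_range: tuple[int, int] = (65, 110),
                        stroke_fraction: float = DEFAULT_STROKE_FRACTION) -> LifeTable:
    """Life table with Gompertz hazard ``h(a) = h0 * exp(growth * (a - a0))``.

    ``qx(a) = 1 - exp(-h(a))``; ``a0`` is the first age of ``age_range``.
    """
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    if growth < 0:
        raise ValueError("growth must be >= 0")
    ages = np.arange(age_range[0], age_range[1] + 1)
    hazard = h0 * np.exp(growth * (ages - ages[0]))
    qx = 1.0 - np.exp(-hazard)
    return LifeTable(ages, qx, stroke_fraction=stroke_fraction,
                     source=f"gompertz(h0={h0:.6g}, growth={growth:g})")


def calibrate_gompertz(target_e0: float = 19.0,
                       growth: float = DEFAULT_GOMPERTZ_GROWTH,
                       age_range: tuple[int, int] = (65, 110)) -> float:
    """Solve for the Gompertz ``h0`` giving a chosen remaining life expectancy.

    Bisection on ``h0``; life expectancy is monotone decreasing in ``h0``.
    """
    lo, hi = 1e-6, 0.5
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        e = gompertz_life_table(mid, growth, age_range).life_expectancy()
        if e > target_e0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@functools.lru_cache(maxsize=8)
def _default_h0(target_e0: float, growth: float) -> float:
    return calibrate_gompertz(target_e0, growth)


def default_life_table(stroke_fraction: float = DEFAULT_STROKE_FRACTION,
                       e65: float = 19.0,
                       growth: float = DEFAULT_GOMPERTZ_GROWTH) -> LifeTable:
    """The bundled background-mortality fixture.

    A Gompertz table over ages 65-110 calibrated so that remaining life
    expectancy at 65 equals ``e65`` (default 19 years).
    """
    return gompertz_life_table(_default_h0(e65, growth), growth,
                               stroke_fraction=stroke_fraction)


def monthly_background_death(lt: LifeTable, age: float, mrs: int,
                             hr_by_mrs) -> float:
    """Monthly non-stroke death probability for one mRS state at one age."""
    if not 0 <= mrs <= 5:
        raise ValueError(f"mrs must be 0..5, got {mrs}")
    qx = lt.annual_qx(age)
    annual_hazard = -math.log1p(-qx) * (1.0 - lt.stroke_fraction)
    hr = hr_by_mrs[mrs]
    return -math.expm1(-(annual_hazard / 12.0) * hr)
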