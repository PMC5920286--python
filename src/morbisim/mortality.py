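"""Mortality schedules, monthly survival and period lifetables.

The engine consumes an annual survival schedule by calendar year, sex and
single year of age (probability of death ``q`` within the year), converted to
monthly survival under a constant within-year hazard.  The same schedule
feeds the period lifetable used by Sullivan's method: survivorship ``l_x``
from radix 100,000, person-years ``L_x = l_x - 0.5 d_x`` (deaths mid
interval) and remaining life expectancy ``e_x``.

The national projection schedule the model was designed around is external
data; :func:`make_toy_schedule` provides a Gompertz schedule with a calendar
improvement factor, calibrated so that 2015 life expectancy at 65 is close
to the English magnitudes (about 18.6 years for men, 21.2 for women).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ScheduleError
from .state import SEX_LEVELS

RADIX = 100_000.0
TERMINAL_AGE = 105
MIN_AGE = 35

# Gompertz hazard h(age) = A * exp(B * age), sex-specific level, with an
# annual improvement factor on the hazard; A chosen so that e65(2015) is
# ~18.6 (men) / ~21.2 (women) under B and the improvement below.
GOMPERTZ_B = 0.105
GOMPERTZ_A = {"male": 1.300e-5, "female": 9.268e-6}
ANNUAL_IMPROVEMENT = 0.015
BASE_YEAR = 2015


def annual_to_monthly_survival(q_annual) -> float:
    """Monthly survival probability implied by an annual death probability.

    ``(1 - q)**(1/12)``: compounding twelve months reproduces ``1 - q``.
    """
    q = np.asarray(q_annual, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise DomainError("annual death probability outside [0, 1]")
    out = (1.0 - q) ** (1.0 / 12.0)
    return float(out) if np.ndim(q_annual) == 0 else out


@dataclass
class MortalitySchedule:
    """Annual death probabilities by (calendar_year, sex, age)."""

    table: pd.DataFrame  # columns: year, sex, age, q

    def __post_init__(self) -> None:
        t = self.table
        required = {"year", "sex", "age", "q"}
        if not required.issubset(t.columns):
            raise ScheduleError(f"schedule needs columns {sorted(required)}")
        if ((t["q"] < 0) | (t["q"] > 1)).any():
            raise ScheduleError("q outside [0, 1]")
        for (year, sex), grp in t.groupby(["year", "sex"]):
            ages = np.sort(grp["age"].to_numpy())
            expected = np.arange(MIN_AGE, ages.max() + 1)
            if ages[0] != MIN_AGE or not np.array_equal(ages, expected):
                raise ScheduleError(
                    f"ages not contiguous from {MIN_AGE} for ({year}, {sex})")
            terminal_q = grp.loc[grp["age"] == ages.max(), "q"].iloc[0]
            if terminal_q != 1.0:
                raise ScheduleError(
                    f"terminal age q must be 1 for ({year}, {sex})")
        self._years = np.sort(t["year"].unique())
        self._terminal = int(t["age"].max())
        # dense lookup q[year_idx, sex_code, age - MIN_AGE]
        n_ages = self._terminal - MIN_AGE + 1
        self._q = np.full((len(self._years), 2, n_ages), np.nan)
        yi = {y: i for i, y in enumerate(self._years)}
        si = {s: i for i, s in enumerate(SEX_LEVELS)}
        for row in t.itertuples(index=False):
            self._q[yi[row.year], si[row.sex], int(row.age) - MIN_AGE] = row.q
        if np.isnan(self._q).any():
            raise ScheduleError("incomplete (year, sex) coverage")

    @property
    def terminal_age(self) -> int:
        return self._terminal

    @property
    def years(self) -> np.ndarray:
        return self._years

    def q_for(self, year: int, sex: str, age: int) -> float:
        return float(self.q_lookup(year)[SEX_LEVELS.index(sex), age - MIN_AGE])

    def q_lookup(self, year: int) -> np.ndarray:
        """Dense (sex, age) -> q array for one year; clamps to known years."""
        idx = int(np.clip(np.searchsorted(self._years, year), 0,
                          len(self._years) - 1))
        if self._years[idx] != year:
            # use nearest available year at the boundaries only
            if year < self._years[0] or year > self._years[-1]:
                idx = 0 if year < self._years[0] else len(self._years) - 1
            else:
                raise ScheduleError(f"no schedule for year {year}")
        return self._q[idx]

    def monthly_survival_lookup(self, year: int) -> np.ndarray:
        return annual_to_monthly_survival(self.q_lookup(year))

    @classmethod
    def from_csv(cls, path) -> "MortalitySchedule":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class LifeTable:
    """Period lifetable from a start age: l_x, L_x, e_x."""

    ages: np.ndarray
    l: np.ndarray
    L: np.ndarray
    e: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "l": self.l,
                             "L": self.L, "e": self.e})

    @property
    def e_start(self) -> float:
        return float(self.e[0])


def build_lifetable(schedule: MortalitySchedule, year: int, sex: str,
                    start_age: int = 65) -> LifeTable:
    """Build the period lifetable implied by one year's schedule.

    ``l_{x+1} = l_x (1 - q_x)``, ``L_x = l_x - 0.5 d_x`` and
    ``e_x = sum_{y >= x} L_y / l_x``.  The terminal age has ``q = 1`` so the
    table closes itself with ``L = 0.5 l``.
    """
    qs = schedule.q_lookup(year)[SEX_LEVELS.index(sex)]
    if start_age < MIN_AGE or start_age > schedule.terminal_age:
        raise ScheduleError(f"start_age {start_age} outside schedule range")
    q = qs[start_age - MIN_AGE:]
    ages = np.arange(start_age, schedule.terminal_age + 1)
    n = len(q)
    l = np.empty(n)
    l[0] = RADIX
    for i in range(n - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q
    L = l - 0.5 * d
    # e_x = reverse cumulative person-years / l_x
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return LifeTable(ages=ages, l=l, L=L, e=e)


def make_toy_schedule(years=range(2014, 2036), *,
                      a: dict | None = None, b: float = GOMPERTZ_B,
                      improvement: float = ANNUAL_IMPROVEMENT,
                      terminal_age: int = TERMINAL_AGE) -> MortalitySchedule:
    """Gompertz-like annual schedule with calendar improvement.

    ``q(age, sex, year) = 1 - exp(-A_sex * exp(B*age) * (1-r)^(year-2015))``,
    closed with ``q = 1`` at the terminal age.
    """
    a = dict(GOMPERTZ_A if a is None else a)
    rows = []
    ages = np.arange(MIN_AGE, terminal_age + 1)
    for year in years:
        factor = (1.0 - improvement) ** (year - BASE_YEAR)
        for sex in SEX_LEVELS:
            h = a[sex] * np.exp(b * ages) * factor
            q = 1.0 - np.exp(-h)
            q[-1] = 1.0
            for age, qq in zip(ages, q):
                rows.append((year, sex, int(age), float(qq)))
    return MortalitySchedule(pd.DataFrame(rows,
                                          columns=["year", "sex", "age", "q"]))
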