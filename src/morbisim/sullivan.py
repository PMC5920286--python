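"""Sullivan health expectancy and decomposition of change.

Sullivan's method splits remaining life expectancy at a reference age into
years lived in each morbidity category by weighting lifetable person-years
``L_x`` with the age-specific category prevalence ``pi_c(x)``:

    years_c = (1 / l_from) * sum_{x >= from} pi_c(x) * L_x

Because the prevalence vectors sum to one at every age, category years sum
exactly to total life expectancy.

The change in category years between two settings (two projection years) is
decomposed into a mortality (survival) component and a prevalence component
by symmetric two-way stepwise replacement: each component is the average of
the two single-step replacements, so the two components are
order-independent and sum exactly to the total change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .mortality import LifeTable
from .state import ConditionSet, SEX_LEVELS
from .tables import MM_CATEGORIES, condition_counts, round1


@dataclass
class PrevalenceSurface:
    """Per-age probability vector over morbidity categories {0,1,2,3,4+}."""

    ages: np.ndarray            # (n_ages,)
    probs: np.ndarray           # (n_ages, 5), rows sum to 1
    categories: tuple[str, ...] = MM_CATEGORIES

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.ages), len(self.categories)):
            raise InputError("surface shape mismatch")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("surface rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(self.categories))
        df.insert(0, "age", self.ages)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrevalenceSurface":
        cats = tuple(c for c in df.columns if c != "age")
        return cls(ages=df["age"].to_numpy(),
                   probs=df[list(cats)].to_numpy(), categories=cats)


def surface_from_snapshot(snapshot: pd.DataFrame, cset: ConditionSet,
                          sex: str, ages: np.ndarray,
                          band_years: int = 5) -> PrevalenceSurface:
    """Estimate a category-prevalence surface from one snapshot.

    Prevalence is pooled over ``band_years``-wide age bands (single-year
    cells are noisy at reduced sample size) and assigned to every single
    year of age in the band; ages beyond the oldest populated band reuse
    the last band's distribution.
    """
    ages = np.asarray(ages, dtype=int)
    sub = snapshot[snapshot["sex"] == SEX_LEVELS.index(sex)]
    age_years = sub["age_months"].to_numpy() // 12
    raw = np.minimum(condition_counts(sub, cset), 4)
    k = len(MM_CATEGORIES)
    probs = np.zeros((len(ages), k))
    last = None
    for i, age in enumerate(ages):
        lo = age - (age - ages[0]) % band_years
        in_band = (age_years >= lo) & (age_years < lo + band_years)
        if in_band.sum() == 0:
            if last is None:
                raise InputError(f"no observations at or below age {age}")
            probs[i] = last
            continue
        counts = np.bincount(raw[in_band], minlength=k)
        probs[i] = counts / counts.sum()
        last = probs[i]
    return PrevalenceSurface(ages=ages, probs=probs)


@dataclass
class HealthExpectancyResult:
    """Total LE at the reference age, years and % share per category."""

    from_age: int
    total_le: float
    years: dict[str, float]
    shares: dict[str, float]

    def years_at_least(self, k: int) -> float:
        """Years lived with k or more conditions (e.g. k=2: multi-morbid)."""
        return float(sum(v for c, v in self.years.items()
                         if (4 if c == "4+" else int(c)) >= k))


def sullivan(lifetable: LifeTable, surface: PrevalenceSurface,
             from_age: int = 65) -> HealthExpectancyResult:
    """Years lived in each morbidity category from ``from_age``."""
    sel = lifetable.ages >= from_age
    ages = lifetable.ages[sel]
    missing = np.setdiff1d(ages, surface.ages)
    if len(missing):
        raise InputError(f"surface missing ages {missing.tolist()}")
    order = {a: i for i, a in enumerate(surface.ages)}
    pi = surface.probs[[order[a] for a in ages]]
    L = lifetable.L[sel]
    l0 = lifetable.l[sel][0]
    years_vec = pi.T @ L / l0
    total = float(L.sum() / l0)
    years = {c: float(y) for c, y in zip(surface.categories, years_vec)}
    shares = {c: (y / total * 100.0) for c, y in years.items()}
    return HealthExpectancyResult(from_age=from_age, total_le=total,
                                  years=years, shares=shares)


def share_of_le(years_in_state: float, total_le: float) -> float:
    """Percent of total life expectancy spent in a state, 1 dp."""
    if total_le <= 0:
        raise InputError("total life expectancy must be positive")
    if not 0 <= years_in_state <= total_le + 1e-12:
        raise InputError("years in state outside [0, total LE]")
    return round1(years_in_state / total_le * 100.0)


@dataclass
class DecompositionResult:
    """Change in category years split into mortality and prevalence parts."""

    category: str
    delta: float
    mortality_component: float
    prevalence_component: float

    @property
    def shares(self) -> dict[str, float]:
        if self.delta == 0:
            return {"mortality": np.nan, "prevalence": np.nan}
        return {
            "mortality": self.mortality_component / self.delta * 100.0,
            "prevalence": self.prevalence_component / self.delta * 100.0,
        }


def _years_at_least(lifetable, surface, category, from_age):
    res = sullivan(lifetable, surface, from_age)
    if category == "2+":
        return res.years_at_least(2)
    if category == "4+":
        return res.years_at_least(4)
    return res.years[category]


def decompose_change(lt_a: LifeTable, surf_a: PrevalenceSurface,
                     lt_b: LifeTable, surf_b: PrevalenceSurface,
                     category: str, from_age: int = 65,
                     ) -> DecompositionResult:
    """Symmetric two-way stepwise-replacement decomposition.

    mortality = mean over prevalence settings of the effect of swapping the
    lifetable; prevalence = mean over lifetables of the effect of swapping
    the surface.  The two components sum exactly to the total change
    ``S(b,b) - S(a,a)``.
    """
    S = {(i, j): _years_at_least(lt, surf, category, from_age)
         for i, lt in (("a", lt_a), ("b", lt_b))
         for j, surf in (("a", surf_a), ("b", surf_b))}
    mortality = 0.5 * ((S["b", "a"] - S["a", "a"])
                       + (S["b", "b"] - S["a", "b"]))
    prevalence = 0.5 * ((S["a", "b"] - S["a", "a"])
                        + (S["b", "b"] - S["b", "a"]))
    return DecompositionResult(category=category,
                               delta=S["b", "b"] - S["a", "a"],
                               mortality_component=mortality,
                               prevalence_component=prevalence)
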