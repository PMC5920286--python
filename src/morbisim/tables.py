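"""Reporting surfaces: prevalence, multi-morbidity distributions and
percent-change summaries.

Conventions mirror the usual presentation of projection tables: prevalence
as a percentage of the alive population in a (year, age-group) stratum to
one decimal place, counts scaled to population persons and rounded to the
nearest hundred, and percent change computed on the scaled counts with
half-away-from-zero rounding to one decimal place.  Rounding is applied
only at this reporting layer.
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import SimulationOutput
from .errors import InputError
from .state import (CIND_MMSE_CUTOFF, ConditionSet, MENTAL_ILL_HEALTH)

#: reporting age groups (label -> [lower, upper) in years)
REPORT_AGE_GROUPS = {
    "65-74": (65, 75),
    "75-84": (75, 85),
    "85+": (85, 1000),
    "65+": (65, 1000),
}

MM_CATEGORIES = ("0", "1", "2", "3", "4+")


def round1(x: float) -> float:
    """Round to 1 decimal place, ties away from zero (printed-table style)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


def round_count(x: float) -> int:
    """Round a scaled count to the nearest hundred."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1E2"),
                                                rounding=ROUND_HALF_UP))


def percent_change(n_start: float, n_end: float) -> float:
    """Percent change from ``n_start`` to ``n_end``, 1 dp."""
    if n_start <= 0:
        raise InputError("percent change undefined for n_start <= 0")
    return round1((n_end - n_start) / n_start * 100.0)


def condition_indicator(df: pd.DataFrame, member: str) -> np.ndarray:
    """0/1 presence of one condition; 'cind' derived from MMSE and dementia."""
    if member == "cind":
        return ((df["mmse"].to_numpy() <= CIND_MMSE_CUTOFF)
                & (df["dementia"].to_numpy() == 0)).astype(np.int64)
    if member not in df.columns:
        raise InputError(f"unknown condition column {member!r}")
    return df[member].to_numpy().astype(np.int64)


def condition_counts(df: pd.DataFrame, cset: ConditionSet) -> np.ndarray:
    """Raw number of member conditions present, per row."""
    total = np.zeros(len(df), dtype=np.int64)
    for m in cset.members:
        total += condition_indicator(df, m)
    return total


def categorise(raw: np.ndarray) -> np.ndarray:
    """Map raw counts to the {0,1,2,3,4+} categories."""
    capped = np.minimum(raw, 4)
    return np.array(MM_CATEGORIES)[capped]


def _snapshots_of(snapshots) -> Mapping[int, pd.DataFrame]:
    if isinstance(snapshots, SimulationOutput):
        return snapshots.snapshots
    return snapshots


def _age_years(df: pd.DataFrame) -> np.ndarray:
    return df["age_months"].to_numpy() // 12


def prevalence_table(snapshots, conditions, scale_factor: float = 100.0,
                     age_groups: Mapping | None = None) -> pd.DataFrame:
    """Prevalence of (and scaled numbers with) individual conditions.

    One row per (year, age_group, condition): percentage of the alive
    stratum with the condition (1 dp) and the scaled count (nearest 100).
    Empty strata produce a null row with a warning.
    """
    age_groups = REPORT_AGE_GROUPS if age_groups is None else age_groups
    rows = []
    for year, snap in sorted(_snapshots_of(snapshots).items()):
        age = _age_years(snap)
        for label, (lo, hi) in age_groups.items():
            stratum = snap[(age >= lo) & (age < hi)]
            n_alive = len(stratum)
            for cond in conditions:
                if n_alive == 0:
                    warnings.warn(f"empty stratum {year}/{label}",
                                  stacklevel=2)
                    rows.append((year, label, cond, np.nan, np.nan, 0))
                    continue
                present = int(condition_indicator(stratum, cond).sum())
                rows.append((year, label, cond,
                             round1(present / n_alive * 100.0),
                             round_count(present * scale_factor),
                             round_count(n_alive * scale_factor)))
    return pd.DataFrame(rows, columns=["year", "age_group", "condition",
                                       "prevalence_pct", "count",
                                       "stratum_count"])


def multimorbidity_table(snapshots, cset: ConditionSet,
                         scale_factor: float = 100.0,
                         age_groups: Mapping | None = None) -> pd.DataFrame:
    """Distribution over morbidity-count categories {0,1,2,3,4+} plus 2+.

    The 2+ row aggregates the 2, 3 and 4+ rows (multi-morbidity).
    """
    age_groups = REPORT_AGE_GROUPS if age_groups is None else age_groups
    rows = []
    for year, snap in sorted(_snapshots_of(snapshots).items()):
        age = _age_years(snap)
        raw_all = condition_counts(snap, cset)
        for label, (lo, hi) in age_groups.items():
            in_group = (age >= lo) & (age < hi)
            n_alive = int(in_group.sum())
            if n_alive == 0:
                warnings.warn(f"empty stratum {year}/{label}", stacklevel=2)
                for cat in MM_CATEGORIES + ("2+",):
                    rows.append((year, label, cat, np.nan, np.nan, 0))
                continue
            raw = raw_all[in_group]
            counts = {cat: int((np.minimum(raw, 4) == i).sum())
                      for i, cat in enumerate(MM_CATEGORIES)}
            counts["2+"] = counts["2"] + counts["3"] + counts["4+"]
            for cat in MM_CATEGORIES + ("2+",):
                rows.append((year, label, cat,
                             round1(counts[cat] / n_alive * 100.0),
                             round_count(counts[cat] * scale_factor),
                             round_count(n_alive * scale_factor)))
    return pd.DataFrame(rows, columns=["year", "age_group", "category",
                                       "prevalence_pct", "count",
                                       "stratum_count"])


def percent_change_table(table: pd.DataFrame, year_start: int,
                         year_end: int) -> pd.DataFrame:
    """Percent change in scaled counts between two reported years."""
    key = "condition" if "condition" in table.columns else "category"
    a = table[table["year"] == year_start].set_index(["age_group", key])
    b = table[table["year"] == year_end].set_index(["age_group", key])
    rows = []
    for idx in a.index:
        n0, n1 = a.loc[idx, "count"], b.loc[idx, "count"]
        if not np.isfinite(n0) or n0 <= 0:
            rows.append((*idx, np.nan))
        else:
            rows.append((*idx, percent_change(n0, n1)))
    out = pd.DataFrame(rows, columns=["age_group", key, "pct_change"])
    out.insert(0, "year_end", year_end)
    out.insert(0, "year_start", year_start)
    return out


def mental_illhealth_overlap(snapshot: pd.DataFrame, cset: ConditionSet,
                             include_mental_in_count: bool = True,
                             ) -> pd.DataFrame:
    """Percent with mental ill-health within each morbidity-count category.

    Mental ill-health is dementia, depression or CIND.  With
    ``include_mental_in_count`` (default) the morbidity count includes the
    mental-ill-health members themselves; otherwise categories count only
    the remaining ("other") conditions.
    """
    mental = np.zeros(len(snapshot), dtype=bool)
    for m in MENTAL_ILL_HEALTH:
        if m in cset.members:
            mental |= condition_indicator(snapshot, m).astype(bool)
    if include_mental_in_count:
        raw = condition_counts(snapshot, cset)
    else:
        others = ConditionSet("others", tuple(
            m for m in cset.members if m not in MENTAL_ILL_HEALTH))
        raw = condition_counts(snapshot, others)
    capped = np.minimum(raw, 4)
    rows = []
    for i, cat in enumerate(MM_CATEGORIES):
        in_cat = capped == i
        n = int(in_cat.sum())
        if n == 0:
            warnings.warn(f"empty morbidity category {cat}", stacklevel=2)
            rows.append((cat, np.nan, 0))
        else:
            rows.append((cat, round1(mental[in_cat].mean() * 100.0), n))
    return pd.DataFrame(rows, columns=["category", "mental_pct", "n"])
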