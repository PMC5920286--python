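"""Monthly discrete-time simulation engine.

Each simulated month, every alive individual is processed in a fixed order:

1. survival Bernoulli draw at the monthly survival probability for the
   individual's current age, sex and calendar year;
2. ageing by one month;
3. one categorical draw per stochastic characteristic, processed in registry
   order (sociodemographic/behaviours, then diseases, then impairments and
   cognition), each draw conditioning on already-updated values of earlier
   characteristics within the same month.

The population is closed: nobody enters after the start, and dementia is
never touched here (it is allocated after the simulation).  The working
representation is a dict of NumPy column arrays; pandas DataFrames are used
at the API boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, ScheduleError
from .mortality import MIN_AGE, MortalitySchedule
from .state import (CharacteristicSpec, MMSE_BAND_REPRESENTATIVE,
                    POPULATION_COLUMNS, default_registry, stochastic_specs,
                    mmse_band_from_score)
from .transitions import TransitionModelBundle


@dataclass
class RunConfig:
    """Simulation run settings."""

    start_year: int = 2014
    start_month: int = 7
    horizon_year: int = 2035
    snapshot_month: int = 7
    seed: int = 0
    n_replicates: int = 1
    scale_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.horizon_year < self.start_year:
            raise InputError("horizon before start year")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")


@dataclass
class SimulationOutput:
    """Annual snapshots (alive individuals, pre-dementia-allocation),
    death log and provenance."""

    snapshots: dict[int, pd.DataFrame]
    deaths: pd.DataFrame  # id, year, month
    replicate: int
    seed: int
    alive_counts: list[int] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return sorted(self.snapshots)


class _Subset(Mapping):
    """Lazy row-subset view over a dict of column arrays."""

    def __init__(self, cols: dict, idx: np.ndarray):
        self._cols, self._idx = cols, idx

    def __getitem__(self, key):
        return self._cols[key][self._idx]

    def __iter__(self):
        return iter(self._cols)

    def __len__(self):
        return len(self._cols)


def population_to_columns(df: pd.DataFrame) -> dict[str, np.ndarray]:
    cols = {}
    for c in df.columns:
        arr = df[c].to_numpy()
        cols[c] = arr.astype(bool) if c == "alive" else arr.astype(
            np.int64, copy=True)
    if "mmse_band" not in cols:
        cols["mmse_band"] = np.asarray(mmse_band_from_score(cols["mmse"]))
    return cols


def columns_to_population(cols: Mapping[str, np.ndarray],
                          mask: np.ndarray | None = None) -> pd.DataFrame:
    sel = slice(None) if mask is None else mask
    return pd.DataFrame({c: np.asarray(cols[c])[sel].copy()
                         for c in POPULATION_COLUMNS})


def _draw_categorical(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    cum = np.cumsum(probs, axis=1)
    return np.minimum((u[:, None] > cum).sum(axis=1), probs.shape[1] - 1)


def step_month(cols: dict[str, np.ndarray], bundle: TransitionModelBundle,
               schedule: MortalitySchedule, year: int,
               rng: np.random.Generator,
               specs: list[CharacteristicSpec] | None = None,
               _survival_lookup: np.ndarray | None = None) -> np.ndarray:
    """Advance the population by one month in place; returns died ids."""
    if specs is None:
        specs = stochastic_specs(default_registry())
    alive = cols["alive"]
    idx = np.flatnonzero(alive)
    if len(idx) == 0:
        return np.empty(0, dtype=np.int64)

    # 1. mortality (schedule=None runs a mortality-free month)
    if schedule is not None:
        age_years = cols["age_months"][idx] // 12
        if age_years.max() > schedule.terminal_age:
            raise ScheduleError(
                f"individual aged {age_years.max()} beyond schedule terminal "
                f"age {schedule.terminal_age}")
        s_lookup = (_survival_lookup if _survival_lookup is not None
                    else schedule.monthly_survival_lookup(year))
        s = s_lookup[cols["sex"][idx], age_years - MIN_AGE]
        died_mask = rng.random(len(idx)) >= s
        died = idx[died_mask]
        alive[died] = False
        idx = idx[~died_mask]
    else:
        died = np.empty(0, dtype=np.int64)

    # 2. ageing
    cols["age_months"][idx] += 1

    # 3. characteristic updates, registry order
    for spec in specs:
        fit = bundle[spec.name]
        col = spec.name
        current = cols[col][idx]
        sub = _Subset(cols, idx)
        probs = fit.monthly_probs(sub, current)
        new = _draw_categorical(probs, rng.random(len(idx)))
        changed = new != current
        if not changed.any():
            continue
        cols[col][idx[changed]] = new[changed]
        if col == "mmse_band":
            rep = np.array([MMSE_BAND_REPRESENTATIVE[b] for b in range(3)])
            cols["mmse"][idx[changed]] = rep[new[changed]]
    return cols["id"][died]


def run_simulation(base: pd.DataFrame, bundle: TransitionModelBundle,
                   schedule: MortalitySchedule, config: RunConfig,
                   registry: Mapping[str, CharacteristicSpec] | None = None,
                   replicate: int = 0) -> SimulationOutput:
    """Run one replicate from start to December of the horizon year.

    A snapshot of the alive population is recorded at the start of the
    snapshot month each year (so the first snapshot, if the snapshot month
    is not before the start month, is the base population itself).
    Replicate ``r`` uses the independent stream seeded by ``(seed, r)``.
    """
    if len(base) == 0:
        raise InputError("empty base population")
    if base["id"].duplicated().any():
        raise InputError("duplicate ids in base population")
    registry = default_registry() if registry is None else registry
    specs = stochastic_specs(registry)
    missing = [s.name for s in specs if s.name not in bundle]
    if missing:
        raise InputError(f"bundle missing models for: {missing}")

    # distinct non-zero domain tag: SeedSequence pads with zeros, so a bare
    # [seed, 0] stream would collide with the generator stream seeded [seed]
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF,
                                 0xE1, replicate + 1])
    cols = population_to_columns(base)

    snapshots: dict[int, pd.DataFrame] = {}
    death_rows: list[tuple[int, int, int]] = []
    alive_counts: list[int] = []

    year, month = config.start_year, config.start_month
    current_lookup_year = None
    s_lookup = None
    while year <= config.horizon_year:
        if month == config.snapshot_month:
            snapshots[year] = columns_to_population(cols, cols["alive"])
        if year != current_lookup_year:
            s_lookup = schedule.monthly_survival_lookup(year)
            current_lookup_year = year
        died = step_month(cols, bundle, schedule, year, rng, specs,
                          _survival_lookup=s_lookup)
        death_rows.extend((int(i), year, month) for i in died)
        alive_counts.append(int(cols["alive"].sum()))
        month += 1
        if month > 12:
            month, year = 1, year + 1

    deaths = pd.DataFrame(death_rows, columns=["id", "year", "month"])
    return SimulationOutput(snapshots=snapshots, deaths=deaths,
                            replicate=replicate, seed=config.seed,
                            alive_counts=alive_counts)


def run_replicates(base: pd.DataFrame, bundle: TransitionModelBundle,
                   schedule: MortalitySchedule, config: RunConfig,
                   registry: Mapping[str, CharacteristicSpec] | None = None,
                   ) -> list[SimulationOutput]:
    """Run ``config.n_replicates`` independent replicates."""
    return [run_simulation(base, bundle, schedule, config, registry,
                           replicate=r)
            for r in range(config.n_replicates)]
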