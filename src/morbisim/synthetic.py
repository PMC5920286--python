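"""Synthetic base population and two-wave panel generation.

The microsimulation was designed around a 1% sample of a national 35+
population (about 303,589 individuals) built from linked survey microdata
that are access-restricted.  This module generates a synthetic stand-in at
configurable size: an age/sex structure loosely matching England 2014,
age-graded condition prevalence curves (logistic in age), behavioural risk
factors correlated with disease through odds multipliers, and a two-wave
panel whose transitions are drawn from a *known* ground-truth transition
bundle so that model fitting and the engine can be tested end to end.

The synthetic marginals are calibrated to published English magnitudes
(e.g. 65+ disease prevalence of order 10-50%) but do not claim to reproduce
any specific survey table; the joint distribution is a modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import (population_to_columns, columns_to_population,
                     step_month)
from .errors import ConfigurationError
from .state import (CharacteristicSpec, DISEASES, POPULATION_COLUMNS,
                    default_registry, stochastic_specs, mmse_band_from_score)
from .transitions import FittedTransition, TransitionModelBundle, _sigmoid

N_FULL_SCALE = 303_589  # 1% sample of the 2014 England 35+ population


@dataclass(frozen=True)
class PrevalenceCurve:
    """Logistic-in-age prevalence: sigmoid(intercept + slope*(age-65)/10
    + sex_offset*female).  An intercept of -inf switches the condition off
    entirely (used by tests); otherwise probabilities must stay in (0, 1).
    """

    intercept: float
    slope_per_decade: float = 0.0
    sex_offset: float = 0.0

    def probability(self, age_years, female, extra_logodds=0.0):
        if np.isneginf(self.intercept):
            return np.zeros_like(np.asarray(age_years, dtype=float))
        lp = (self.intercept
              + self.slope_per_decade * (np.asarray(age_years) - 65.0) / 10.0
              + self.sex_offset * np.asarray(female)
              + extra_logodds)
        return _sigmoid(lp)


#: default per-condition prevalence curves (male, age 65 reference)
DEFAULT_PREVALENCE_CURVES: dict[str, PrevalenceCurve] = {
    "arthritis": PrevalenceCurve(-1.15, 0.50, 0.35),
    "cancer": PrevalenceCurve(-2.95, 0.50, 0.0),
    "chd": PrevalenceCurve(-2.25, 0.55, -0.45),
    "depression": PrevalenceCurve(-4.40, 0.05, 0.35),
    "diabetes": PrevalenceCurve(-2.30, 0.25, -0.15),
    "hypertension": PrevalenceCurve(-0.85, 0.45, 0.0),
    "respiratory": PrevalenceCurve(-2.10, 0.20, 0.0),
    "stroke": PrevalenceCurve(-3.85, 0.70, 0.0),
    "hearing": PrevalenceCurve(-3.25, 0.80, -0.20),
    "vision": PrevalenceCurve(-4.10, 0.70, 0.10),
}

#: default (age_lo, age_hi_exclusive, female_share, weight) structure;
#: weights loosely match the England 2014 35+ age pyramid
DEFAULT_AGE_SEX_STRUCTURE = (
    (35, 45, 0.503, 0.225),
    (45, 55, 0.507, 0.235),
    (55, 65, 0.510, 0.200),
    (65, 75, 0.520, 0.165),
    (75, 85, 0.570, 0.115),
    (85, 101, 0.670, 0.060),
)

#: odds multipliers linking behaviours to disease presence at generation
DEFAULT_RISK_ODDS = {"inactive": 1.4, "obese": 1.5, "smoking_current": 1.6}


@dataclass
class SyntheticConfig:
    """Settings for the synthetic base population."""

    n_individuals: int = 30_000
    seed: int = 0
    age_range: tuple[int, int] = (35, 100)
    age_sex_structure: tuple = DEFAULT_AGE_SEX_STRUCTURE
    prevalence_curves: Mapping[str, PrevalenceCurve] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_CURVES))
    risk_odds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_ODDS))
    scale_factor: float = 100.0

    def __post_init__(self) -> None:
        w = sum(row[3] for row in self.age_sex_structure)
        if not np.isclose(w, 1.0, atol=1e-6):
            raise ConfigurationError(f"age-structure weights sum to {w}, not 1")
        lo, hi = self.age_range
        ages = np.array([lo, hi], dtype=float)
        for name, curve in self.prevalence_curves.items():
            for female in (0, 1):
                p = curve.probability(ages, female)
                if np.any(p >= 1.0) or np.any(p < 0.0):
                    raise ConfigurationError(
                        f"degenerate prevalence curve for {name!r}")

    def with_n(self, n: int, seed: int | None = None) -> "SyntheticConfig":
        return replace(self, n_individuals=n,
                       seed=self.seed if seed is None else seed)


def _behaviour_logodds(config: SyntheticConfig, inactive, bmi_cat, smoking):
    """Extra disease log-odds from correlated risk factors."""
    lo = np.zeros(len(np.asarray(inactive)), dtype=float)
    lo += np.log(config.risk_odds.get("inactive", 1.0)) * (inactive == 1)
    lo += np.log(config.risk_odds.get("obese", 1.0)) * (bmi_cat == 3)
    lo += np.log(config.risk_odds.get("smoking_current", 1.0)) * (smoking == 2)
    return lo


def condition_probabilities(config: SyntheticConfig, name: str,
                            age_years, female, inactive, bmi_cat, smoking,
                            ) -> np.ndarray:
    """Per-individual generation probability for one condition.

    Exposed so tests can compare realised prevalence against the exact
    probabilities used at generation time.
    """
    curve = config.prevalence_curves[name]
    extra = _behaviour_logodds(config, np.asarray(inactive),
                               np.asarray(bmi_cat), np.asarray(smoking))
    return curve.probability(age_years, female, extra)


def generate_base_population(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the synthetic base population (one row per individual).

    Deterministic for a fixed seed.  Dementia is left unset (all zero): it
    is assigned by the allocation step, never at generation.
    """
    rng = np.random.default_rng(int(config.seed) & 0x7FFFFFFF)
    n = int(config.n_individuals)
    if n < 1:
        raise ConfigurationError("n_individuals must be >= 1")

    # age band and sex from the configured structure
    struct = config.age_sex_structure
    cell_w = np.array([row[3] for row in struct], dtype=float)
    cell_w = cell_w / cell_w.sum()
    band = rng.choice(len(struct), size=n, p=cell_w)
    lo = np.array([row[0] for row in struct])[band]
    hi = np.array([row[1] for row in struct])[band]
    fem_share = np.array([row[2] for row in struct])[band]
    sex = (rng.random(n) < fem_share).astype(np.int64)  # 1 = female
    age_years = (lo + rng.random(n) * (hi - lo))
    age_years = np.clip(age_years, config.age_range[0],
                        config.age_range[1]).astype(int)
    age_months = age_years * 12 + rng.integers(0, 12, size=n)
    female = sex

    # education: cohort gradient (younger cohorts more educated)
    p_high = _sigmoid(-0.2 - 0.35 * (age_years - 65) / 10.0)
    p_low = _sigmoid(-1.1 + 0.40 * (age_years - 65) / 10.0)
    u = rng.random(n)
    education = np.where(u < p_low, 0, np.where(u < p_low + (1 - p_low - p_high
                                                             ).clip(0), 1, 2))
    ses = rng.choice(3, size=n, p=(0.3, 0.4, 0.3))

    # marital: widowhood rises with age, stronger for women
    p_wid = _sigmoid(-3.2 + 1.1 * (age_years - 65) / 10.0 + 0.8 * female)
    p_single = 0.12 * np.ones(n)
    u = rng.random(n)
    marital = np.where(u < p_wid, 2, np.where(u < p_wid + p_single, 0, 1))

    # behaviours
    p_current = _sigmoid(-1.1 - 0.35 * (age_years - 65) / 10.0)
    p_former = 0.30
    u = rng.random(n)
    smoking = np.where(u < p_current, 2,
                       np.where(u < p_current + p_former, 1, 0))
    inactive = (rng.random(n)
                < _sigmoid(-1.0 + 0.45 * (age_years - 65) / 10.0)
                ).astype(np.int64)
    u = rng.random(n)
    p_under, p_normal, p_over = 0.02, 0.32, 0.42
    bmi_cat = np.where(u < p_under, 0,
                       np.where(u < p_under + p_normal, 1,
                                np.where(u < p_under + p_normal + p_over,
                                         2, 3)))

    out = {
        "id": np.arange(n, dtype=np.int64),
        "sex": sex, "education": education.astype(np.int64),
        "ses": ses.astype(np.int64),
        "age_months": age_months.astype(np.int64),
        "alive": np.ones(n, dtype=np.int64),
        "marital": marital.astype(np.int64),
        "smoking": smoking.astype(np.int64),
        "inactive": inactive, "bmi_cat": bmi_cat.astype(np.int64),
    }

    # residence: care home entry is rare and strongly age-graded
    p_care = np.where(age_years >= 65,
                      _sigmoid(-6.0 + 1.6 * (age_years - 65) / 10.0), 0.0)
    out["residence"] = (rng.random(n) < p_care).astype(np.int64)

    # diseases and impairments from the prevalence curves + risk odds
    for name in DISEASES + ("hearing", "vision"):
        if name == "dementia":
            out[name] = np.zeros(n, dtype=np.int64)
            continue
        p = condition_probabilities(config, name, age_years, female,
                                    inactive, bmi_cat, smoking)
        out[name] = (rng.random(n) < p).astype(np.int64)

    # cognition: band probabilities rise with age, then an integer score
    p_imp = _sigmoid(-4.9 + 1.2 * (age_years - 65) / 10.0)
    p_mild = _sigmoid(-2.5 + 0.5 * (age_years - 65) / 10.0)
    u = rng.random(n)
    band3 = np.where(u < p_imp, 2, np.where(u < p_imp + p_mild, 1, 0))
    mmse = np.select(
        [band3 == 0, band3 == 1, band3 == 2],
        [rng.integers(26, 31, size=n), rng.integers(21, 26, size=n),
         rng.integers(8, 21, size=n)])
    out["mmse"] = mmse.astype(np.int64)

    df = pd.DataFrame(out)[list(POPULATION_COLUMNS)]
    return df


def write_population_csv(df: pd.DataFrame, path, header_comment=None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_population_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"population CSV missing columns {missing}")
    if df.isna().any().any():
        raise ConfigurationError("population CSV contains missing values")
    return df[list(POPULATION_COLUMNS)]


# --------------------------------------------------------------------------
# ground-truth transition bundle


def default_truth_bundle(registry=None,
                         interval_months: int = 24) -> TransitionModelBundle:
    """Hand-set, plausible 2-year transition models used as ground truth.

    Onset probabilities are of the order seen in English panel data (for
    example ~8%/2y arthritis onset at 65, ~1.5%/2y stroke onset at 65,
    rising with age); recoverable characteristics carry a strong own-state
    coefficient so persistence dominates.  These are the coefficients the
    panel generator draws from and that parameter-recovery tests try to
    re-estimate.
    """
    registry = default_registry() if registry is None else registry

    def binary(name, beta):
        spec = registry[name]
        return FittedTransition(
            name=name, family="binary_logit", states=spec.states,
            covariates=spec.predictors, interval_months=interval_months,
            absorbing=spec.absorbing, beta=np.asarray(beta, dtype=float))

    models: dict[str, FittedTransition] = {}
    # marital: single/married/widowed; ref = single
    models["marital"] = FittedTransition(
        name="marital", family="generalised_logit",
        states=registry["marital"].states,
        covariates=registry["marital"].predictors,
        interval_months=interval_months,
        # rows: const, age, sex, marital_married, marital_widowed
        beta=np.array([[-5.0, -8.0],
                       [-0.2, 0.8],
                       [0.0, 0.5],
                       [10.0, 9.0],
                       [0.5, 12.0]]))
    # smoking: never/former/current; ref = never
    models["smoking"] = FittedTransition(
        name="smoking", family="generalised_logit",
        states=registry["smoking"].states,
        covariates=registry["smoking"].predictors,
        interval_months=interval_months,
        # rows: const, age, sex, education, smoking_former, smoking_current
        beta=np.array([[-6.0, -7.0],
                       [0.1, -0.3],
                       [0.0, 0.0],
                       [0.0, -0.1],
                       [9.0, 1.5],
                       [6.3, 9.3]]))
    models["inactive"] = binary(
        "inactive", [-2.8, 0.35, 0.10, 0.25, 3.2])
    models["bmi_cat"] = FittedTransition(
        name="bmi_cat", family="ordinal_logit",
        states=registry["bmi_cat"].states,
        covariates=registry["bmi_cat"].predictors,
        interval_months=interval_months,
        beta=np.array([0.0, 0.0, 0.3, 5.0]),  # age, sex, inactive, bmi_cat
        thresholds=np.array([2.5, 7.6, 12.7]))
    # absorbing disease onset models
    # covariates: age, sex, education, ses, smoking, inactive, bmi_cat (+extras)
    base = dict(
        arthritis=[-3.30, 0.25, 0.20, -0.05, -0.05, 0.05, 0.15, 0.10],
        cancer=[-4.20, 0.35, 0.00, 0.00, 0.00, 0.10, 0.05, 0.05],
        diabetes=[-4.90, 0.20, -0.10, -0.05, -0.05, 0.05, 0.20, 0.35],
        hypertension=[-3.70, 0.20, 0.00, -0.05, -0.05, 0.05, 0.15, 0.25],
        respiratory=[-4.70, 0.20, 0.00, -0.05, -0.05, 0.35, 0.10, 0.05],
    )
    for name, beta in base.items():
        models[name] = binary(name, beta)
    models["chd"] = binary(
        "chd", [-4.60, 0.35, -0.30, -0.05, -0.05, 0.15, 0.10, 0.10,
                0.30, 0.30])  # + hypertension, diabetes
    models["stroke"] = binary(
        "stroke", [-5.70, 0.50, -0.10, -0.05, -0.05, 0.10, 0.10, 0.05,
                   0.40])  # + hypertension
    models["depression"] = binary(
        "depression", [-4.60, 0.05, 0.30, -0.05, -0.05, 0.05, 0.15, 0.05,
                       4.30])  # + own state
    models["hearing"] = binary("hearing", [-4.00, 0.50, -0.20, 5.00])
    models["vision"] = binary("vision", [-4.50, 0.50, 0.10, 4.60])
    models["mmse_band"] = FittedTransition(
        name="mmse_band", family="ordinal_logit",
        states=registry["mmse_band"].states,
        covariates=registry["mmse_band"].predictors,
        interval_months=interval_months,
        beta=np.array([0.6, 0.0, -0.3, 5.5]),  # age, sex, education, own band
        thresholds=np.array([4.2, 7.4]))
    return TransitionModelBundle(models=models,
                                 interval_months=interval_months,
                                 metadata={"source": "synthetic ground truth"})


# --------------------------------------------------------------------------
# two-wave panel


@dataclass
class PanelDataset:
    """Two-wave panel: wave-1 states, wave-2 states (or died), interval."""

    wave1: pd.DataFrame
    wave2: pd.DataFrame
    interval_months: int = 24
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path, header_comment=None) -> None:
        w1 = self.wave1.copy()
        w1.insert(0, "wave", 1)
        w2 = self.wave2.copy()
        w2.insert(0, "wave", 2)
        out = pd.concat([w1, w2], ignore_index=True)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, interval_months: int = 24) -> "PanelDataset":
        df = pd.read_csv(path, comment="#")
        w1 = df[df["wave"] == 1].drop(columns="wave").reset_index(drop=True)
        w2 = df[df["wave"] == 2].drop(columns="wave").reset_index(drop=True)
        return cls(wave1=w1, wave2=w2, interval_months=interval_months)


def _interval_draw(fit: FittedTransition, cols, current: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Single interval-level draw of the wave-2 state."""
    p = fit.interval_probs(cols)
    n = len(current)
    if fit.family == "binary_logit":
        if fit.absorbing:
            onset = (rng.random(n) < p[:, 1]) & (current == 0)
            return np.where(current == 1, 1, onset.astype(int))
        return (rng.random(n) < p[:, 1]).astype(int)
    cum = np.cumsum(p, axis=1)
    return np.minimum((rng.random(n)[:, None] > cum).sum(axis=1),
                      p.shape[1] - 1)


def generate_panel(base: pd.DataFrame, truth: TransitionModelBundle,
                   interval_months: int = 24, seed: int = 0,
                   mode: str = "monthly", schedule=None,
                   registry=None, start_year: int = 2014) -> PanelDataset:
    """Generate wave-2 states from the ground-truth bundle.

    ``mode='monthly'`` (default) applies the truth's monthly probabilities
    month by month with the same semantics as the engine (covariates are
    re-read each month, so characteristics co-evolve); ``mode='interval'``
    takes one interval-level draw per characteristic at frozen wave-1
    covariates.  Mortality is applied only when a schedule is supplied.
    """
    from .state import MMSE_BAND_REPRESENTATIVE

    registry = default_registry() if registry is None else registry
    specs = stochastic_specs(registry)
    missing = [s.name for s in specs if s.name not in truth]
    if missing:
        raise ConfigurationError(
            f"truth bundle missing models for: {missing}")
    if mode not in ("monthly", "interval"):
        raise ConfigurationError(f"unknown panel mode {mode!r}")

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xBA])
    wave1 = base.reset_index(drop=True).copy()
    cols = population_to_columns(wave1)

    if mode == "monthly":
        year, month = start_year, 1
        for _ in range(interval_months):
            step_month(cols, truth, schedule, year, rng, specs)
            month += 1
            if month > 12:
                month, year = 1, year + 1
        wave2 = columns_to_population(cols)
    else:
        alive_idx = np.flatnonzero(cols["alive"])
        if schedule is not None:
            # compounded monthly survival along the ageing trajectory
            surv = np.ones(len(alive_idx))
            for m in range(interval_months):
                ages = (cols["age_months"][alive_idx] + m) // 12
                q = schedule.q_lookup(start_year)[cols["sex"][alive_idx],
                                                  ages - 35]
                surv *= (1.0 - q) ** (1.0 / 12.0)
            dead = rng.random(len(alive_idx)) >= surv
            cols["alive"][alive_idx[dead]] = False
        idx = np.flatnonzero(cols["alive"])
        frozen = {k: v[idx].copy() for k, v in cols.items()}
        for spec in specs:
            fit = truth[spec.name]
            current = frozen[spec.name]
            new = _interval_draw(fit, frozen, current, rng)
            cols[spec.name][idx] = new
            if spec.name == "mmse_band":
                changed = new != current
                rep = np.array([MMSE_BAND_REPRESENTATIVE[b] for b in range(3)])
                cols["mmse"][idx[changed]] = rep[new[changed]]
        cols["age_months"][idx] += interval_months
        wave2 = columns_to_population(cols)

    return PanelDataset(wave1=wave1, wave2=wave2,
                        interval_months=interval_months,
                        metadata={"mode": mode, "seed": int(seed),
                                  "mortality": schedule is not None})
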