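"""Characteristic registry, individual state container and condition counting.

Every characteristic an individual carries is described by a
:class:`CharacteristicSpec`.  Characteristics are *fixed* (sex, education,
socio-economic status, residence), *deterministic* (age advances one month per
simulated month) or *stochastic* (everything else: updated by a fitted
transition model).  Dementia is special: it is carried on the state but is
assigned by the post-simulation allocation step, never by the engine, and it
never appears as a predictor in any transition model.

Categorical characteristics are stored as small integer codes; the label
tuples below fix the coding and are the single source of truth for CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Iterable, Mapping

from .errors import ConfigurationError, DomainError

# --- categorical codings (index = stored integer code) ----------------------

SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("low", "mid", "high")
SES_LEVELS = ("low", "mid", "high")
RESIDENCE_LEVELS = ("community", "care_home")
MARITAL_LEVELS = ("single", "married", "widowed")
SMOKING_LEVELS = ("never", "former", "current")
BMI_LEVELS = ("under", "normal", "overweight", "obese")
# cognition bands in increasing severity; code 2 is the MMSE 0-20 band
MMSE_BAND_LEVELS = ("normal", "mild", "impaired")
MMSE_BAND_REPRESENTATIVE = {0: 28, 1: 23, 2: 12}

CIND_MMSE_CUTOFF = 20  # MMSE 0-20, no dementia

DISEASES = (
    "arthritis",
    "cancer",
    "chd",
    "dementia",
    "depression",
    "diabetes",
    "hypertension",
    "respiratory",
    "stroke",
)
IMPAIRMENT_FLAGS = ("hearing", "vision")

#: columns of a base-population table, in canonical order
POPULATION_COLUMNS = (
    ("id", "sex", "education", "ses", "residence", "age_months", "alive",
     "marital", "smoking", "inactive", "bmi_cat")
    + DISEASES
    + IMPAIRMENT_FLAGS
    + ("mmse",)
)

MENTAL_ILL_HEALTH = ("dementia", "depression", "cind")


@dataclass(frozen=True)
class ConditionSet:
    """Named list of conditions over which morbidity is counted."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        valid = set(DISEASES) | set(IMPAIRMENT_FLAGS) | {"cind"}
        unknown = [m for m in self.members if m not in valid]
        if unknown:
            raise ConfigurationError(f"unknown condition name(s): {unknown}")


DISEASES_ONLY = ConditionSet("diseases_only", DISEASES)
DISEASES_AND_IMPAIRMENTS = ConditionSet(
    "diseases_and_impairments", DISEASES + ("cind",) + IMPAIRMENT_FLAGS
)


@dataclass(frozen=True)
class CharacteristicSpec:
    """Registry entry: state space, model family, predictors, absorbing flag.

    ``absorbing`` means that once the condition is present it is never left
    (ever-diagnosed chronic disease); only meaningful for binary
    characteristics.
    """

    name: str
    kind: str  # fixed | deterministic | stochastic
    states: tuple[str, ...]
    model_family: str = "none"  # binary_logit | ordinal_logit | generalised_logit | none
    predictors: tuple[str, ...] = ()
    absorbing: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "deterministic", "stochastic"):
            raise ConfigurationError(f"{self.name}: bad kind {self.kind!r}")
        if self.model_family not in (
            "binary_logit", "ordinal_logit", "generalised_logit", "none"
        ):
            raise ConfigurationError(
                f"{self.name}: bad model family {self.model_family!r}")
        if self.kind in ("fixed", "deterministic") and self.model_family != "none":
            raise ConfigurationError(
                f"{self.name}: {self.kind} characteristics take no model")
        if self.absorbing and len(self.states) != 2:
            raise ConfigurationError(
                f"{self.name}: absorbing only meaningful for binary states")
        if "dementia" in self.predictors:
            raise ConfigurationError(
                f"{self.name}: dementia may not be used as a predictor "
                "(it is allocated after the simulation)")


_BINARY = ("absent", "present")

_BEHAVIOUR_PREDICTORS = ("age", "sex")
_DISEASE_PREDICTORS = ("age", "sex", "education", "ses",
                       "smoking", "inactive", "bmi_cat")


def default_registry() -> dict[str, CharacteristicSpec]:
    """Default characteristic registry, in engine update order.

    Order within a month: sociodemographic/behaviours first, then diseases,
    then impairments and cognition, so each update sees already-updated
    values of earlier characteristics.
    """
    specs: list[CharacteristicSpec] = [
        CharacteristicSpec("sex", "fixed", SEX_LEVELS),
        CharacteristicSpec("education", "fixed", EDUCATION_LEVELS),
        CharacteristicSpec("ses", "fixed", SES_LEVELS),
        CharacteristicSpec("residence", "fixed", RESIDENCE_LEVELS),
        CharacteristicSpec("age", "deterministic", ("months",)),
        # sociodemographic + behaviours
        CharacteristicSpec("marital", "stochastic", MARITAL_LEVELS,
                           "generalised_logit",
                           ("age", "sex", "marital_married",
                            "marital_widowed")),
        CharacteristicSpec("smoking", "stochastic", SMOKING_LEVELS,
                           "generalised_logit",
                           ("age", "sex", "education", "smoking_former",
                            "smoking_current")),
        CharacteristicSpec("inactive", "stochastic", _BINARY, "binary_logit",
                           ("age", "sex", "bmi_cat", "inactive")),
        CharacteristicSpec("bmi_cat", "stochastic", BMI_LEVELS, "ordinal_logit",
                           ("age", "sex", "inactive", "bmi_cat")),
        # diseases (ever-diagnosed -> absorbing, except depression)
        CharacteristicSpec("arthritis", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS, absorbing=True),
        CharacteristicSpec("cancer", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS, absorbing=True),
        CharacteristicSpec("chd", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS + ("hypertension", "diabetes"),
                           absorbing=True),
        CharacteristicSpec("depression", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS + ("depression",)),
        CharacteristicSpec("diabetes", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS, absorbing=True),
        CharacteristicSpec("hypertension", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS, absorbing=True),
        CharacteristicSpec("respiratory", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS, absorbing=True),
        CharacteristicSpec("stroke", "stochastic", _BINARY, "binary_logit",
                           _DISEASE_PREDICTORS + ("hypertension",),
                           absorbing=True),
        # dementia lives on the state but is owned by the allocation module
        CharacteristicSpec("dementia", "stochastic", _BINARY, "none"),
        # impairments and cognition (self-report of current state: recoverable)
        CharacteristicSpec("hearing", "stochastic", _BINARY, "binary_logit",
                           _BEHAVIOUR_PREDICTORS + ("hearing",)),
        CharacteristicSpec("vision", "stochastic", _BINARY, "binary_logit",
                           _BEHAVIOUR_PREDICTORS + ("vision",)),
        CharacteristicSpec("mmse_band", "stochastic", MMSE_BAND_LEVELS,
                           "ordinal_logit",
                           ("age", "sex", "education", "mmse_band")),
    ]
    return {s.name: s for s in specs}


def stochastic_specs(registry: Mapping[str, CharacteristicSpec]
                     ) -> list[CharacteristicSpec]:
    """Specs the engine updates each month, in registry order."""
    return [s for s in registry.values()
            if s.kind == "stochastic" and s.model_family != "none"]


def registry_to_json(registry: Mapping[str, CharacteristicSpec]) -> str:
    return json.dumps({k: asdict(v) for k, v in registry.items()}, indent=2)


def registry_from_json(text: str) -> dict[str, CharacteristicSpec]:
    raw = json.loads(text)
    out = {}
    for name, d in raw.items():
        d = dict(d)
        d["states"] = tuple(d["states"])
        d["predictors"] = tuple(d.get("predictors", ()))
        out[name] = CharacteristicSpec(**d)
    return out


@dataclass
class IndividualState:
    """One person's full state: fixed attributes, age and current values."""

    id: int
    sex: int
    education: int
    ses: int
    residence: int
    age_months: int
    alive: bool = True
    marital: int = 1
    smoking: int = 0
    inactive: int = 0
    bmi_cat: int = 1
    arthritis: int = 0
    cancer: int = 0
    chd: int = 0
    dementia: int = 0
    depression: int = 0
    diabetes: int = 0
    hypertension: int = 0
    respiratory: int = 0
    stroke: int = 0
    hearing: int = 0
    vision: int = 0
    mmse: int = 28

    def __post_init__(self) -> None:
        if self.age_months < 35 * 12:
            raise DomainError(f"age_months {self.age_months} below 35 years")
        if not 0 <= self.mmse <= 30:
            raise DomainError(f"mmse {self.mmse} outside [0, 30]")

    @classmethod
    def from_row(cls, row: Mapping) -> "IndividualState":
        return cls(**{c: (bool(row[c]) if c == "alive" else int(row[c]))
                      for c in POPULATION_COLUMNS})

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in POPULATION_COLUMNS}


def classify_cind(mmse: int, dementia: bool) -> bool:
    """Cognitive impairment no dementia: MMSE 0-20 without a dementia flag."""
    if not 0 <= mmse <= 30:
        raise DomainError(f"mmse {mmse} outside [0, 30]")
    return mmse <= CIND_MMSE_CUTOFF and not dementia


def _condition_present(state: IndividualState, name: str) -> bool:
    if name == "cind":
        return classify_cind(state.mmse, bool(state.dementia))
    try:
        return bool(getattr(state, name))
    except AttributeError:
        raise ConfigurationError(f"unknown condition name: {name!r}") from None


def count_conditions(state: IndividualState,
                     condition_set: ConditionSet) -> tuple[int, str]:
    """Count member conditions present; category capped at ``"4+"``.

    Multi-morbidity is a raw count of two or more.
    """
    raw = sum(_condition_present(state, m) for m in condition_set.members)
    return raw, ("4+" if raw >= 4 else str(raw))


def has_mental_ill_health(state: IndividualState) -> bool:
    """Dementia, depression, or CIND."""
    return (bool(state.dementia) or bool(state.depression)
            or classify_cind(state.mmse, bool(state.dementia)))


def mmse_band_from_score(mmse) -> "int | object":
    """Map an MMSE score (scalar or array) to the 3-band severity code."""
    import numpy as np

    arr = np.asarray(mmse)
    band = np.where(arr <= CIND_MMSE_CUTOFF, 2, np.where(arr <= 25, 1, 0))
    return band if arr.ndim else int(band)
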