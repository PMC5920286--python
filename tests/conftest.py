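import numpy as np
import pandas as pd
import pytest

from morbisim import (SyntheticConfig, default_registry, default_truth_bundle,
                      generate_base_population, make_toy_schedule)
from morbisim.state import CharacteristicSpec


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def truth(registry):
    return default_truth_bundle(registry)


@pytest.fixture(scope="session")
def schedule():
    return make_toy_schedule(range(2014, 2037))


@pytest.fixture(scope="session")
def flat_schedule():
    """No calendar improvement: period lifetable = cohort experience."""
    return make_toy_schedule(range(2014, 2037), improvement=0.0)


@pytest.fixture(scope="session")
def small_base():
    cfg = SyntheticConfig(n_individuals=2000, seed=11)
    return generate_base_population(cfg)


def make_cohort(n: int, age_years: int = 65, sex: int = 0,
                seed: int = 0) -> pd.DataFrame:
    """Homogeneous cohort: everyone the same age and sex, no conditions."""
    from morbisim.state import POPULATION_COLUMNS

    df = pd.DataFrame(0, index=range(n), columns=list(POPULATION_COLUMNS),
                      dtype=np.int64)
    df["id"] = np.arange(n)
    df["sex"] = sex
    df["age_months"] = age_years * 12
    df["alive"] = 1
    df["marital"] = 1
    df["bmi_cat"] = 1
    df["mmse"] = 28
    return df


def single_condition_registry(name: str = "stroke", absorbing: bool = True):
    """Registry with exactly one stochastic (binary) characteristic."""
    reg = {k: v for k, v in default_registry().items()
           if v.kind in ("fixed", "deterministic")}
    reg[name] = CharacteristicSpec(name, "stochastic", ("absent", "present"),
                                   "binary_logit", ("age", "sex"),
                                   absorbing=absorbing)
    return reg
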