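"""Interval-to-monthly conversion, monthly transition laws and model fitting."""

import numpy as np
import pytest

from morbisim import (fit_transition_model, generate_panel,
                      interval_to_monthly, monthly_transition_probabilities)
from morbisim.errors import DegenerateFitError, DomainError, SchemaError
from morbisim.state import CharacteristicSpec, IndividualState
from morbisim.synthetic import PanelDataset
from morbisim.transitions import FittedTransition, fit_bundle

from conftest import make_cohort, single_condition_registry


class TestIntervalToMonthly:
    def test_fixed_points(self):
        assert interval_to_monthly(0.0, 24) == 0.0
        assert interval_to_monthly(1.0, 24) == 1.0

    def test_round_trip(self):
        m = interval_to_monthly(0.5, 24)
        assert abs(1 - (1 - m) ** 24 - 0.5) < 1e-12
        for p in np.linspace(0.001, 0.999, 57):
            m = interval_to_monthly(p, 24)
            assert abs(1 - (1 - m) ** 24 - p) < 1e-12

    def test_monotonic(self):
        grid = np.linspace(0.0, 1.0, 101)
        m = interval_to_monthly(grid, 24)
        assert np.all(np.diff(m) > 0)

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_domain(self, p):
        with pytest.raises(DomainError):
            interval_to_monthly(p, 24)
        with pytest.raises(DomainError):
            interval_to_monthly(0.5, 0)


def _random_cols(rng, n):
    return {
        "age_months": rng.integers(35 * 12, 100 * 12, n),
        "sex": rng.integers(0, 2, n),
        "education": rng.integers(0, 3, n),
        "ses": rng.integers(0, 3, n),
        "smoking": rng.integers(0, 3, n),
        "inactive": rng.integers(0, 2, n),
        "bmi_cat": rng.integers(0, 4, n),
        "marital": rng.integers(0, 3, n),
        "mmse_band": rng.integers(0, 3, n),
        "hypertension": rng.integers(0, 2, n),
        "diabetes": rng.integers(0, 2, n),
        "depression": rng.integers(0, 2, n),
        "hearing": rng.integers(0, 2, n),
        "vision": rng.integers(0, 2, n),
        "arthritis": rng.integers(0, 2, n),
        "cancer": rng.integers(0, 2, n),
        "chd": rng.integers(0, 2, n),
        "respiratory": rng.integers(0, 2, n),
        "stroke": rng.integers(0, 2, n),
    }


class TestMonthlyProbabilities:
    def test_distributions_sum_to_one(self, truth):
        rng = np.random.default_rng(5)
        cols = _random_cols(rng, 500)
        for name, fit in truth.models.items():
            current_col = name
            current = np.asarray(cols[current_col]) % fit.n_states
            probs = fit.monthly_probs(cols, current)
            assert probs.shape == (500, fit.n_states)
            assert np.all(probs >= 0) and np.all(probs <= 1)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_absorbing_present_stays(self, truth):
        rng = np.random.default_rng(6)
        cols = _random_cols(rng, 100)
        fit = truth["arthritis"]
        probs = fit.monthly_probs(cols, np.ones(100, dtype=int))
        np.testing.assert_array_equal(probs[:, 1], 1.0)
        np.testing.assert_array_equal(probs[:, 0], 0.0)

    def test_logistic_tail_gives_zero_onset(self):
        fit = FittedTransition(name="x", family="binary_logit",
                               states=("absent", "present"),
                               covariates=(), interval_months=24,
                               absorbing=True, beta=np.array([-1e9]))
        cols = {"age_months": np.full(10, 65 * 12)}
        probs = fit.monthly_probs(cols, np.zeros(10, dtype=int))
        np.testing.assert_allclose(probs[:, 1], 0.0, atol=1e-300)

    def test_binary_round_trip_over_interval(self, truth):
        """Compounding the monthly flip 24x reproduces the 2-year
        probability for fixed covariates."""
        rng = np.random.default_rng(7)
        cols = _random_cols(rng, 200)
        for name in ("arthritis", "stroke", "depression", "hearing"):
            fit = truth[name]
            current = np.zeros(200, dtype=int)
            p2y = fit.interval_probs(cols)[:, 1]
            if fit.absorbing:
                expected = p2y
            else:
                expected = p2y  # onset side: current absent
            m = fit.monthly_probs(cols, current)[:, 1]
            np.testing.assert_allclose(1 - (1 - m) ** 24, expected,
                                       atol=1e-9)

    def test_single_individual_map(self, truth):
        s = IndividualState(id=1, sex=1, education=1, ses=1, residence=0,
                            age_months=70 * 12, hypertension=1)
        probs = monthly_transition_probabilities(truth, "chd", s)
        assert set(probs) == {"absent", "present"}
        assert abs(sum(probs.values()) - 1.0) < 1e-12
        s_chd = IndividualState(id=1, sex=1, education=1, ses=1, residence=0,
                                age_months=70 * 12, chd=1)
        assert monthly_transition_probabilities(
            truth, "chd", s_chd)["present"] == 1.0

    def test_missing_covariate_schema_error(self):
        fit = FittedTransition(name="x", family="binary_logit",
                               states=("absent", "present"),
                               covariates=("nonexistent",),
                               interval_months=24, beta=np.zeros(2))
        with pytest.raises(SchemaError, match="nonexistent"):
            fit.monthly_probs({"age_months": np.array([800])},
                              np.zeros(1, dtype=int))


class TestFitting:
    def _onset_panel(self, truth, registry, n=20_000, seed=3,
                     mode="interval"):
        base = make_cohort(n, age_years=70)
        return generate_panel(base, truth, seed=seed, mode=mode,
                              registry=registry)

    def test_constant_outcome_raises(self, truth):
        reg = single_condition_registry("stroke")
        zero = FittedTransition(
            name="stroke", family="binary_logit",
            states=("absent", "present"), covariates=("age", "sex"),
            interval_months=24, absorbing=True,
            beta=np.array([-1e9, 0.0, 0.0]))
        from morbisim.transitions import TransitionModelBundle
        bundle = TransitionModelBundle({"stroke": zero})
        panel = self._onset_panel(bundle, reg, n=500)
        spec = reg["stroke"]
        with pytest.raises(DegenerateFitError):
            fit_transition_model(panel, spec)

    def test_no_event_limit(self):
        """Both states present but nobody flips: predicted onset < 1/n."""
        n = 4000
        base = make_cohort(n, age_years=70)
        base.loc[: n // 4, "hearing"] = 1  # recoverable, own-state predictor
        panel = PanelDataset(wave1=base,
                             wave2=base.assign(
                                 age_months=base.age_months + 24),
                             interval_months=24)
        spec = CharacteristicSpec("hearing", "stochastic",
                                  ("absent", "present"), "binary_logit",
                                  ("age", "sex", "hearing"))
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_transition_model(panel, spec)
        assert fit.metadata["penalized"]
        cols = {"age_months": np.array([70 * 12]), "sex": np.array([0]),
                "hearing": np.array([0])}
        assert fit.interval_probs(cols)[0, 1] < 1.0 / n

    def test_binary_recovery_within_ci(self, truth, registry):
        """Coefficients of a known onset model are recovered within the
        fitted 95% CI for nearly all coefficients."""
        cfg_n = 40_000
        from morbisim import SyntheticConfig, generate_base_population
        base = generate_base_population(
            SyntheticConfig(n_individuals=cfg_n, seed=21))
        panel = generate_panel(base, truth, seed=22, mode="interval",
                               registry=registry)
        hits = total = 0
        for name in ("arthritis", "diabetes", "stroke"):
            fit = fit_transition_model(panel, registry[name])
            assert not fit.metadata["penalized"]
            bse = np.asarray(fit.metadata["bse"])
            err = np.abs(fit.beta - truth[name].beta)
            hits += int((err <= 1.96 * bse).sum())
            total += len(fit.beta)
        assert hits / total >= 0.85

    def test_ordinal_recovery(self, truth, registry):
        from morbisim import SyntheticConfig, generate_base_population
        base = generate_base_population(
            SyntheticConfig(n_individuals=30_000, seed=31))
        panel = generate_panel(base, truth, seed=32, mode="interval",
                               registry=registry)
        fit = fit_transition_model(panel, registry["bmi_cat"])
        assert np.all(np.diff(fit.thresholds) > 0)
        bse = np.asarray(fit.metadata["bse"])
        err = np.abs(fit.beta - truth["bmi_cat"].beta)
        assert np.all(err <= 4 * bse + 0.05)
        np.testing.assert_allclose(fit.thresholds, truth["bmi_cat"].thresholds,
                                   atol=0.3)

    def test_bundle_json_round_trip(self, truth):
        from morbisim.transitions import TransitionModelBundle
        again = TransitionModelBundle.from_json(truth.to_json())
        assert set(again.models) == set(truth.models)
        for name in truth.models:
            np.testing.assert_array_equal(again[name].beta, truth[name].beta)
            assert again[name].covariates == truth[name].covariates
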