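"""Transition models: fitting, serialisation and monthly probabilities.

Each stochastic characteristic has a regression model of its wave-2 state on
wave-1 covariates, fitted on a two-wave panel of survivors:

* ``binary_logit`` — logistic regression.  Absorbing characteristics are
  fitted on the at-risk subset (condition absent at wave 1) as an onset
  model; recoverable ones include their own wave-1 state as a predictor so a
  single model captures both onset and persistence.
* ``ordinal_logit`` — proportional-odds model (ordered categories).
* ``generalised_logit`` — multinomial logit, first state as reference.

The fitted linear predictor yields the probability of each wave-2 state over
the panel interval (2 years by default).  The engine needs *monthly*
probabilities: each off-diagonal interval probability ``p`` is converted with
the constant-hazard formula ``1 - (1 - p)**(1/interval_months)`` and the
stay-probability takes the remainder.  For a binary characteristic with fixed
covariates, compounding the monthly probability over the interval reproduces
the interval probability exactly.

Age enters every design matrix as ``(age_years - 65) / 10`` so that
coefficients are per-decade and O(1); the transform is part of the covariate
schema and applied identically at fit and prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .errors import (DegenerateFitError, DomainError, SchemaError,
                     ConfigurationError)
from .state import CharacteristicSpec, IndividualState, stochastic_specs

AGE_CENTER_YEARS = 65.0
AGE_SCALE_YEARS = 10.0

_SEPARATION_COEF = 15.0  # |coef| beyond this on scaled covariates => separation


def interval_to_monthly(p_interval, interval_months: int):
    """Convert an interval transition probability to a monthly one.

    Constant-hazard assumption: ``1 - (1 - p)**(1/interval_months)``.
    Accepts scalars or arrays; validates the [0, 1] domain.
    """
    if interval_months < 1:
        raise DomainError(f"interval_months must be >= 1, got {interval_months}")
    p = np.asarray(p_interval, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("interval probability outside [0, 1]")
    out = 1.0 - (1.0 - p) ** (1.0 / interval_months)
    return float(out) if np.ndim(p_interval) == 0 else out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


#: derived dummy covariates: name -> (source column, level coded 1)
DERIVED_COVARIATES = {
    "smoking_former": ("smoking", 1),
    "smoking_current": ("smoking", 2),
    "marital_married": ("marital", 1),
    "marital_widowed": ("marital", 2),
}


def covariate_vector(cols: Mapping, name: str) -> np.ndarray:
    """One covariate column; 'age' is derived from age_months, per decade."""
    if name == "age":
        return (np.asarray(cols["age_months"], float) / 12.0
                - AGE_CENTER_YEARS) / AGE_SCALE_YEARS
    if name in DERIVED_COVARIATES:
        src, level = DERIVED_COVARIATES[name]
        try:
            return (np.asarray(cols[src]) == level).astype(float)
        except KeyError:
            raise SchemaError(f"missing covariate: {src!r}") from None
    try:
        col = cols[name]
    except KeyError:
        raise SchemaError(f"missing covariate: {name!r}") from None
    return np.asarray(col, dtype=float)


def design_matrix(cols: Mapping, covariates: Sequence[str]) -> np.ndarray:
    """Intercept-first design matrix for the given covariate names."""
    n = len(np.asarray(cols["age_months"]))
    parts = [np.ones(n)] + [covariate_vector(cols, c) for c in covariates]
    return np.column_stack(parts)


@dataclass
class FittedTransition:
    """One characteristic's fitted (or ground-truth) transition model."""

    name: str
    family: str  # binary_logit | ordinal_logit | generalised_logit
    states: tuple[str, ...]
    covariates: tuple[str, ...]
    interval_months: int
    absorbing: bool = False
    # binary: beta (p+1,); ordinal: beta (p,), thresholds (k-1,) increasing;
    # generalised: beta (p+1, k-1), reference = state 0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))
    thresholds: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    # ---- interval-scale predictions ------------------------------------

    def interval_probs(self, cols: Mapping) -> np.ndarray:
        """Per-state probability at the end of the interval, shape (n, k).

        For absorbing binaries this is the *onset* model (probability of the
        wave-2 state among those at risk at wave 1).
        """
        if self.family == "binary_logit":
            X = design_matrix(cols, self.covariates)
            p1 = _sigmoid(X @ self.beta)
            return np.column_stack([1.0 - p1, p1])
        if self.family == "ordinal_logit":
            X = design_matrix(cols, self.covariates)[:, 1:]  # no intercept
            xb = X @ self.beta
            cum = _sigmoid(self.thresholds[None, :] - xb[:, None])
            cum = np.column_stack([cum, np.ones(len(xb))])
            probs = np.diff(cum, prepend=0.0, axis=1)
            return np.clip(probs, 0.0, 1.0)
        if self.family == "generalised_logit":
            X = design_matrix(cols, self.covariates)
            eta = X @ self.beta  # (n, k-1)
            eta = np.column_stack([np.zeros(len(X)), eta])
            eta -= eta.max(axis=1, keepdims=True)
            e = np.exp(eta)
            return e / e.sum(axis=1, keepdims=True)
        raise ConfigurationError(f"{self.name}: unknown family {self.family}")

    # ---- monthly transition law ----------------------------------------

    def monthly_probs(self, cols: Mapping, current: np.ndarray) -> np.ndarray:
        """Monthly transition distribution given current state, shape (n, k).

        Each destination's interval probability is converted independently;
        the stay-probability takes the remainder (renormalised if the
        converted moves would exceed 1, which cannot occur for realistic
        inputs but is guarded).  An absorbing characteristic already present
        stays present with probability 1.
        """
        current = np.asarray(current, dtype=int)
        n, k = len(current), self.n_states
        p_int = self.interval_probs(cols)

        if self.family == "binary_logit":
            onset = p_int[:, 1]
            if self.absorbing:
                m = interval_to_monthly(onset, self.interval_months)
                out = np.zeros((n, 2))
                at_risk = current == 0
                out[at_risk, 0] = 1.0 - m[at_risk]
                out[at_risk, 1] = m[at_risk]
                out[~at_risk, 1] = 1.0
                return out
            # recoverable: probability of flipping state over the interval
            p_move = np.where(current == 0, onset, 1.0 - onset)
            m = interval_to_monthly(p_move, self.interval_months)
            out = np.zeros((n, 2))
            dest = 1 - current
            out[np.arange(n), dest] = m
            out[np.arange(n), current] = 1.0 - m
            return out

        move = interval_to_monthly(p_int, self.interval_months)
        move[np.arange(n), current] = 0.0
        total = move.sum(axis=1)
        over = total > 1.0
        if np.any(over):
            move[over] *= ((1.0 - 1e-12) / total[over])[:, None]
            total = move.sum(axis=1)
        out = move
        out[np.arange(n), current] = 1.0 - total
        return out

    # ---- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name, "family": self.family,
            "states": list(self.states), "covariates": list(self.covariates),
            "interval_months": self.interval_months,
            "absorbing": self.absorbing,
            "beta": np.asarray(self.beta).tolist(),
            "thresholds": (None if self.thresholds is None
                           else np.asarray(self.thresholds).tolist()),
            "metadata": _jsonable(self.metadata),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedTransition":
        return cls(
            name=d["name"], family=d["family"], states=tuple(d["states"]),
            covariates=tuple(d["covariates"]),
            interval_months=int(d["interval_months"]),
            absorbing=bool(d["absorbing"]),
            beta=np.asarray(d["beta"], dtype=float),
            thresholds=(None if d.get("thresholds") is None
                        else np.asarray(d["thresholds"], dtype=float)),
            metadata=d.get("metadata", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class TransitionModelBundle:
    """Fitted transition models for every stochastic characteristic."""

    models: dict[str, FittedTransition]
    interval_months: int = 24
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> FittedTransition:
        return self.models[name]

    def __contains__(self, name: str) -> bool:
        return name in self.models

    def to_json(self) -> str:
        return json.dumps({
            "interval_months": self.interval_months,
            "metadata": _jsonable(self.metadata),
            "models": {k: m.to_dict() for k, m in self.models.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TransitionModelBundle":
        raw = json.loads(text)
        return cls(
            models={k: FittedTransition.from_dict(v)
                    for k, v in raw["models"].items()},
            interval_months=int(raw["interval_months"]),
            metadata=raw.get("metadata", {}),
        )


# --------------------------------------------------------------------------
# fitting


def _outcome_and_design(panel, spec: CharacteristicSpec):
    """Extract (y wave-2, wave-1 columns, subset mask) for one characteristic.

    Only survivors contribute; absorbing characteristics are further
    restricted to individuals at risk (absent) at wave 1.
    """
    from .state import mmse_band_from_score

    w1, w2 = panel.wave1, panel.wave2
    # np.array (not asarray): a bool 'alive' column would otherwise yield a
    # view, and the &= below would corrupt the shared panel in place
    mask = np.array(w2["alive"], dtype=bool, copy=True)
    if spec.absorbing:
        mask &= np.asarray(w1[spec.name], dtype=int) == 0
    if spec.name == "mmse_band":
        out = (np.asarray(w2["mmse_band"]) if "mmse_band" in w2.columns
               else mmse_band_from_score(np.asarray(w2["mmse"])))
        y = np.asarray(out, dtype=int)[mask]
    else:
        y = np.asarray(w2[spec.name], dtype=int)[mask]
    cols = {c: np.asarray(w1[c])[mask] for c in w1.columns}
    if "mmse_band" not in cols and "mmse" in cols:
        cols["mmse_band"] = np.asarray(mmse_band_from_score(cols["mmse"]))
    return y, cols, mask


def fit_transition_model(panel, spec: CharacteristicSpec,
                         ) -> FittedTransition:
    """Maximum-likelihood fit of the family given by ``spec.model_family``.

    Raises :class:`DegenerateFitError` when the outcome is constant; complete
    separation triggers a warning and a penalised (ridge) refit recorded in
    the metadata.
    """
    if spec.model_family == "none":
        raise ConfigurationError(f"{spec.name}: characteristic takes no model")
    y, cols, _ = _outcome_and_design(panel, spec)
    observed = np.unique(y)
    if len(observed) < 2:
        raise DegenerateFitError(
            f"{spec.name}: outcome constant in panel (value {observed})")

    interval = int(panel.interval_months)
    common = dict(name=spec.name, states=spec.states,
                  covariates=tuple(spec.predictors),
                  interval_months=interval, absorbing=spec.absorbing)

    if spec.model_family == "binary_logit":
        X = design_matrix(cols, spec.predictors)
        beta, bse, meta = _fit_binary(y, X)
        meta["n"] = int(len(y))
        return FittedTransition(family="binary_logit", beta=beta,
                                metadata={**meta, "bse": bse}, **common)

    if spec.model_family == "ordinal_logit":
        k = len(spec.states)
        if len(observed) < k:
            raise DegenerateFitError(
                f"{spec.name}: only {len(observed)}/{k} ordinal levels observed")
        X = design_matrix(cols, spec.predictors)[:, 1:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = OrderedModel(y, X, distr="logit").fit(
                method="bfgs", disp=0, maxiter=500)
        p = X.shape[1]
        beta = np.asarray(res.params[:p])
        thr = np.asarray(res.model.transform_threshold_params(res.params))[1:-1]
        meta = {"n": int(len(y)), "llf": float(res.llf), "penalized": False,
                "bse": np.asarray(res.bse[:p]).tolist()}
        return FittedTransition(family="ordinal_logit", beta=beta,
                                thresholds=thr, metadata=meta, **common)

    # generalised_logit
    k = len(spec.states)
    if len(observed) < k:
        raise DegenerateFitError(
            f"{spec.name}: only {len(observed)}/{k} states observed in panel")
    X = design_matrix(cols, spec.predictors)
    beta, meta = _fit_multinomial(y, X, k)
    meta["n"] = int(len(y))
    return FittedTransition(family="generalised_logit", beta=beta,
                            metadata=meta, **common)


def _fit_binary(y: np.ndarray, X: np.ndarray):
    """Logit MLE with a ridge fallback on separation/non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            if converged and np.all(np.abs(res.params) < _SEPARATION_COEF):
                return (np.asarray(res.params),
                        np.asarray(res.bse).tolist(),
                        {"llf": float(res.llf), "penalized": False})
        except Exception:
            pass
    warnings.warn("separation or non-convergence; refitting with L2 penalty",
                  stacklevel=2)
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=100.0, max_iter=1000)
    lr.fit(X[:, 1:] if X.shape[1] > 1 else np.zeros((len(y), 1)), y)
    beta = np.concatenate([lr.intercept_, lr.coef_.ravel()
                           if X.shape[1] > 1 else []])
    return beta, None, {"llf": None, "penalized": True}


def _fit_multinomial(y: np.ndarray, X: np.ndarray, k: int):
    """MNLogit MLE with a ridge fallback on separation/non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y, X).fit(disp=0, maxiter=500)
            params = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", True))
            if (converged and np.all(np.isfinite(params))
                    and np.all(np.abs(params) < _SEPARATION_COEF)):
                return params, {"llf": float(res.llf), "penalized": False,
                                "bse": np.asarray(res.bse).tolist()}
        except Exception:
            pass
    warnings.warn("separation or non-convergence in multinomial fit; "
                  "refitting with L2 penalty", stacklevel=2)
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=100.0, max_iter=2000)
    lr.fit(X[:, 1:], y)
    # symmetric softmax -> reference-category (state 0) parameterisation
    intercept = lr.intercept_ - lr.intercept_[0]
    coef = lr.coef_ - lr.coef_[0]
    beta = np.vstack([intercept[1:], coef[1:].T])
    return beta, {"llf": None, "penalized": True, "bse": None}


def fit_bundle(panel, registry: Mapping[str, CharacteristicSpec],
               ) -> TransitionModelBundle:
    """Fit every stochastic characteristic's model on the panel."""
    models = {}
    for spec in stochastic_specs(registry):
        models[spec.name] = fit_transition_model(panel, spec)
    return TransitionModelBundle(models=models,
                                 interval_months=int(panel.interval_months))


def monthly_transition_probabilities(bundle: TransitionModelBundle,
                                     characteristic: str,
                                     state: IndividualState) -> dict[str, float]:
    """Per-state monthly probability map for one individual."""
    if characteristic not in bundle:
        raise ConfigurationError(
            f"bundle has no model for {characteristic!r}")
    fit = bundle[characteristic]
    cols = {k: np.asarray([v]) for k, v in state.to_dict().items()}
    from .state import mmse_band_from_score
    cols["mmse_band"] = np.asarray([mmse_band_from_score(state.mmse)])
    current_col = ("mmse_band" if characteristic == "mmse_band"
                   else characteristic)
    current = np.asarray(cols[current_col], dtype=int)
    probs = fit.monthly_probs(cols, current)[0]
    return dict(zip(fit.states, probs.tolist()))
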