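"""Multivariate logistic NTCP model and univariate association screening.

NTCP = exp(g(x)) / (1 + exp(g(x))) with linear predictor
g(x) = alpha + sum_i beta_i x_i. Ships the published fixed 3-variable
model for late GI toxicity

    g(x) = -1.283 + 0.028 * V65 - 1.442 * AH/AC + 1.458 * AcuteGI

where V65 is the percentage (0-100) of rectal volume receiving at least
65 Gy, AH/AC flags antihypertensive/anticoagulant use and AcuteGI flags
grade 1-2 acute toxicity. Refitting on a cohort is by maximum
likelihood (statsmodels Logit). Univariate screening reports the
Spearman rank correlation of each covariate with the late-GI outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .dvh_io import Cohort

__all__ = [
    "LogisticModel",
    "AssociationResult",
    "LogisticNTCPModel",
    "published_model",
    "logistic_ntcp",
    "linear_predictor",
    "fit_logistic",
    "covariate_frame",
    "univariate_association",
    "univariate_logistic",
    "SeparationWarning",
]

PUBLISHED_COEFFICIENTS = {"v65_percent": 0.028, "ah_ac": -1.442, "acute_gi": 1.458}
PUBLISHED_INTERCEPT = -1.283

_COEF_CAP = 50.0  # cap for non-finite coefficients under complete separation


class SeparationWarning(UserWarning):
    """Raised when the outcome is (quasi-)completely separated."""


@dataclass(frozen=True)
class LogisticModel:
    """Logistic NTCP model: intercept alpha and named coefficients beta."""

    intercept: float
    coefficients: dict[str, float]
    converged: bool = True
    separation: bool = False

    @property
    def order(self) -> int:
        """Model order s: number of covariates."""
        return len(self.coefficients)


@dataclass(frozen=True)
class AssociationResult:
    covariate_name: str
    rs: float
    p_value: float


def published_model() -> LogisticModel:
    """The published fixed 3-variable logistic NTCP model (V65 in percent)."""
    return LogisticModel(intercept=PUBLISHED_INTERCEPT, coefficients=dict(PUBLISHED_COEFFICIENTS))


def linear_predictor(x: dict[str, float] | pd.DataFrame, model: LogisticModel):
    """g(x) = alpha + sum_i beta_i x_i; errors on a missing covariate."""
    if isinstance(x, pd.DataFrame):
        missing = [k for k in model.coefficients if k not in x.columns]
        if missing:
            raise KeyError(f"missing covariates: {missing}")
        g = model.intercept + sum(
            beta * x[name].to_numpy(dtype=float)
            for name, beta in model.coefficients.items()
        )
        return np.asarray(g, dtype=float)
    missing = [k for k in model.coefficients if k not in x]
    if missing:
        raise KeyError(f"missing covariates: {missing}")
    return float(model.intercept + sum(b * x[k] for k, b in model.coefficients.items()))


def logistic_ntcp(x: dict[str, float] | pd.DataFrame, model: LogisticModel):
    """NTCP = expit(g(x))."""
    from scipy.special import expit

    g = linear_predictor(x, model)
    out = expit(g)
    return float(out) if np.ndim(out) == 0 else out


def covariate_frame(cohort: Cohort) -> pd.DataFrame:
    """Per-patient covariate table (V65 in percent, binary flags, outcome)."""
    from .evaluation import v_at_dose

    rows = [
        {
            "patient_id": p.patient_id,
            "v65_percent": 100.0 * v_at_dose(p.dvh, 65.0),
            "ah_ac": p.ah_ac,
            "acute_gi": p.acute_gi,
            "age_years": p.age_years,
            "late_gi": p.late_gi,
        }
        for p in cohort
    ]
    return pd.DataFrame(rows).set_index("patient_id")


class LogisticNTCPModel(BaseEstimator, ClassifierMixin):
    """Scikit-learn style logistic NTCP estimator over named covariates.

    ``X`` is a DataFrame with the covariate columns, ``y`` the binary
    outcome. ``fit`` maximizes the Bernoulli likelihood (statsmodels
    Logit, Newton); complete separation yields capped coefficients, a
    warning and ``separation_`` set.
    """

    def __init__(self, covariate_names=("v65_percent", "ah_ac", "acute_gi")):
        self.covariate_names = covariate_names

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("outcome must contain both classes")
        names = list(self.covariate_names)
        design = sm.add_constant(X[names].to_numpy(dtype=float), has_constant="add")
        separation = False
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
                params = res.params
                bse = res.bse
                converged = bool(res.mle_retvals["converged"])
            except (sm.tools.sm_exceptions.PerfectSeparationWarning,
                    sm.tools.sm_exceptions.PerfectSeparationError,
                    np.linalg.LinAlgError):
                separation = True
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, design).fit(method="bfgs", disp=0, maxiter=500)
                params = np.clip(res.params, -_COEF_CAP, _COEF_CAP)
                bse = np.full_like(params, np.inf)
                converged = False
                warnings.warn(
                    "complete separation detected; coefficients capped at "
                    f"+/-{_COEF_CAP}", SeparationWarning, stacklevel=2,
                )
        self.intercept_ = float(params[0])
        self.coef_ = {name: float(b) for name, b in zip(names, params[1:])}
        self.intercept_se_ = float(bse[0])
        self.coef_se_ = {name: float(s) for name, s in zip(names, bse[1:])}
        self.converged_ = converged
        self.separation_ = separation
        self.model_ = LogisticModel(
            intercept=self.intercept_,
            coefficients=dict(self.coef_),
            converged=converged,
            separation=separation,
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = logistic_ntcp(X, self.model_)
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_logistic(cohort: Cohort, covariate_names=("v65_percent", "ah_ac", "acute_gi")) -> LogisticModel:
    """Refit the logistic NTCP model on a cohort by maximum likelihood."""
    X = covariate_frame(cohort)
    est = LogisticNTCPModel(covariate_names=covariate_names)
    est.fit(X, X["late_gi"].to_numpy())
    return est.model_


def univariate_association(cohort: Cohort, covariate_name: str) -> AssociationResult:
    """Spearman rank correlation of one covariate with the late-GI outcome.

    Mid-ranks for ties; two-sided p-value from the t approximation with
    n - 2 degrees of freedom.
    """
    X = covariate_frame(cohort)
    if covariate_name not in X.columns:
        raise KeyError(f"unknown covariate {covariate_name!r}")
    x = X[covariate_name].to_numpy(dtype=float)
    y = X["late_gi"].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError(f"covariate {covariate_name!r} is constant; correlation undefined")
    rs, p = stats.spearmanr(x, y)
    return AssociationResult(covariate_name=covariate_name, rs=float(rs), p_value=float(p))


def univariate_logistic(cohort: Cohort, covariate_name: str) -> LogisticModel:
    """Single-covariate logistic fit (the screening variant phrased as a
    per-covariate logistic regression rather than a rank correlation)."""
    return fit_logistic(cohort, covariate_names=(covariate_name,))
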