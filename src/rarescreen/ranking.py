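"""Poisson-regression patient ranking.

With no diagnosed cases to train on, the rank target is a proxy: the count
of distinct AADCd-associated concepts a patient is gold-positive for,
excluding epilepsy/seizures (whose relationship to the disease is
confounded — oculogyric crises are misread as seizures). A log-link
Poisson regression maps the 10 patient-level concept probabilities
(epilepsy included as a *predictor*) to a predicted symptom count

    E[y | x] = exp(b0 + sum_c b_c x_c),

and that predicted count is the patient's rank score. Goodness of fit is
D-squared, 1 - residual deviance / null deviance. Because the score is a
monotone transform of the linear predictor, the patient ordering is
invariant to the intercept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .concepts import CONCEPTS, NON_EPILEPSY_CONCEPTS, REFERENCE_RANK_COEFFICIENTS

__all__ = [
    "PoissonRankModel",
    "RankResult",
    "PoissonRanker",
    "reference_model",
    "symptom_count_target",
    "fit_poisson",
    "rank_score",
    "d_squared",
    "rank_patients",
]


@dataclass(frozen=True)
class PoissonRankModel:
    intercept: float
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(CONCEPTS):
            raise ValueError("need exactly one coefficient per modeled concept")

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in CONCEPTS])

    def to_json(self) -> str:
        return json.dumps({"intercept": self.intercept,
                           "coefficients": self.coefficients}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PoissonRankModel":
        obj = json.loads(text)
        return cls(intercept=float(obj["intercept"]),
                   coefficients={k: float(v) for k, v in obj["coefficients"].items()})


def reference_model() -> PoissonRankModel:
    """The coefficient vector fitted on the development cohort, intercept 0
    (unpublished; irrelevant to the ordering)."""
    return PoissonRankModel(intercept=0.0,
                            coefficients=dict(REFERENCE_RANK_COEFFICIENTS))


@dataclass(frozen=True)
class RankResult:
    patient_id: str
    score: float
    rank: int  # 1-based, descending score


def symptom_count_target(gold_row) -> int:
    """Count of gold-positive concepts among the 9 non-epilepsy concepts."""
    return int(sum(bool(gold_row[c]) for c in NON_EPILEPSY_CONCEPTS))


class PoissonRanker(RegressorMixin, BaseEstimator):
    """Log-link Poisson regression of symptom count on the 10 concept
    probabilities; maximum likelihood via IRLS (statsmodels GLM).

    Fitted attributes: ``intercept_``, ``coef_`` (ordered as ``CONCEPTS``),
    ``model_`` (the :class:`PoissonRankModel`).
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "PoissonRanker":
        X = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("y must be nonnegative integer counts")
        if len(X) < X.shape[1] + 1:
            raise ValueError(f"need at least {X.shape[1] + 1} patients to fit")
        if np.all(y == 0):
            raise ValueError("degenerate target: all symptom counts are zero")
        const_cols = [c for c in X.columns if X[c].nunique() <= 1]
        if const_cols:
            warnings.warn(f"constant predictor column(s): {const_cols}",
                          stacklevel=2)
        design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        res = sm.GLM(y, design, family=sm.families.Poisson()).fit(
            maxiter=self.max_iter, tol=self.tol, scale=1.0)
        if not res.converged:
            raise RuntimeError(
                f"Poisson IRLS did not converge in {self.max_iter} iterations "
                f"(final deviance {res.deviance:.6g})")
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.bse_ = np.asarray(res.bse[1:], dtype=float)
        self.feature_names_in_ = np.asarray(X.columns)
        self.model_ = PoissonRankModel(
            intercept=self.intercept_,
            coefficients=dict(zip(X.columns, self.coef_)))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = self._as_frame(X)[list(self.feature_names_in_)]
        eta = self.intercept_ + X.to_numpy(dtype=float) @ self.coef_
        return np.exp(eta)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(CONCEPTS):
            raise ValueError(f"expected a 2-D matrix with {len(CONCEPTS)} columns")
        return pd.DataFrame(X, columns=list(CONCEPTS))


def fit_poisson(X: pd.DataFrame, y) -> PoissonRankModel:
    return PoissonRanker().fit(X, y).model_


def rank_score(model: PoissonRankModel, probs) -> float:
    """exp(intercept + sum coefficient * probability); strictly positive."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(CONCEPTS),):
        raise ValueError(f"expected {len(CONCEPTS)} probabilities")
    if probs.min() < 0.0 or probs.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.exp(model.intercept + probs @ model.coef_vector()))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # y log(y/mu) terms vanish at y = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def d_squared(model: PoissonRankModel, X: pd.DataFrame, y) -> float:
    """1 - residual deviance / null deviance (Poisson deviance)."""
    y = np.asarray(y, dtype=float)
    Xf = PoissonRanker._as_frame(X)
    mu = np.exp(model.intercept + Xf.to_numpy(dtype=float) @ model.coef_vector())
    null_dev = _poisson_deviance(y, np.full_like(y, y.mean()))
    if null_dev <= 0.0:
        raise ValueError("null deviance is zero; D-squared undefined")
    return 1.0 - _poisson_deviance(y, mu) / null_dev


def rank_patients(scores: dict[str, float]) -> list[RankResult]:
    """Descending-score ranking; ties broken by patient id so the output is
    a deterministic permutation regardless of input order."""
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [RankResult(patient_id=pid, score=float(s), rank=i + 1)
            for i, (pid, s) in enumerate(ordered)]
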