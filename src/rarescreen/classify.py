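"""Per-concept calibrated 3-class sentence classifiers.

Each concept gets its own max-margin (SVM) model over the combined sentence
features, trained with optional negative downsampling, then calibrated:
the labeled pool is split 2/3 for the base model and 1/3 for per-class
isotonic regression mapping raw margins to probabilities, which are
renormalized onto the simplex. Model selection uses 5x2 cross-validated
multiclass log-loss over a config grid with patient-disjoint folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.isotonic import IsotonicRegression
from sklearn.svm import SVC, LinearSVC
from sklearn.utils.validation import check_is_fitted

from .concepts import KLASS_NAMES, Klass

__all__ = [
    "ConceptClassifierConfig",
    "CalibratedConceptClassifier",
    "CVResult",
    "downsample_negatives",
    "train_calibrated",
    "predict_sentence",
    "multiclass_log_loss",
    "grid_search_5x2",
]

_N_CLASSES = 3


@dataclass(frozen=True)
class ConceptClassifierConfig:
    concept: str | None = None
    kernel: str = "linear"          # linear | rbf
    penalty_param: float = 1.0      # SVM margin penalty C
    gamma: float | str = "scale"    # rbf kernel width (ignored for linear)
    downsample_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.penalty_param <= 0:
            raise ValueError("penalty_param must be positive")
        if not (0.0 < self.downsample_rate <= 1.0):
            raise ValueError("downsample_rate must be in (0, 1]")


def downsample_negatives(X, y: np.ndarray, rate: float, seed: int = 0):
    """Keep every positive and negative-qualified example; keep
    ``round(rate * n_negative)`` negatives sampled without replacement.
    Original example order is preserved. Raises the positive-class
    concentration without touching the informative classes."""
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must be in (0, 1]")
    y = np.asarray(y)
    neg_idx = np.flatnonzero(y == Klass.NEGATIVE)
    if rate == 1.0 or len(neg_idx) == 0:
        return X, y
    n_keep = int(np.floor(rate * len(neg_idx) + 0.5))
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(y != Klass.NEGATIVE), kept_neg]))
    return X[keep], y[keep]


class CalibratedConceptClassifier(ClassifierMixin, BaseEstimator):
    """3-class SVM with per-class isotonic calibration.

    One-vs-rest margins from the base SVM (``LinearSVC`` for the linear
    kernel, ``SVC`` for rbf) are mapped to probabilities by monotone
    nondecreasing per-class isotonic calibrators fitted on a held-out third
    of the (already downsampled) training pool, then renormalized to sum to
    one. Isotonicity preserves within-class rank order of the raw margins.
    Deterministic for fixed data and seed.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0,
                 gamma: str | float = "scale", downsample_rate: float = 1.0,
                 calibration_fraction: float = 1 / 3, seed: int = 0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.downsample_rate = downsample_rate
        self.calibration_fraction = calibration_fraction
        self.seed = seed

    # -- internals --------------------------------------------------------

    def _base_model(self):
        if self.kernel == "linear":
            return LinearSVC(C=self.C, random_state=self.seed, dual=True,
                             max_iter=5000)
        if self.kernel == "rbf":
            return SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                       decision_function_shape="ovr", random_state=self.seed)
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def _margins(self, X) -> np.ndarray:
        """Per-class OvR margins, one column per class in ``classes_``."""
        scores = self.base_model_.decision_function(X)
        if scores.ndim == 1:  # binary base model: sklearn emits one margin
            scores = np.column_stack([-scores, scores])
        return scores

    def _stratified_split(self, y: np.ndarray):
        rng = np.random.default_rng(self.seed)
        train_idx, cal_idx = [], []
        for klass in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == klass))
            n_cal = max(1, int(round(self.calibration_fraction * len(idx))))
            if len(idx) - n_cal < 1:
                raise ValueError(
                    f"class {KLASS_NAMES[int(klass)]!r} has too few examples "
                    "to appear in both the training and calibration portions")
            cal_idx.append(idx[:n_cal])
            train_idx.append(idx[n_cal:])
        return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(cal_idx))

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y) -> "CalibratedConceptClassifier":
        y = np.asarray(y, dtype=int)
        if X.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        X, y = downsample_negatives(X, y, self.downsample_rate, self.seed)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes after downsampling")
        train_idx, cal_idx = self._stratified_split(y)
        self.base_model_ = self._base_model().fit(X[train_idx], y[train_idx])
        margins = self._margins(X[cal_idx])
        y_cal = y[cal_idx]
        self.calibrators_ = []
        for k, klass in enumerate(self.base_model_.classes_):
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(margins[:, k], (y_cal == klass).astype(float))
            self.calibrators_.append(iso)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Simplex probabilities over the three classes (columns ordered
        negative, negative_qualified, positive; absent classes get 0)."""
        check_is_fitted(self, "base_model_")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match training "
                f"layout {self.n_features_in_}")
        margins = self._margins(X)
        raw = np.column_stack([
            cal.predict(margins[:, k]) for k, cal in enumerate(self.calibrators_)
        ])
        full = np.zeros((X.shape[0], _N_CLASSES))
        for k, klass in enumerate(self.base_model_.classes_):
            full[:, int(klass)] = raw[:, k]
        totals = full.sum(axis=1, keepdims=True)
        flat = totals.ravel() <= 0.0
        if flat.any():  # calibrators all at 0: fall back to uniform over seen classes
            for klass in self.base_model_.classes_:
                full[flat, int(klass)] = 1.0 / len(self.base_model_.classes_)
            totals = full.sum(axis=1, keepdims=True)
        return full / totals

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def train_calibrated(X, y, config: ConceptClassifierConfig) -> CalibratedConceptClassifier:
    return CalibratedConceptClassifier(
        kernel=config.kernel, C=config.penalty_param, gamma=config.gamma,
        downsample_rate=config.downsample_rate, seed=config.seed,
    ).fit(X, y)


def predict_sentence(model: CalibratedConceptClassifier, features) -> np.ndarray:
    """One sentence -> simplex-3 probability vector."""
    if sp.issparse(features):
        row = features
    else:
        row = np.asarray(features, dtype=float).reshape(1, -1)
    return model.predict_proba(row)[0]


def multiclass_log_loss(pred: np.ndarray, truth: np.ndarray,
                        eps: float = 1e-15) -> float:
    """Mean negative log probability of the true class, probabilities
    clipped to [eps, 1-eps]."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if pred.shape[0] != len(truth):
        raise ValueError("pred and truth length mismatch")
    p_true = np.clip(pred[np.arange(len(truth)), truth], eps, 1.0 - eps)
    return float(-np.mean(np.log(p_true)))


@dataclass
class CVResult:
    mean_losses: list[float]
    grid: list[ConceptClassifierConfig]
    best_index: int

    @property
    def best_config(self) -> ConceptClassifierConfig:
        return self.grid[self.best_index]


def _config_sort_key(cfg: ConceptClassifierConfig) -> tuple:
    # tie-break: smaller penalty first, linear before rbf (prefer simpler)
    return (cfg.penalty_param, 0 if cfg.kernel == "linear" else 1)


def patient_halves(patient_ids, seed: int, n_repeats: int) -> list[tuple[set, set]]:
    """Seeded 50/50 patient splits for the 2-fold repetitions; every split
    is patient-disjoint and covers all patients."""
    unique_patients = np.unique(np.asarray(patient_ids))
    if len(unique_patients) < 2:
        raise ValueError("need at least 2 patients for patient-disjoint folds")
    halves = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        order = rng.permutation(unique_patients)
        half = len(order) // 2
        halves.append((set(order[:half]), set(order[half:])))
    return halves


def grid_search_5x2(X, y, patient_ids, grid: list[ConceptClassifierConfig],
                    seed: int = 0, n_repeats: int = 5) -> CVResult:
    """5 repetitions of patient-disjoint 2-fold cross-validation.

    Each repetition splits the *patients* 50/50; each half trains a model
    evaluated by multiclass log-loss on the other, giving 10 evaluations
    per grid point. Returns the per-point mean losses and the minimizer
    (ties broken toward the simpler configuration).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    y = np.asarray(y, dtype=int)
    patient_ids = np.asarray(patient_ids)

    folds = []
    for set_a, _ in patient_halves(patient_ids, seed, n_repeats):
        mask_a = np.array([p in set_a for p in patient_ids])
        folds.append((np.flatnonzero(mask_a), np.flatnonzero(~mask_a)))

    losses = np.zeros((len(grid), 2 * n_repeats))
    for g, cfg in enumerate(grid):
        col = 0
        for idx_a, idx_b in folds:
            for train_idx, test_idx in ((idx_a, idx_b), (idx_b, idx_a)):
                model = train_calibrated(X[train_idx], y[train_idx], cfg)
                proba = model.predict_proba(X[test_idx])
                losses[g, col] = multiclass_log_loss(proba, y[test_idx])
                col += 1
    means = losses.mean(axis=1)
    best = min(range(len(grid)),
               key=lambda i: (means[i], _config_sort_key(grid[i])))
    return CVResult(mean_losses=means.tolist(), grid=list(grid), best_index=best)
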