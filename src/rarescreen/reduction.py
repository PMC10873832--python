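"""Reduction: collapsing sentence-level concept probabilities per patient
into one patient-level concept probability.

A patient's chart yields many sentence predictions per concept. The
reduction family covers closed-form aggregators (max, min, mean, and
noisy-or — ``1 - prod(1 - p_i)``, which accumulates independent evidence
with every mention) and trained combiners over fixed-length summaries of
the probability streams. The best kind per concept is chosen by patient-
level average precision against a programmatically built gold standard:
a patient is gold-positive for a concept iff at least one *unqualified*
annotation of it exists anywhere in their notes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .concepts import CONCEPTS
from .corpus import SpanAnnotation
from .evaluation import average_precision

__all__ = [
    "ReductionKind",
    "REDUCTION_TIEBREAK_ORDER",
    "reduce_probabilities",
    "summary_features",
    "TrainedCombiner",
    "train_combiner",
    "build_patient_gold",
    "select_reduction",
    "patient_concept_scores",
]


class ReductionKind(str, Enum):
    MAX = "max"
    MIN = "min"
    MEAN = "mean"
    NOISY_OR = "noisy_or"
    TRAINED_LINEAR = "trained_linear"
    TRAINED_MLP = "trained_mlp"


#: Preference order on ties: closed-form, evidence-accumulating first.
REDUCTION_TIEBREAK_ORDER: tuple[ReductionKind, ...] = (
    ReductionKind.NOISY_OR, ReductionKind.MAX, ReductionKind.MEAN,
    ReductionKind.MIN, ReductionKind.TRAINED_LINEAR, ReductionKind.TRAINED_MLP,
)


def reduce_probabilities(kind: ReductionKind | str, positive_probs) -> float:
    """Collapse a list of positive-class probabilities to one probability.

    Empty evidence reduces to 0 for every kind: a patient with no relevant
    sentences cannot be ranked up.
    """
    kind = ReductionKind(kind)
    p = np.asarray(list(positive_probs), dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if p.size == 0:
        return 0.0
    if kind is ReductionKind.MAX:
        return float(p.max())
    if kind is ReductionKind.MIN:
        return float(p.min())
    if kind is ReductionKind.MEAN:
        return float(p.mean())
    if kind is ReductionKind.NOISY_OR:
        return float(1.0 - np.prod(1.0 - p))
    raise ValueError(f"{kind.value} requires a trained combiner")


def summary_features(p_neg, p_negqual, p_pos) -> np.ndarray:
    """Fixed-length summary of a patient's three class-probability streams.

    Per stream: count, max, mean, and the top-3 order statistics
    (zero-padded), so the summary length never depends on how many
    sentences the patient has.
    """
    out = []
    for stream in (p_neg, p_negqual, p_pos):
        p = np.sort(np.asarray(list(stream), dtype=float))[::-1]
        top3 = np.pad(p[:3], (0, max(0, 3 - p.size)))
        out.extend([float(p.size), float(p.max()) if p.size else 0.0,
                    float(p.mean()) if p.size else 0.0, *top3.tolist()])
    return np.asarray(out)


class TrainedCombiner:
    """Trained reduction over per-patient summaries.

    ``trained_linear`` is a linear SVM whose margins are isotonically mapped
    to [0, 1] on the training summaries; ``trained_mlp`` is a small
    two-layer network used through its predicted probability. Both are
    seeded and deterministic.
    """

    def __init__(self, kind: ReductionKind, seed: int = 0):
        kind = ReductionKind(kind)
        if kind not in (ReductionKind.TRAINED_LINEAR, ReductionKind.TRAINED_MLP):
            raise ValueError(f"{kind.value} is not a trained reduction")
        self.kind = kind
        self.seed = seed

    def fit(self, summaries: np.ndarray, gold: np.ndarray) -> "TrainedCombiner":
        summaries = np.asarray(summaries, dtype=float)
        gold = np.asarray(gold, dtype=int)
        if len(np.unique(gold)) < 2:
            raise ValueError("gold standard is single-class; cannot train a combiner")
        if self.kind is ReductionKind.TRAINED_LINEAR:
            self._svm = LinearSVC(random_state=self.seed, dual=True,
                                  max_iter=5000).fit(summaries, gold)
            margins = self._svm.decision_function(summaries)
            self._iso = IsotonicRegression(y_min=0.0, y_max=1.0,
                                           out_of_bounds="clip")
            self._iso.fit(margins, gold.astype(float))
        else:
            self._mlp = MLPClassifier(hidden_layer_sizes=(8,), max_iter=2000,
                                      random_state=self.seed).fit(summaries, gold)
        return self

    def predict(self, summaries: np.ndarray) -> np.ndarray:
        summaries = np.asarray(summaries, dtype=float)
        if self.kind is ReductionKind.TRAINED_LINEAR:
            return self._iso.predict(self._svm.decision_function(summaries))
        pos_col = int(np.flatnonzero(self._mlp.classes_ == 1)[0])
        return self._mlp.predict_proba(summaries)[:, pos_col]


def train_combiner(kind: ReductionKind | str, summaries: np.ndarray,
                   gold: np.ndarray, seed: int = 0) -> TrainedCombiner:
    return TrainedCombiner(kind, seed=seed).fit(summaries, gold)


def build_patient_gold(
    annotations: list[SpanAnnotation],
    note_patient: dict[str, str],
    patient_ids: list[str],
    concepts: tuple[str, ...] = CONCEPTS,
) -> pd.DataFrame:
    """Patient-concept gold standard from span annotations.

    A patient is positive for a concept iff they have at least one
    unqualified (positive) annotation of it; patients whose only mentions
    are negated / not-patient / hypothetical are negative, as are patients
    with no mentions at all.
    """
    gold = pd.DataFrame(False, index=pd.Index(patient_ids, name="patient_id"),
                        columns=list(concepts))
    for ann in annotations:
        if ann.concept in gold.columns and ann.is_positive:
            pid = note_patient.get(ann.note_id)
            if pid in gold.index:
                gold.loc[pid, ann.concept] = True
    return gold


def select_reduction(
    predictions: dict[str, dict[ReductionKind, np.ndarray]],
    gold: pd.DataFrame,
    candidates: tuple[ReductionKind, ...] = REDUCTION_TIEBREAK_ORDER,
) -> dict[str, ReductionKind]:
    """Per concept, the reduction kind with the highest patient-level
    average precision on validation patients; ties resolve in
    ``REDUCTION_TIEBREAK_ORDER``. ``predictions[concept][kind]`` must align
    with ``gold.index``."""
    chosen: dict[str, ReductionKind] = {}
    for concept, by_kind in predictions.items():
        labels = gold[concept].to_numpy(dtype=int)
        if labels.sum() == 0 or labels.sum() == len(labels):
            raise ValueError(
                f"concept {concept!r} has a degenerate validation gold "
                "standard (needs at least one positive and one negative patient)")
        best_kind, best_ap = None, -np.inf
        for kind in candidates:
            if kind not in by_kind:
                continue
            ap = average_precision(np.asarray(by_kind[kind], dtype=float), labels)
            if ap > best_ap + 1e-12:
                best_kind, best_ap = kind, ap
        if best_kind is None:
            raise ValueError(f"no candidate predictions for concept {concept!r}")
        chosen[concept] = best_kind
    return chosen


def patient_concept_scores(
    sentence_predictions: pd.DataFrame,
    reductions: dict[str, ReductionKind | str],
    patient_ids: list[str],
    concepts: tuple[str, ...] = CONCEPTS,
) -> pd.DataFrame:
    """Patients x concepts matrix of reduced positive-class probabilities.

    ``sentence_predictions`` is the long per-sentence prediction table with
    columns patient_id, concept, p_pos. Patients with no sentences score 0
    for every concept.
    """
    missing = [c for c in concepts if c not in reductions]
    if missing:
        raise ValueError(f"no reduction kind for concepts {missing}")
    matrix = pd.DataFrame(0.0, index=pd.Index(patient_ids, name="patient_id"),
                          columns=list(concepts))
    grouped = sentence_predictions.groupby(["patient_id", "concept"],
                                           observed=True)["p_pos"]
    for (pid, concept), probs in grouped:
        if pid in matrix.index and concept in matrix.columns:
            matrix.loc[pid, concept] = reduce_probabilities(
                ReductionKind(reductions[concept]), probs.to_numpy())
    return matrix
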