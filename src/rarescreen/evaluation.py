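"""Evaluation metrics and protocol.

Average precision and ROC AUC for per-concept patient ranking, prevalence
and lift (AP / prevalence, the multiple over random ordering), the blinded
top/bottom-k review selection, 2x2 significance tests on the review
outcome, and the spectral-clustering + PCA diagnostic over the patient
concept-probability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

__all__ = [
    "ReviewTable2x2",
    "average_precision",
    "roc_auc",
    "lift",
    "concept_metrics",
    "fisher_exact_2x2",
    "chi_square_yates",
    "select_extremes",
    "cluster_diagnostics",
]


@dataclass(frozen=True)
class ReviewTable2x2:
    """Top/bottom review counts: a = top flagged, b = top not-flagged,
    c = bottom flagged, d = bottom not-flagged."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def top_flagged_fraction(self) -> float:
        """Flagged fraction of the top group — the review PPV."""
        return self.a / (self.a + self.b)


def average_precision(scores, labels) -> float:
    """Mean, over the positives, of precision at each positive's rank.

    The step-function (non-interpolated) definition on a stable descending
    sort, so tied scores keep their input order. Requires >= 1 positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    hits = np.cumsum(ranked)
    precision_at_pos = hits[ranked == 1] / (np.flatnonzero(ranked == 1) + 1)
    return float(precision_at_pos.mean())


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: probability a random positive outscores a random
    negative, ties counted 1/2."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def lift(ap: float, prevalence: float) -> float:
    if prevalence <= 0.0:
        raise ValueError("lift undefined at zero prevalence")
    return ap / prevalence


def concept_metrics(scores: pd.DataFrame, gold: pd.DataFrame) -> pd.DataFrame:
    """Per-concept AP / AUC / prevalence / lift rows over a patient cohort.

    ``scores`` and ``gold`` are patients x concepts frames on the same
    index; concepts with degenerate gold get NaN metrics.
    """
    rows = []
    gold = gold.loc[scores.index]
    for concept in scores.columns:
        y = gold[concept].to_numpy(dtype=int)
        s = scores[concept].to_numpy(dtype=float)
        n, n_pos = len(y), int(y.sum())
        prevalence = n_pos / n if n else np.nan
        if 0 < n_pos < n:
            ap = average_precision(s, y)
            auc = roc_auc(s, y)
            row_lift = lift(ap, prevalence)
        else:
            ap = auc = row_lift = np.nan
        rows.append({"concept": concept, "n_subjects": n, "n_positive": n_pos,
                     "prevalence": prevalence, "ap": ap, "auc": auc,
                     "lift": row_lift})
    return pd.DataFrame(rows).set_index("concept")


def _check_margins(table: ReviewTable2x2) -> np.ndarray:
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    return counts


def fisher_exact_2x2(table: ReviewTable2x2) -> float:
    """Two-sided Fisher exact p, probability-ordering definition (sums the
    hypergeometric probabilities of tables as or more extreme)."""
    counts = _check_margins(table)
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def chi_square_yates(table: ReviewTable2x2) -> tuple[float, float]:
    """Continuity-corrected chi-square with 1 df: (statistic, p)."""
    counts = _check_margins(table)
    res = stats.chi2_contingency(counts, correction=True)
    return float(res.statistic), float(res.pvalue)


def select_extremes(ranked, k: int, seed: int = 0):
    """Top-k and bottom-k of a ranked patient list, plus a seeded shuffled
    review order over their union carrying no group labels (reviewers stay
    blinded to which end each patient came from)."""
    ranked = list(ranked)
    if 2 * k > len(ranked):
        raise ValueError(f"2k={2 * k} exceeds {len(ranked)} patients")
    top = ranked[:k]
    bottom = ranked[-k:]
    ids = [r.patient_id for r in top] + [r.patient_id for r in bottom]
    rng = np.random.default_rng(seed)
    review_order = [ids[i] for i in rng.permutation(len(ids))]
    return top, bottom, review_order


def cluster_diagnostics(matrix: pd.DataFrame, n_clusters: int = 5,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Spectral clustering of the patient concept-probability matrix plus a
    2-D PCA projection for plotting.

    Uses only the concept probabilities — never the rank score — so cluster
    structure is an independent check on the ranking. Default 5 clusters
    (the smallest count giving clean, non-tiny groups in the development
    study); exposed as a parameter.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < n_clusters:
        raise ValueError("fewer patients than clusters")
    labels = SpectralClustering(
        n_clusters=n_clusters, random_state=seed, assign_labels="kmeans",
        affinity="nearest_neighbors",
        n_neighbors=min(10, X.shape[0] - 1),
    ).fit_predict(X)
    coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    return labels, coords
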