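"""Metrics, 2x2 significance tests, review selection, clustering."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from rarescreen.evaluation import (
    ReviewTable2x2,
    average_precision,
    chi_square_yates,
    cluster_diagnostics,
    concept_metrics,
    fisher_exact_2x2,
    lift,
    roc_auc,
    select_extremes,
)
from rarescreen.ranking import RankResult


def brute_force_ap(scores, labels):
    """Independent AP oracle: walk the stable descending order explicitly."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    hits, total = 0, 0.0
    for rank, i in enumerate(order, start=1):
        if labels[i]:
            hits += 1
            total += hits / rank
    return total / sum(labels)


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney oracle with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAveragePrecision:
    def test_perfect_separation(self):
        assert average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_hand_enumerated_example(self):
        # positives at ranks 1 and 3: (1/1 + 2/3) / 2
        assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == \
            pytest.approx((1 + 2 / 3) / 2)

    def test_matches_brute_force_on_all_labelings(self):
        rng = np.random.default_rng(0)
        for n in range(2, 7):
            scores = rng.uniform(size=n)
            for labels in product([0, 1], repeat=n):
                if sum(labels) == 0:
                    continue
                assert average_precision(scores, labels) == \
                    pytest.approx(brute_force_ap(scores, labels), abs=1e-12)

    def test_matches_sklearn_when_scores_are_untied(self):
        """With no ties the stable-order step function coincides with the
        library implementation, which groups tied scores by threshold."""
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(8)
        for _ in range(10):
            scores = rng.permutation(np.linspace(0.01, 0.99, 25))
            labels = rng.integers(2, size=25)
            if labels.sum() == 0:
                labels[0] = 1
            assert average_precision(scores, labels) == \
                pytest.approx(average_precision_score(labels, scores), abs=1e-12)

    def test_tied_scores_use_stable_input_order(self):
        scores = [0.5, 0.5, 0.5]
        assert average_precision(scores, [1, 0, 0]) == 1.0
        assert average_precision(scores, [0, 0, 1]) == pytest.approx(1 / 3)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.4, 0.2], [0, 0])


class TestRocAuc:
    def test_perfect_and_random(self):
        assert roc_auc([3, 2, 1], [1, 1, 0]) == 1.0
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=4000)
        labels = rng.integers(2, size=4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.integers(0, 5, size=15).astype(float)  # forces ties
            labels = rng.integers(2, size=15)
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == \
                pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestLift:
    def test_identity_against_prevalence(self):
        ap, prev = 0.44, 0.2
        assert lift(ap, prev) * prev == pytest.approx(ap, abs=1e-12)
        assert lift(0.3, 0.3) == pytest.approx(1.0)

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValueError):
            lift(0.5, 0.0)


class TestFisherExact:
    def test_enumerated_small_table(self):
        # margins (2,2)/(2,2): p(observed)=1/6, the opposite extreme adds 1/6
        table = ReviewTable2x2(2, 0, 0, 2)
        expected = sum(
            hypergeom.pmf(a, 4, 2, 2)
            for a in range(3)
            if hypergeom.pmf(a, 4, 2, 2) <= hypergeom.pmf(2, 4, 2, 2) + 1e-12
        )
        assert fisher_exact_2x2(table) == pytest.approx(1 / 3, abs=1e-12)
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=1e-12)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(ReviewTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(ReviewTable2x2(0, 0, 5, 5))


class TestChiSquareYates:
    def test_balanced_table(self):
        stat, p = chi_square_yates(ReviewTable2x2(10, 10, 10, 10))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        a, b, c, d = 12, 5, 3, 14
        n = a + b + c + d
        expected = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = chi_square_yates(ReviewTable2x2(a, b, c, d))
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_transpose_invariance(self):
        t = ReviewTable2x2(12, 5, 3, 14)
        tt = ReviewTable2x2(12, 3, 5, 14)  # transposed margins
        assert chi_square_yates(t)[0] == pytest.approx(chi_square_yates(tt)[0])
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(tt))


class TestSelectExtremes:
    def _ranked(self, n):
        return [RankResult(f"p{i:03d}", float(n - i), i + 1) for i in range(n)]

    def test_disjoint_top_and_bottom(self):
        top, bottom, review = select_extremes(self._ranked(50), k=10, seed=0)
        assert len(top) == len(bottom) == 10
        assert not {r.patient_id for r in top} & {r.patient_id for r in bottom}
        assert sorted(review) == sorted(
            [r.patient_id for r in top] + [r.patient_id for r in bottom])

    def test_half_split_reviews_everyone_once(self):
        _, _, review = select_extremes(self._ranked(20), k=10, seed=1)
        assert sorted(review) == sorted(f"p{i:03d}" for i in range(20))

    def test_seeded_review_order_reproducible_and_shuffled(self):
        r1 = select_extremes(self._ranked(60), k=15, seed=5)[2]
        r2 = select_extremes(self._ranked(60), k=15, seed=5)[2]
        assert r1 == r2
        assert r1 != sorted(r1)  # blinded order, not rank order

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            select_extremes(self._ranked(10), k=6, seed=0)


class TestClusterDiagnostics:
    def test_recovers_two_separated_blobs(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        blob0 = np.clip(rng.normal(0.15, 0.05, size=(60, 10)), 0, 1)
        blob1 = np.clip(rng.normal(0.85, 0.05, size=(60, 10)), 0, 1)
        matrix = pd.DataFrame(np.vstack([blob0, blob1]))
        truth = np.array([0] * 60 + [1] * 60)
        labels, coords = cluster_diagnostics(matrix, n_clusters=2, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.95
        assert coords.shape == (120, 2)
        # components come variance-ordered
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_too_few_clusters_rejected(self):
        matrix = pd.DataFrame(np.zeros((5, 10)))
        with pytest.raises(ValueError):
            cluster_diagnostics(matrix, n_clusters=1)


def test_concept_metrics_identities():
    idx = [f"p{i}" for i in range(10)]
    scores = pd.DataFrame({"hypotonia": np.linspace(1, 0, 10)}, index=idx)
    gold = pd.DataFrame({"hypotonia": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]}, index=idx)
    row = concept_metrics(scores, gold).loc["hypotonia"]
    assert row["prevalence"] == pytest.approx(row["n_positive"] / row["n_subjects"])
    assert row["lift"] == pytest.approx(row["ap"] / row["prevalence"], abs=1e-12)
    assert row["ap"] == 1.0 and row["auc"] == 1.0
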