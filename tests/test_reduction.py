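"""Reduction functions, patient gold construction, and reduction selection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarescreen.concepts import CONCEPTS
from rarescreen.corpus import SpanAnnotation
from rarescreen.evaluation import average_precision
from rarescreen.reduction import (
    ReductionKind,
    build_patient_gold,
    patient_concept_scores,
    reduce_probabilities,
    select_reduction,
    summary_features,
    train_combiner,
)

probs = st.lists(st.floats(0.0, 1.0), max_size=8)


def union_probability(p):
    """Inclusion-exclusion oracle for P(at least one event)."""
    total = 0.0
    for r in range(1, len(p) + 1):
        for subset in combinations(p, r):
            total += (-1) ** (r + 1) * np.prod(subset)
    return total


class TestReduceProbabilities:
    def test_noisy_or_examples(self):
        assert reduce_probabilities("noisy_or", [0.5, 0.5]) == pytest.approx(0.75)
        assert reduce_probabilities("noisy_or", [0.3]) == pytest.approx(0.3)
        assert reduce_probabilities("max", [0.3]) == pytest.approx(0.3)
        assert reduce_probabilities("noisy_or", []) == 0.0

    def test_empty_evidence_is_zero_for_all_kinds(self):
        for kind in ("max", "min", "mean", "noisy_or"):
            assert reduce_probabilities(kind, []) == 0.0

    def test_noisy_or_matches_inclusion_exclusion_oracle(self):
        rng = np.random.default_rng(0)
        for n in range(1, 5):
            for _ in range(50):
                p = rng.uniform(size=n)
                assert reduce_probabilities("noisy_or", p) == pytest.approx(
                    union_probability(p), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(probs)
    def test_noisy_or_dominates_max(self, p):
        assert reduce_probabilities("noisy_or", p) >= \
            reduce_probabilities("max", p) - 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(probs, st.floats(0.0, 1.0))
    def test_appending_evidence_is_monotone(self, p, extra):
        for kind in ("max", "noisy_or"):
            assert reduce_probabilities(kind, p + [extra]) >= \
                reduce_probabilities(kind, p) - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reduce_probabilities("mean", [0.5, 1.2])


class TestPatientGold:
    def _note_patient(self):
        return {"n1": "pA", "n2": "pA", "n3": "pB"}

    def test_any_positive_annotation_marks_patient(self):
        anns = [SpanAnnotation("n2", "hypotonia", 0, 5)]
        gold = build_patient_gold(anns, self._note_patient(), ["pA", "pB"])
        assert gold.loc["pA", "hypotonia"]
        assert not gold.loc["pB", "hypotonia"]

    def test_only_qualified_mentions_stay_negative(self):
        anns = [SpanAnnotation("n1", "insomnia", 0, 5,
                               modifiers=frozenset({"negated"})),
                SpanAnnotation("n2", "insomnia", 1, 6,
                               modifiers=frozenset({"hypothetical"}))]
        gold = build_patient_gold(anns, self._note_patient(), ["pA"])
        assert not gold.loc["pA", "insomnia"]

    def test_no_annotations_all_absent(self):
        gold = build_patient_gold([], self._note_patient(), ["pA", "pB"])
        assert not gold.to_numpy().any()
        assert list(gold.columns) == list(CONCEPTS)


class TestSelectReduction:
    def _gold(self, labels):
        frame = pd.DataFrame(False, index=[f"p{i}" for i in range(len(labels))],
                             columns=list(CONCEPTS))
        frame["hypotonia"] = labels
        return frame

    def test_strictly_dominating_kind_selected(self):
        gold = self._gold([1, 1, 0, 0])
        preds = {"hypotonia": {
            ReductionKind.MEAN: np.array([0.9, 0.8, 0.1, 0.2]),  # perfect
            ReductionKind.MAX: np.array([0.1, 0.2, 0.9, 0.8]),   # inverted
        }}
        assert select_reduction(preds, gold)["hypotonia"] is ReductionKind.MEAN

    def test_tie_breaks_toward_noisy_or(self):
        gold = self._gold([1, 0])
        same = np.array([0.9, 0.1])
        preds = {"hypotonia": {k: same for k in
                               (ReductionKind.MEAN, ReductionKind.NOISY_OR,
                                ReductionKind.MAX)}}
        assert select_reduction(preds, gold)["hypotonia"] is ReductionKind.NOISY_OR

    def test_degenerate_gold_names_concept(self):
        gold = self._gold([1, 1])
        with pytest.raises(ValueError, match="hypotonia"):
            select_reduction({"hypotonia": {ReductionKind.MAX: np.ones(2)}}, gold)

    def test_single_strong_mention_favours_max_or_noisy_or_over_mean(self):
        """Positive patients carry one strong sentence among low-probability
        noise, so evidence-accumulating reductions must beat averaging."""
        rng = np.random.default_rng(3)
        labels, by_kind = [], {k: [] for k in
                               (ReductionKind.NOISY_OR, ReductionKind.MAX,
                                ReductionKind.MEAN)}
        for i in range(60):
            pos = i < 20
            stream = rng.uniform(0.0, 0.25, size=12)
            if pos:
                stream[rng.integers(12)] = rng.uniform(0.85, 1.0)
            labels.append(int(pos))
            for kind in by_kind:
                by_kind[kind].append(reduce_probabilities(kind, stream))
        gold = pd.DataFrame(False, index=[f"p{i}" for i in range(60)],
                            columns=list(CONCEPTS))
        gold["hypotonia"] = labels
        chosen = select_reduction(
            {"hypotonia": {k: np.array(v) for k, v in by_kind.items()}}, gold)
        assert chosen["hypotonia"] in (ReductionKind.NOISY_OR, ReductionKind.MAX)


class TestTrainedCombiners:
    def test_linear_combiner_recovers_max_rule(self):
        """When the generator's true patient rule is max-of-stream, a trained
        linear combiner should rank at least as well as mean reduction."""
        rng = np.random.default_rng(1)
        summaries, gold, mean_scores = [], [], []
        for _ in range(120):
            label = rng.integers(2)
            stream = rng.uniform(0, 0.3, size=10)
            if label:
                stream[rng.integers(10)] = rng.uniform(0.9, 1.0)
            summaries.append(summary_features([], [], stream))
            mean_scores.append(stream.mean())
            gold.append(label)
        summaries, gold = np.asarray(summaries), np.asarray(gold)
        model = train_combiner("trained_linear", summaries, gold, seed=0)
        ap_trained = average_precision(model.predict(summaries), gold)
        ap_mean = average_precision(np.asarray(mean_scores), gold)
        assert ap_trained >= ap_mean

    def test_constant_summaries_constant_output(self):
        summaries = np.tile(summary_features([0.5], [0.5], [0.5]), (40, 1))
        gold = np.array([0, 1] * 20)
        model = train_combiner("trained_mlp", summaries, gold, seed=0)
        out = model.predict(summaries)
        assert np.allclose(out, out[0])

    def test_same_seed_same_model(self):
        rng = np.random.default_rng(2)
        summaries = rng.uniform(size=(50, 18))
        gold = (summaries[:, 4] > 0.5).astype(int)
        a = train_combiner("trained_mlp", summaries, gold, seed=7)
        b = train_combiner("trained_mlp", summaries, gold, seed=7)
        assert np.array_equal(a.predict(summaries), b.predict(summaries))

    def test_single_class_gold_rejected(self):
        with pytest.raises(ValueError):
            train_combiner("trained_linear", np.zeros((10, 18)), np.zeros(10))


class TestPatientConceptScores:
    def test_single_sentence_patient_equals_that_probability(self):
        preds = pd.DataFrame({"patient_id": ["pA"] * len(CONCEPTS),
                              "concept": list(CONCEPTS),
                              "p_pos": 0.42})
        for kind in ("max", "min", "mean", "noisy_or"):
            matrix = patient_concept_scores(preds, {c: kind for c in CONCEPTS},
                                            ["pA"])
            assert np.allclose(matrix.loc["pA"], 0.42)

    def test_patient_without_sentences_scores_zero(self):
        preds = pd.DataFrame({"patient_id": ["pA"], "concept": ["hypotonia"],
                              "p_pos": [0.9]})
        matrix = patient_concept_scores(preds, {c: "noisy_or" for c in CONCEPTS},
                                        ["pA", "pEmpty"])
        assert matrix.loc["pEmpty"].sum() == 0.0
        assert ((matrix >= 0) & (matrix <= 1)).all().all()

    def test_missing_reduction_kind_rejected(self):
        preds = pd.DataFrame({"patient_id": [], "concept": [], "p_pos": []})
        with pytest.raises(ValueError, match="hypotonia"):
            patient_concept_scores(
                preds, {c: "max" for c in CONCEPTS if c != "hypotonia"}, [])
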