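"""Poisson rank model: target construction, fit, scoring, D-squared."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from rarescreen.concepts import (
    CONCEPTS,
    NON_EPILEPSY_CONCEPTS,
    REFERENCE_RANK_COEFFICIENTS,
)
from rarescreen.ranking import (
    PoissonRanker,
    PoissonRankModel,
    d_squared,
    fit_poisson,
    rank_patients,
    rank_score,
    reference_model,
    symptom_count_target,
)


def _simulate(n, beta0, coefs, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(size=(n, len(CONCEPTS))), columns=list(CONCEPTS))
    beta = np.array([coefs[c] for c in CONCEPTS])
    mu = np.exp(beta0 + X.to_numpy() @ beta)
    return X, rng.poisson(mu)


class TestSymptomCountTarget:
    def test_epilepsy_excluded(self):
        row = {c: True for c in CONCEPTS}
        assert symptom_count_target(row) == 9
        only_epilepsy = {c: c == "epilepsy_or_seizures" for c in CONCEPTS}
        assert symptom_count_target(only_epilepsy) == 0
        assert symptom_count_target({c: False for c in CONCEPTS}) == 0

    def test_counts_each_present_concept_once(self):
        row = {c: c in NON_EPILEPSY_CONCEPTS[:4] for c in CONCEPTS}
        assert symptom_count_target(row) == 4


class TestFit:
    def test_parameter_recovery_single_replicate(self):
        X, y = _simulate(5000, -1.8, REFERENCE_RANK_COEFFICIENTS, seed=0)
        ranker = PoissonRanker().fit(X, y)
        truth = np.array([REFERENCE_RANK_COEFFICIENTS[c] for c in CONCEPTS])
        assert np.all(np.abs(ranker.coef_ - truth) <= 3 * ranker.bse_)

    def test_fit_matches_generic_convex_optimizer(self):
        """IRLS solution equals a direct Nelder/BFGS-style NLL minimizer."""
        X, y = _simulate(50, 0.2, {c: 0.3 for c in CONCEPTS}, seed=1)
        ranker = PoissonRanker().fit(X, y)
        design = np.column_stack([np.ones(len(X)), X.to_numpy()])

        def nll(params):
            eta = design @ params
            return np.sum(np.exp(eta) - y * eta)

        start = np.zeros(design.shape[1])
        res = minimize(nll, start, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000})
        fitted = np.concatenate([[ranker.intercept_], ranker.coef_])
        assert np.allclose(fitted, res.x, atol=1e-6)

    def test_all_zero_counts_flagged(self):
        X = pd.DataFrame(np.random.default_rng(0).uniform(size=(30, 10)),
                         columns=list(CONCEPTS))
        with pytest.raises(ValueError, match="degenerate"):
            PoissonRanker().fit(X, np.zeros(30))

    def test_constant_column_warns(self):
        X, y = _simulate(60, 0.0, {c: 0.2 for c in CONCEPTS}, seed=2)
        X["hypotonia"] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            PoissonRanker().fit(X, y)

    def test_too_few_patients_rejected(self):
        X, y = _simulate(8, 0.0, {c: 0.0 for c in CONCEPTS}, seed=3)
        with pytest.raises(ValueError, match="at least"):
            PoissonRanker().fit(X, y)


class TestRankScore:
    def test_unit_change_in_developmental_delay(self):
        model = reference_model()
        base = np.full(len(CONCEPTS), 0.5)
        lo, hi = base.copy(), base.copy()
        idx = CONCEPTS.index("developmental_delay")
        lo[idx], hi[idx] = 0.0, 1.0
        ratio = rank_score(model, hi) / rank_score(model, lo)
        assert ratio == pytest.approx(np.exp(1.299), rel=1e-12)

    def test_epilepsy_probability_lowers_score(self):
        model = reference_model()
        base = np.full(len(CONCEPTS), 0.5)
        worse = base.copy()
        worse[CONCEPTS.index("epilepsy_or_seizures")] = 0.9
        assert rank_score(model, worse) < rank_score(model, base)

    def test_all_zero_probabilities_give_exp_intercept(self):
        model = PoissonRankModel(intercept=1.5,
                                 coefficients=dict(REFERENCE_RANK_COEFFICIENTS))
        assert rank_score(model, np.zeros(10)) == pytest.approx(np.exp(1.5))

    def test_score_positive_and_shape_checked(self):
        model = reference_model()
        assert rank_score(model, np.ones(10)) > 0
        with pytest.raises(ValueError):
            rank_score(model, np.ones(9))

    def test_monotone_in_coefficient_sign(self):
        model = reference_model()
        rng = np.random.default_rng(4)
        base = rng.uniform(size=10)
        for concept, coef in REFERENCE_RANK_COEFFICIENTS.items():
            up = base.copy()
            idx = CONCEPTS.index(concept)
            up[idx] = min(1.0, base[idx] + 0.1)
            if up[idx] == base[idx]:
                continue
            delta = rank_score(model, up) - rank_score(model, base)
            assert np.sign(delta) == np.sign(coef)


class TestDSquared:
    def test_perfect_model_scores_one(self):
        X = pd.DataFrame(np.zeros((40, 10)), columns=list(CONCEPTS))
        X["hypotonia"] = [1.0] * 20 + [0.0] * 20
        y = np.array([3.0] * 20 + [1.0] * 20)
        exact = PoissonRankModel(intercept=0.0,
                                 coefficients={**{c: 0.0 for c in CONCEPTS},
                                               "hypotonia": np.log(3.0)})
        assert d_squared(exact, X, y) == pytest.approx(1.0, abs=1e-12)

    def test_zero_null_deviance_rejected(self):
        X = pd.DataFrame(np.zeros((10, 10)), columns=list(CONCEPTS))
        model = PoissonRankModel(intercept=np.log(3.0),
                                 coefficients={c: 0.0 for c in CONCEPTS})
        with pytest.raises(ValueError):
            d_squared(model, X, np.full(10, 3.0))

    def test_intercept_only_fit_scores_zero(self):
        y = np.array([0, 1, 2, 3, 4, 5.0])
        X = pd.DataFrame(np.zeros((6, 10)), columns=list(CONCEPTS))
        model = PoissonRankModel(intercept=np.log(y.mean()),
                                 coefficients={c: 0.0 for c in CONCEPTS})
        assert d_squared(model, X, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_deviances(self):
        # 4 patients, single active predictor; deviances computed by hand
        X = pd.DataFrame(np.zeros((4, 10)), columns=list(CONCEPTS))
        X["hypotonia"] = [0.0, 0.0, 1.0, 1.0]
        y = np.array([1.0, 2.0, 3.0, 6.0])
        model = PoissonRankModel(intercept=np.log(1.5),
                                 coefficients={**{c: 0.0 for c in CONCEPTS},
                                               "hypotonia": np.log(3.0)})
        mu = np.array([1.5, 1.5, 4.5, 4.5])
        dev = 2 * np.sum(y * np.log(y / mu) - (y - mu))
        mu0 = np.full(4, y.mean())
        dev0 = 2 * np.sum(y * np.log(y / mu0) - (y - mu0))
        assert d_squared(model, X, y) == pytest.approx(1 - dev / dev0, rel=1e-12)


class TestRankPatients:
    def test_descending_with_stable_id_tiebreak(self):
        scores = {"b": 2.0, "a": 2.0, "c": 5.0}
        ranked = rank_patients(scores)
        assert [r.patient_id for r in ranked] == ["c", "a", "b"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_input_order_invariance(self):
        scores = {f"p{i}": float(i % 7) for i in range(30)}
        shuffled = dict(sorted(scores.items(), key=lambda kv: hash(kv[0])))
        assert rank_patients(scores) == rank_patients(shuffled)

    def test_intercept_invariance_of_ordering(self):
        rng = np.random.default_rng(6)
        probs = rng.uniform(size=(25, 10))
        m0 = reference_model()
        m1 = PoissonRankModel(intercept=2.5,
                              coefficients=dict(REFERENCE_RANK_COEFFICIENTS))
        s0 = {f"p{i}": rank_score(m0, row) for i, row in enumerate(probs)}
        s1 = {f"p{i}": rank_score(m1, row) for i, row in enumerate(probs)}
        assert [r.patient_id for r in rank_patients(s0)] == \
               [r.patient_id for r in rank_patients(s1)]


def test_fit_poisson_round_trips_through_json():
    X, y = _simulate(200, -0.5, {c: 0.25 for c in CONCEPTS}, seed=7)
    model = fit_poisson(X, y)
    back = PoissonRankModel.from_json(model.to_json())
    assert back == model
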