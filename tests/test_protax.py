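import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protaxsound.features import block_distances
from protaxsound.protax import (
    UNKNOWN,
    ClassificationResult,
    ProtaxCalibrator,
    ReferenceDatabase,
    TrainingEvent,
    build_predictors,
    generate_training_events,
    modified_logit,
    simulate_events,
)


class TestModifiedLogit:
    def test_midpoint_maps_to_zero(self):
        assert modified_logit(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_endpoints_are_finite_closed_forms(self):
        # logit(eps/(1-eps)) at eps = 0.001
        expected = np.log(0.001 / 0.999)
        assert modified_logit(0.0) == pytest.approx(expected, abs=1e-12)
        assert modified_logit(1.0) == pytest.approx(-expected, abs=1e-12)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            modified_logit(1.2)
        with pytest.raises(ValueError):
            modified_logit(-0.1)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_and_antisymmetric(self, p, q):
        lo, hi = sorted((p, q))
        assert modified_logit(lo) <= modified_logit(hi)
        assert modified_logit(p) == pytest.approx(-modified_logit(1 - p), abs=1e-9)


def _toy_refdb():
    rng = np.random.default_rng(0)
    summaries = rng.standard_normal((4, 96))
    return ReferenceDatabase(
        sample_ids=["a1", "a2", "b1", "b2"],
        species_of=np.asarray(["A", "A", "B", "B"]),
        summaries=summaries,
    )


class TestBuildPredictors:
    def test_vector_has_eight_predictors_per_candidate(self):
        db = _toy_refdb()
        X = build_predictors(db.summaries[0], db, np.array([0.7, 0.3]), np.array([0.5, 0.5]))
        assert X.shape == (2, 8)

    def test_query_identical_to_reference_has_zero_distances(self):
        db = _toy_refdb()
        X = build_predictors(db.summaries[2], db, np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(X[1, :6], 0.0, atol=1e-12)  # species B row

    def test_minima_match_brute_force_over_reference_pairs(self):
        db = _toy_refdb()
        q = np.random.default_rng(5).standard_normal(96)
        X = build_predictors(q, db, np.array([0.4, 0.6]), np.array([0.2, 0.8]))
        for si, sp in enumerate(["A", "B"]):
            refs = [i for i, s in enumerate(db.species_of) if s == sp]
            brute = np.min([block_distances(q, db.summaries[i]) for i in refs], axis=0)
            np.testing.assert_allclose(X[si, :6], brute)

    def test_probability_predictors_use_modified_logit(self):
        db = _toy_refdb()
        X = build_predictors(db.summaries[0], db, np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert X[0, 6] == pytest.approx(modified_logit(1.0))
        assert X[1, 6] == pytest.approx(modified_logit(0.0))
        assert X[0, 7] == pytest.approx(0.0)

    def test_misaligned_probability_vector_rejected(self):
        db = _toy_refdb()
        with pytest.raises(ValueError, match="classes"):
            build_predictors(db.summaries[0], db, np.array([0.5, 0.3, 0.2]), np.array([0.5, 0.5]))


class TestTrainingEvents:
    def test_two_events_per_reference_sample(self):
        db = _toy_refdb()
        probs = np.full((4, 2), 0.5)
        events = generate_training_events(db, probs, probs)
        assert len(events) == 8
        assert sum(e.mode == "known" for e in events) == 4

    def test_unknown_mode_excludes_query_species(self):
        db = _toy_refdb()
        probs = np.full((4, 2), 0.5)
        events = generate_training_events(db, probs, probs)
        for e in events:
            if e.mode == "unknown":
                assert e.truth == UNKNOWN
                sp = db.species_of[db.sample_ids.index(e.query_id)]
                assert sp not in e.candidates

    def test_singleton_species_gets_sentinel_distances(self):
        rng = np.random.default_rng(1)
        db = ReferenceDatabase(
            sample_ids=["a1", "b1", "b2"],
            species_of=np.asarray(["A", "B", "B"]),
            summaries=rng.standard_normal((3, 96)),
        )
        probs = np.full((3, 2), 0.5)
        events = generate_training_events(db, probs, probs)
        known_a = next(e for e in events if e.query_id == "a1" and e.mode == "known")
        dm = db.block_distance_matrices()
        sentinel = dm.reshape(6, -1).max(axis=1)
        np.testing.assert_allclose(known_a.X[0, :6], sentinel)  # A emptied by removal
        assert known_a.truth == "A"

    def test_truth_must_be_a_candidate(self):
        with pytest.raises(ValueError):
            TrainingEvent(X=np.zeros((1, 8)), candidates=["A"], truth="B")


class TestCalibratorFit:
    def test_distance_informative_events_get_negative_slopes(self):
        rng = np.random.default_rng(2)
        events = []
        for k in range(300):
            X = np.abs(rng.standard_normal((3, 8)))
            y = rng.integers(0, 3)
            X[y, :6] *= 0.1  # true species has the smallest distances
            events.append(TrainingEvent(X=X, candidates=["a", "b", "c"],
                                        truth="abc"[y], mode="known"))
        for k in range(100):
            X = 1.0 + np.abs(rng.standard_normal((3, 8)))
            events.append(TrainingEvent(X=X, candidates=["a", "b", "c"],
                                        truth=UNKNOWN, mode="unknown"))
        cal = ProtaxCalibrator().fit(events)
        assert cal.converged_
        assert np.all(cal.coef_[:6] <= 0.0)

    def test_identical_predictors_give_uniform_probabilities(self):
        events = simulate_events(0.0, np.zeros(8), 600, n_candidates=3, seed=0)
        cal = ProtaxCalibrator(prior_sd=1.0).fit(events)
        # identical predictor rows across candidates -> equal species shares
        p = cal.predict_proba(np.ones((3, 8)))
        assert p[0] == pytest.approx(p[1], abs=1e-12)
        assert p[1] == pytest.approx(p[2], abs=1e-12)
        # uninformative simulated design -> slopes shrink toward zero
        assert np.abs(cal.coef_).max() < 0.2

    def test_parameter_recovery_within_three_standard_errors(self):
        beta0, beta = 1.0, np.array([-1.5, -0.8, 0.0, -0.3, 0.5, -0.2, 1.2, 0.9])
        events = simulate_events(beta0, beta, 2000, n_candidates=10, seed=7)
        cal = ProtaxCalibrator(prior_sd=10.0).fit(events)
        assert cal.converged_
        se = cal.standard_errors(events)
        # compare on the standardized scale the estimator works on: transform
        # the true coefficients by the same standardization
        truth_std = np.concatenate([
            [beta0 + beta @ cal.x_mean_], beta * cal.x_sd_,
        ])
        z = np.abs(np.concatenate([[cal.intercept_], cal.coef_]) - truth_std) / se
        assert np.all(z < 3.0)

    def test_single_mode_events_rejected(self):
        events = [e for e in simulate_events(0.0, np.zeros(8), 50, seed=1)
                  if e.mode == "known"]
        with pytest.raises(ValueError, match="both"):
            ProtaxCalibrator().fit(events)


class TestPredict:
    def _fitted(self):
        events = simulate_events(0.5, np.array([-1.0] * 6 + [1.0, 1.0]), 400, seed=3)
        return ProtaxCalibrator().fit(events)

    def test_probabilities_sum_to_one(self):
        cal = self._fitted()
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = cal.predict_proba(rng.standard_normal((5, 8)))
            assert p.shape == (6,)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_candidate_zero_score_splits_evenly_with_unknown(self):
        cal = self._fitted()
        # craft predictors whose linear score is exactly 0: exp(0)/(exp(0)+1)
        z = -cal.intercept_ * cal.coef_ / (cal.coef_ @ cal.coef_)
        x = cal.x_mean_ + z * cal.x_sd_
        p = cal.predict_proba(x[None, :])
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-9)

    def test_two_species_toy_matches_hand_softmax(self):
        cal = self._fitted()
        X = np.random.default_rng(4).standard_normal((2, 8))
        Z = (X - cal.x_mean_) / cal.x_sd_
        scores = cal.intercept_ + Z @ cal.coef_
        expect = np.exp(np.append(scores, 0.0))
        expect /= expect.sum()
        np.testing.assert_allclose(cal.predict_proba(X), expect, atol=1e-12)

    def test_candidate_permutation_permutes_probabilities(self):
        cal = self._fitted()
        X = np.random.default_rng(5).standard_normal((4, 8))
        perm = [2, 0, 3, 1]
        p = cal.predict_proba(X)
        q = cal.predict_proba(X[perm])
        np.testing.assert_allclose(q[:4], p[:4][perm], atol=1e-12)
        assert q[4] == pytest.approx(p[4], abs=1e-12)

    def test_monotonicity_in_distance_predictor(self):
        cal = self._fitted()
        assert cal.coef_[0] < 0  # fitted slope on x1 is negative by design
        X = np.abs(np.random.default_rng(6).standard_normal((3, 8)))
        p0 = cal.predict_proba(X)
        X2 = X.copy()
        X2[0, 0] += 1.0  # worsen species 0's best match
        p1 = cal.predict_proba(X2)
        assert p1[0] < p0[0]
        assert np.all(p1[1:] >= p0[1:])

    def test_classification_result_contract(self):
        cal = self._fitted()
        res = cal.classify("q", np.zeros((3, 8)), ["a", "b", "c"])
        assert res.outcomes[-1] == UNKNOWN
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        ranked = res.ranked()
        assert list(ranked["rank"]) == [1, 2, 3, 4]
        with pytest.raises(ValueError):
            ClassificationResult("q", ["a"], np.array([0.6, 0.6]))

    def test_json_round_trip(self):
        cal = self._fitted()
        text = cal.to_json(["a", "b"])
        back, species = ProtaxCalibrator.from_json(text)
        assert species == ["a", "b"]
        X = np.random.default_rng(7).standard_normal((2, 8))
        np.testing.assert_allclose(back.predict_proba(X), cal.predict_proba(X))
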