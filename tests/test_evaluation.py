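import numpy as np
import pandas as pd
import pytest

from protaxsound.evaluation import (
    make_cv_folds,
    reliability_curve,
    reliability_from_results,
    species_calibration_pvalues,
    top1_accuracy,
)
from protaxsound.protax import UNKNOWN, ClassificationResult


def _result(qid, probs, species=("a", "b", "c")):
    p = np.asarray(probs, dtype=float)
    return ClassificationResult(qid, list(species) + [UNKNOWN], p / p.sum())


class TestTop1Accuracy:
    def test_all_correct_and_all_wrong(self):
        results = [_result("q1", [0.9, 0.05, 0.03, 0.02]),
                   _result("q2", [0.1, 0.8, 0.05, 0.05])]
        assert top1_accuracy(results, ["a", "b"]) == 1.0
        assert top1_accuracy(results, ["b", "a"]) == 0.0

    def test_three_query_toy_counts_two_thirds(self):
        results = [
            _result("q1", [0.7, 0.1, 0.1, 0.1]),   # argmax a, truth a -> hit
            _result("q2", [0.1, 0.7, 0.1, 0.1]),   # argmax b, truth b -> hit
            _result("q3", [0.7, 0.1, 0.1, 0.1]),   # argmax a, truth c -> miss
        ]
        assert top1_accuracy(results, ["a", "b", "c"]) == pytest.approx(2 / 3)

    def test_unknown_counts_only_for_out_of_database_queries(self):
        results = [_result("q1", [0.1, 0.1, 0.1, 0.7])] * 2
        assert top1_accuracy(results, ["a", UNKNOWN], in_database=[True, False]) == 0.5

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            top1_accuracy([_result("q", [1, 0, 0, 0])], [])


class TestReliabilityCurve:
    def test_perfect_confident_classifier_sits_on_identity(self):
        curve = reliability_curve(np.ones(10), np.ones(10))
        np.testing.assert_array_equal(curve.cum_predicted, np.arange(1, 11))
        np.testing.assert_array_equal(curve.cum_correct, np.arange(1, 11))
        assert curve.deviation == 0.0

    def test_calibrated_bernoulli_draws_stay_close_to_identity(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.2, 0.95, 1000)
        y = rng.random(1000) < p
        assert reliability_curve(p, y).deviation < 0.05

    def test_maximal_overconfidence_is_detected(self):
        n = 50
        curve = reliability_curve(np.full(n, 0.9), np.zeros(n))
        assert curve.cum_correct[-1] == 0.0
        assert curve.cum_predicted[-1] == pytest.approx(0.9 * n)
        assert curve.deviation == pytest.approx(np.mean(0.9 * np.arange(1, n + 1)) / n)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reliability_curve(np.empty(0), np.empty(0))


class TestSpeciesPvalues:
    def test_degenerate_single_sample_certain_and_correct(self):
        results = [_result("q", [1e-9, 1e-9, 1e-9, 0.0], species=("a", "b", "c"))]
        results = [_result("q", [1.0, 0.0, 0.0, 0.0])]
        out = species_calibration_pvalues(results, ["a"], n_sims=2000, seed=0)
        assert out[0].p_value == 1.0
        assert out[0].n == 1 and out[0].k == 1

    def test_gross_overconfidence_flagged(self):
        # 20 samples, all predicted 0.5 for the top class, all correct:
        # binomial tail P(X = 20) = 2^-20 -> tiny two-tailed p
        results = [_result(f"q{i}", [0.5, 0.3, 0.2, 0.0]) for i in range(20)]
        out = species_calibration_pvalues(results, ["a"] * 20, n_sims=10000, seed=1)
        assert out[0].p_value < 0.01

    def test_calibrated_cohort_gives_roughly_uniform_pvalues(self):
        rng = np.random.default_rng(2)
        results, truth = [], []
        for sp in range(25):
            for i in range(20):
                p_top = rng.uniform(0.3, 0.95)
                correct = rng.random() < p_top  # calibrated by construction
                rest = (1 - p_top) / 3
                probs = np.full(4, rest)
                probs[0] = p_top
                outcomes = [f"sp{sp}", "zz_other", "zz_b", UNKNOWN]
                if not correct:  # top mass goes to a decoy species
                    outcomes = ["zz_other", f"sp{sp}", "zz_b", UNKNOWN]
                results.append(ClassificationResult(f"s{sp}q{i}", outcomes, probs))
                truth.append(f"sp{sp}")
        out = species_calibration_pvalues(results, truth, n_sims=4000, seed=3)
        ps = np.array([c.p_value for c in out])
        # discreteness piles mass near 1; just require no excess of tiny p
        assert (ps < 0.05).mean() < 0.2

    def test_order_invariance_within_species(self):
        results = [_result(f"q{i}", [0.5 + 0.01 * i, 0.2, 0.2, 0.1]) for i in range(6)]
        truth = ["a", "b", "a", "a", "b", "a"]
        a = species_calibration_pvalues(results, truth, n_sims=3000, seed=4)
        perm = [3, 1, 5, 0, 4, 2]
        b = species_calibration_pvalues([results[i] for i in perm],
                                        [truth[i] for i in perm], n_sims=3000, seed=4)
        assert {c.species: c.k for c in a} == {c.species: c.k for c in b}

    def test_low_n_sims_warns(self):
        results = [_result("q", [1.0, 0.0, 0.0, 0.0])]
        with pytest.warns(UserWarning, match="unstable"):
            species_calibration_pvalues(results, ["a"], n_sims=100, seed=0)


class TestMakeCvFolds:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["species_id", "author", "day"])

    def test_distinct_sessions_spread_evenly(self):
        rows = [("s1", f"auth{i}", f"day{i}") for i in range(10)]
        folds = make_cv_folds(self._meta(rows), k=5, seed=0)
        counts = np.bincount(folds, minlength=5)
        assert set(counts) == {2}

    def test_shared_author_day_never_split(self):
        rows = [("s1", "a", "d1"), ("s1", "a", "d1"), ("s1", "b", "d2"),
                ("s1", "c", "d3"), ("s1", "e", "d4")]
        folds = make_cv_folds(self._meta(rows), k=2, seed=3)
        assert folds[0] == folds[1]

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"s{rng.integers(3)}", f"a{rng.integers(4)}", f"d{rng.integers(5)}")
            for _ in range(60)
        ]
        folds = make_cv_folds(self._meta(rows), k=5, seed=2)
        assert folds.size == 60
        assert set(folds) <= {0, 1, 2, 3, 4}

    def test_atomic_single_group_species_warns(self):
        rows = [("lonely", "a", "d"), ("lonely", "a", "d")]
        with pytest.warns(UserWarning, match="lonely"):
            make_cv_folds(self._meta(rows), k=2, seed=0)

    def test_deterministic_given_seed(self):
        rows = [(f"s{i % 4}", f"a{i % 3}", f"d{i % 5}") for i in range(40)]
        f1 = make_cv_folds(self._meta(rows), k=5, seed=9)
        f2 = make_cv_folds(self._meta(rows), k=5, seed=9)
        np.testing.assert_array_equal(f1, f2)
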