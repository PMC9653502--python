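import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ontofeat.models import (
    CVConfig,
    EvalError,
    ModelSpec,
    balanced_accuracy,
    categorize_results,
    cross_validate,
    feature_importance,
    fit_binary_relevance,
    fit_predict_binary_relevance,
    hamming_loss,
    recall_macro,
    relative_improvement,
    runtime_benchmark,
)

from _metric_oracles import (
    oracle_balanced_accuracy,
    oracle_hamming,
    oracle_recall,
)


class TestHammingLoss:
    def test_identity_is_zero(self):
        Y = np.eye(3, dtype=int)
        assert hamming_loss(Y, Y) == 0.0

    def test_complement_is_one(self):
        Y = np.eye(3, dtype=int)
        assert hamming_loss(Y, 1 - Y) == 1.0

    def test_single_cell_difference(self):
        Y = np.zeros((2, 3), dtype=int)
        P = Y.copy()
        P[0, 0] = 1
        assert hamming_loss(Y, P) == pytest.approx(1 / 6)

    def test_shape_mismatch(self):
        with pytest.raises(EvalError, match="shape"):
            hamming_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    @given(arrays(np.int8, (4, 3), elements=st.integers(0, 1)),
           arrays(np.int8, (4, 3), elements=st.integers(0, 1)))
    def test_symmetric(self, A, B):
        assert hamming_loss(A, B) == hamming_loss(B, A)


class TestBalancedAccuracy:
    def test_perfect(self):
        Y = np.array([[1, 0], [0, 1]])
        assert balanced_accuracy(Y, Y) == 1.0

    def test_always_negative_is_half(self):
        Y = np.array([[1], [0], [1], [0]])
        assert balanced_accuracy(Y, np.zeros_like(Y)) == 0.5

    def test_matches_bruteforce_on_random_case(self):
        rng = np.random.default_rng(11)
        Y = rng.integers(0, 2, (4, 3))
        Y[:, 0] = [1, 0, 1, 0]  # guarantee one evaluable label
        P = rng.integers(0, 2, (4, 3))
        assert balanced_accuracy(Y, P) == pytest.approx(oracle_balanced_accuracy(Y, P), abs=1e-12)

    def test_all_degenerate_labels_raise(self):
        Y = np.ones((3, 2), dtype=int)
        with pytest.raises(EvalError, match="undefined"):
            balanced_accuracy(Y, Y)


class TestRecall:
    def test_perfect(self):
        Y = np.array([[1, 0], [0, 1], [1, 1]])
        assert recall_macro(Y, Y) == 1.0

    def test_nothing_predicted(self):
        Y = np.array([[1, 0], [0, 1], [1, 1]])
        assert recall_macro(Y, np.zeros_like(Y)) == 0.0

    def test_hand_built_case(self):
        # label 0: 2 positives, 1 hit → 0.5 ; label 1: 1 positive, 1 hit → 1.0
        Y = np.array([[1, 0], [1, 1], [0, 0]])
        P = np.array([[1, 0], [0, 1], [0, 0]])
        assert recall_macro(Y, P) == pytest.approx((0.5 + 1.0) / 2)
        assert recall_macro(Y, P) == pytest.approx(oracle_recall(Y, P), abs=1e-12)


class TestCategorize:
    def test_equal_sets_correct(self):
        counts = categorize_results([frozenset({"HSType1"})], [frozenset({"HSType1"})])
        assert counts == {"correct": 1, "partially_correct": 0, "incorrect": 0}

    def test_overlap_not_equal_is_partial(self):
        counts = categorize_results(
            [frozenset({"HSType1"})], [frozenset({"HSType1", "Gliosis"})]
        )
        assert counts["partially_correct"] == 1

    def test_disjoint_is_incorrect(self):
        counts = categorize_results([frozenset({"HSType1"})], [frozenset({"Tumor"})])
        assert counts["incorrect"] == 1

    def test_length_mismatch(self):
        with pytest.raises(EvalError, match="length"):
            categorize_results([frozenset()], [])

    @given(
        st.lists(
            st.tuples(
                st.frozensets(st.sampled_from("abcd"), min_size=1),
                st.frozensets(st.sampled_from("abcd")),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_counts_partition_n(self, pairs):
        true_sets = [t for t, _ in pairs]
        pred_sets = [p for _, p in pairs]
        counts = categorize_results(true_sets, pred_sets)
        assert sum(counts.values()) == len(pairs)


class TestRelativeImprovement:
    @pytest.mark.parametrize("base,mapped,expected", [(14, 19, 35.7), (11, 17, 54.5), (9, 12, 33.3)])
    def test_reference_improvements(self, base, mapped, expected):
        assert relative_improvement(base, mapped) == expected

    def test_no_change_is_zero(self):
        assert relative_improvement(10, 10) == 0.0

    def test_zero_base_rejected(self):
        with pytest.raises(EvalError):
            relative_improvement(0, 5)


class TestBinaryRelevance:
    def test_separable_recovery(self):
        X = np.repeat(np.eye(3), 10, axis=0)
        Y = X.astype(int)
        pred = fit_predict_binary_relevance(X, Y, X[:6], ModelSpec("logistic_regression", seed=0))
        assert np.array_equal(pred, Y[:6])

    def test_all_negative_label_never_predicted(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 4))
        Y = np.zeros((20, 2), dtype=int)
        Y[:10, 0] = 1
        pred = fit_predict_binary_relevance(X, Y, X, ModelSpec("random_forest", seed=0))
        assert pred[:, 1].sum() == 0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 5))
        Y = (rng.random((30, 3)) < 0.4).astype(int)
        spec = ModelSpec("gradient_tree_boosting", seed=5)
        a = fit_predict_binary_relevance(X, Y, X, spec)
        b = fit_predict_binary_relevance(X, Y, X, spec)
        assert np.array_equal(a, b)

    def test_unknown_kind_rejected(self):
        with pytest.raises(EvalError, match="unknown model kind"):
            ModelSpec("svm")


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(2)
    X = np.repeat(np.eye(4), 10, axis=0)
    Y = X.astype(int)
    idx = rng.permutation(len(X))
    return X[idx], Y[idx]


class TestCrossValidate:
    def test_same_seed_identical(self, separable):
        X, Y = separable
        cv = CVConfig(folds=5, repetitions=2, seed=3)
        spec = ModelSpec("logistic_regression", seed=3)
        a = cross_validate(X, Y, spec, cv)
        b = cross_validate(X, Y, spec, cv)
        strip = lambda reps: [{k: v for k, v in r.items() if k != "runtime_seconds"} for r in reps]
        assert strip(a.per_repetition) == strip(b.per_repetition)

    def test_each_patient_tested_once_and_correct(self, separable):
        X, Y = separable
        result = cross_validate(X, Y, ModelSpec("logistic_regression", seed=0), CVConfig(5, 1, 0))
        # separable construction → every patient recovered in each repetition
        assert result.correct_count == len(X)
        assert result.incorrect_count == 0

    def test_counts_partition(self, separable):
        X, Y = separable
        result = cross_validate(X, Y, ModelSpec("random_forest", seed=0), CVConfig(5, 1, 0))
        total = result.correct_count + result.partially_correct_count + result.incorrect_count
        assert total == len(X)

    def test_too_few_rows(self):
        with pytest.raises(EvalError, match="at least"):
            cross_validate(np.zeros((3, 2)), np.ones((3, 1), dtype=int),
                           ModelSpec("logistic_regression"), CVConfig(5, 1, 0))


class TestFeatureImportance:
    def _cohort(self, informative_category, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        signal = rng.integers(0, 2, (n, 4))
        noise = rng.integers(0, 2, (n, 12))
        X = np.hstack([signal, noise]).astype(float)
        Y = signal[:, :2].astype(int)  # labels depend only on the signal block
        categories = [informative_category] * 4 + ["imaging"] * 4 + ["anatomy"] * 4 + ["immunohistochemistry"] * 4
        return X, Y, categories

    @pytest.mark.parametrize("kind", ["logistic_regression", "random_forest", "gradient_tree_boosting"])
    def test_informative_category_dominates(self, kind):
        X, Y, categories = self._cohort("microscopy")
        models = fit_binary_relevance(X, Y, ModelSpec(kind, seed=0))
        scores = feature_importance(models, X, categories)
        top = max(scores, key=scores.get)
        assert top == "microscopy"

    def test_null_noise_near_uniform(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (150, 12)).astype(float)
        Y = rng.integers(0, 2, (150, 2))
        Y[:, 0] |= np.arange(150) % 2  # keep labels non-degenerate
        categories = ["microscopy"] * 3 + ["imaging"] * 3 + ["anatomy"] * 3 + ["immunohistochemistry"] * 3
        models = fit_binary_relevance(X, Y, ModelSpec("random_forest", seed=4))
        scores = feature_importance(models, X, categories)
        assert max(scores.values()) < 0.5

    def test_scores_sum_to_one(self):
        X, Y, categories = self._cohort("microscopy")
        models = fit_binary_relevance(X, Y, ModelSpec("gradient_tree_boosting", seed=1))
        scores = feature_importance(models, X, categories)
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unfitted_rejected(self):
        with pytest.raises(EvalError):
            feature_importance([object()], np.zeros((2, 2)), ["a", "b"])


class TestRuntimeBenchmark:
    def test_noop_nonnegative(self):
        result = runtime_benchmark(lambda: None, executions=3)
        assert result.mean_seconds >= 0.0

    def test_seven_runs_recorded(self):
        result = runtime_benchmark(lambda: sum(range(100)), executions=7)
        assert len(result.runs) == 7

    def test_failure_reports_run_index(self):
        calls = {"n": 0}

        def flaky():
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")

        with pytest.raises(EvalError, match="run 1"):
            runtime_benchmark(flaky, executions=3)

    def test_improvement_arithmetic_reuse(self):
        slow = runtime_benchmark(lambda: sum(range(20000)), executions=2).mean_seconds
        fast = runtime_benchmark(lambda: None, executions=2).mean_seconds
        assert relative_improvement(slow * 1e9, fast * 1e9) < 0.0
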