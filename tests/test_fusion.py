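import numpy as np
import pandas as pd
import pytest

from crydx.fusion import (
    ClassifierSpec,
    CVPlan,
    PNNClassifier,
    build_score_vectors,
    evaluate_fusion,
    random_oversample,
    stratified_repeated_kfold,
    train_fusion_classifier,
)


def score_table(file_ids, labels, scores):
    return pd.DataFrame({"file_id": file_ids, "label": labels, "score": scores})


class TestBuildScoreVectors:
    def test_join_sizes_mimic_test_dataset(self, rng):
        # 86 healthy + 93 sick files carrying both cry types
        ids = [f"f{i}" for i in range(179)]
        labels = [1] * 86 + [0] * 93
        exp = score_table(ids, labels, rng.standard_normal(179))
        insv = score_table(ids, labels, rng.standard_normal(179))
        v = build_score_vectors(exp, insv)
        assert len(v) == 179
        assert set(v.columns) >= {"file_id", "label", "exp_score", "insv_score"}

    def test_disjoint_ids_drop_everything(self, rng):
        exp = score_table(["a", "b"], [1, 0], [0.1, 0.2])
        insv = score_table(["c", "d"], [1, 0], [0.3, 0.4])
        v = build_score_vectors(exp, insv)
        assert len(v) == 0
        assert v.attrs["n_dropped"] == 4

    def test_one_to_one_preserves_size(self, rng):
        exp = score_table(["a", "b"], [1, 0], [0.1, 0.2])
        insv = score_table(["a", "b"], [1, 0], [0.3, 0.4])
        assert len(build_score_vectors(exp, insv)) == 2

    def test_duplicate_ids_rejected(self, rng):
        exp = score_table(["a", "a"], [1, 1], [0.1, 0.2])
        insv = score_table(["a", "b"], [1, 0], [0.3, 0.4])
        with pytest.raises(ValueError, match="duplicate"):
            build_score_vectors(exp, insv)


class TestRandomOversample:
    def test_minority_duplicated_to_balance(self, rng):
        X = rng.standard_normal((93, 2))
        y = np.array([1] * 29 + [0] * 64)
        Xo, yo = random_oversample(X, y, seed=0)
        assert np.sum(yo == 1) == 64 and np.sum(yo == 0) == 64

    def test_balanced_input_untouched(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        Xo, yo = random_oversample(X, y, seed=0)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.standard_normal((50, 2))
        y = np.array([1] * 10 + [0] * 40)
        a = random_oversample(X, y, seed=7)
        b = random_oversample(X, y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_only_existing_rows_duplicated(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array([1] * 5 + [0] * 25)
        Xo, yo = random_oversample(X, y, seed=1)
        minority_rows = {tuple(r) for r in X[y == 1]}
        new_rows = {tuple(r) for r in Xo[30:]}
        assert new_rows <= minority_rows

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            random_oversample(rng.standard_normal((5, 2)), np.ones(5), seed=0)


class TestStratifiedRepeatedKfold:
    def test_divisible_case_exact_fold_composition(self):
        y = np.array([1] * 50 + [0] * 50)
        for _, train, test in stratified_repeated_kfold(y, CVPlan(n_folds=10, rounds=1, seed=0)):
            assert np.sum(y[test] == 1) == 5 and np.sum(y[test] == 0) == 5

    def test_uneven_case_within_one_sample(self):
        y = np.array([1] * 86 + [0] * 93)
        for _, _, test in stratified_repeated_kfold(y, CVPlan(n_folds=10, rounds=1, seed=0)):
            assert abs(np.sum(y[test] == 1) - 8.6) <= 1
            assert abs(np.sum(y[test] == 0) - 9.3) <= 1

    def test_test_folds_partition_indices(self):
        y = np.array([1] * 30 + [0] * 40)
        plan = CVPlan(n_folds=5, rounds=2, seed=1)
        per_round: dict[int, list] = {}
        for rnd, _, test in stratified_repeated_kfold(y, plan):
            per_round.setdefault(rnd, []).append(test)
        assert set(per_round) == {0, 1}
        for folds in per_round.values():
            allidx = np.concatenate(folds)
            assert len(allidx) == 70 and len(set(allidx)) == 70

    def test_class_smaller_than_k_rejected(self):
        y = np.array([1] * 2 + [0] * 50)
        with pytest.raises(ValueError):
            next(iter(stratified_repeated_kfold(y, CVPlan(n_folds=5, rounds=1, seed=0))))


def separable_blobs(n=40, gap=6.0, seed=0):
    r = np.random.default_rng(seed)
    X = np.vstack([r.standard_normal((n, 2)) - gap / 2, r.standard_normal((n, 2)) + gap / 2])
    y = np.array([0] * n + [1] * n)
    return X, y


class TestClassifierBank:
    def test_linear_svm_separates_blobs_exactly(self):
        X, y = separable_blobs()
        model = train_fusion_classifier(ClassifierSpec(kind="svm-linear"), X, y, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_pnn_small_spread_memorizes_training_labels(self):
        X, y = separable_blobs(n=20, gap=1.0, seed=1)  # overlapping classes
        model = train_fusion_classifier(ClassifierSpec(kind="pnn"), X, y, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    @pytest.mark.parametrize("kind", ["mlp", "svm-quad", "svm-poly3", "svm-rbf", "svm-mlp"])
    def test_all_kinds_fit_and_predict(self, kind):
        X, y = separable_blobs()
        model = train_fusion_classifier(ClassifierSpec(kind=kind), X, y, seed=0)
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_single_class_fold_rejected(self, rng):
        with pytest.raises(ValueError):
            train_fusion_classifier(ClassifierSpec(kind="mlp"), rng.standard_normal((5, 2)), np.ones(5))

    def test_permuted_labels_give_chance_level_cv(self):
        r = np.random.default_rng(9)
        X = r.standard_normal((120, 2))
        y = r.integers(0, 2, 120)  # labels independent of scores
        vectors = pd.DataFrame({"exp_score": X[:, 0], "insv_score": X[:, 1], "label": y})
        out = evaluate_fusion(
            vectors, [ClassifierSpec(kind="svm-linear")], CVPlan(n_folds=5, rounds=20, seed=0)
        )
        assert abs(out["svm-linear"].accuracy - 0.5) < 0.1


class TestEvaluateFusion:
    def _vectors(self, n=60, gap=8.0, seed=0):
        X, y = separable_blobs(n=n // 2, gap=gap, seed=seed)
        return pd.DataFrame({"exp_score": X[:, 0], "insv_score": X[:, 1], "label": y})

    def test_perfect_separation_zero_errors(self):
        out = evaluate_fusion(
            self._vectors(),
            [ClassifierSpec(kind="svm-linear"), ClassifierSpec(kind="pnn")],
            CVPlan(n_folds=5, rounds=2, seed=0),
        )
        for s in out.values():
            assert s.fpr == 0.0 and s.fnr == 0.0 and s.accuracy == 1.0

    def test_repeat_call_bit_identical(self):
        v = self._vectors(gap=2.0)
        plan = CVPlan(n_folds=5, rounds=3, seed=4)
        a = evaluate_fusion(v, [ClassifierSpec(kind="svm-rbf")], plan)["svm-rbf"]
        b = evaluate_fusion(v, [ClassifierSpec(kind="svm-rbf")], plan)["svm-rbf"]
        assert a == b

    def test_row_order_insensitive_statistically(self):
        v = self._vectors(n=100, gap=3.0, seed=2)
        plan = CVPlan(n_folds=5, rounds=20, seed=4)
        a = evaluate_fusion(v, [ClassifierSpec(kind="svm-linear")], plan)["svm-linear"]
        shuffled = v.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = evaluate_fusion(shuffled, [ClassifierSpec(kind="svm-linear")], plan)["svm-linear"]
        assert abs(a.accuracy - b.accuracy) < 0.05

    def test_ci_contains_point_estimate(self):
        v = self._vectors(gap=2.0)
        s = evaluate_fusion(v, [ClassifierSpec(kind="mlp")], CVPlan(n_folds=5, rounds=2, seed=0))["mlp"]
        assert s.ci[0] <= s.p_cv <= s.ci[1]
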