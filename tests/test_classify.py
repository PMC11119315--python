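"""Binary task construction, learners, and stratified cross-validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from nirsfuse.classify import (
    CVReport,
    LearnerSpec,
    build_learner,
    cross_validate,
    evaluate_tasks,
    make_binary_task,
    predict_knn,
    predict_lda,
    reports_frame,
    train_boosted,
    train_knn,
    train_lda,
)


class TestBinaryTask:
    def test_md_positive_mapping(self):
        np.testing.assert_array_equal(make_binary_task([1, 2, 3, 2], 2), [0, 1, 0, 1])

    def test_sn_positive_mapping(self):
        np.testing.assert_array_equal(make_binary_task([1, 2, 3, 2], 3), [0, 0, 1, 0])

    def test_absent_positive_class_rejected(self):
        with pytest.raises(ValueError, match="no examples"):
            make_binary_task([1, 1, 1], 2)

    def test_invalid_positive_code_rejected(self):
        with pytest.raises(ValueError, match="positive_class"):
            make_binary_task([1, 2, 3], 1)


class TestKNN:
    def test_nearest_point_hand_check(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1])
        model = train_knn(X, y, LearnerSpec(kind="knn", knn_k=1))
        assert predict_knn(model, [[0.1, 0.0]])[0] == 0

    def test_query_on_training_point(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        y = np.array([0, 1, 0])
        model = train_knn(X, y, LearnerSpec(kind="knn", knn_k=1))
        assert predict_knn(model, [[5.0, 5.0]])[0] == 1

    def test_k_equals_n_gives_global_majority(self, rng):
        X = rng.normal(size=(9, 2))
        y = np.array([0] * 6 + [1] * 3)
        model = train_knn(X, y, LearnerSpec(kind="knn", knn_k=9))
        queries = rng.normal(size=(5, 2)) * 10
        assert (predict_knn(model, queries) == 0).all()

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError, match="exceeds training size"):
            train_knn(np.zeros((3, 2)), np.array([0, 1, 0]), LearnerSpec(kind="knn", knn_k=5))


class TestLDA:
    def test_midpoint_decision_boundary(self):
        # two 1-D classes at means -1 and +1, equal variance and priors:
        # the boundary is at 0, so 0.1 goes to the positive class
        rng = np.random.default_rng(0)
        x0 = rng.normal(-1.0, 0.5, size=200)[:, None]
        x1 = rng.normal(+1.0, 0.5, size=200)[:, None]
        X = np.vstack([x0, x1])
        y = np.array([0] * 200 + [1] * 200)
        model = train_lda(X, y)
        assert predict_lda(model, [[0.1]])[0] == 1
        assert predict_lda(model, [[-0.1]])[0] == 0

    def test_duplicated_feature_column_no_crash(self, rng):
        x = rng.normal(size=(40, 1))
        X = np.hstack([x, x])  # singular pooled covariance
        y = (x[:, 0] > 0).astype(int)
        model = train_lda(X, y)
        assert predict_lda(model, X).shape == (40,)

    def test_separated_blobs_high_training_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(8, 1, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        model = train_lda(X, y)
        assert np.mean(predict_lda(model, X) == y) >= 0.99

    def test_single_row_class_rejected(self):
        with pytest.raises(ValueError, match="2 rows per class"):
            train_lda(np.zeros((3, 2)), np.array([0, 0, 1]))


class TestBoosted:
    @pytest.mark.parametrize("backend", ["gbm_light", "gbm_xtreme"])
    def test_separable_blobs_cv_accuracy(self, backend, rng):
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(6, 1, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        rep = cross_validate(X, y, LearnerSpec(kind=backend), k_folds=5, seed=0)
        assert rep.mean_accuracy >= 0.95

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(size=(120, 4))
        y = np.array([0, 1] * 60)
        rng.shuffle(y)
        rep = cross_validate(X, y, LearnerSpec(kind="gbm_light"), k_folds=5, seed=1)
        # binomial 95% interval around 0.5 for n = 120
        half_width = 1.96 * np.sqrt(0.25 / 120)
        assert abs(rep.mean_accuracy - 0.5) <= 2 * half_width

    def test_monotone_single_feature_matches_threshold_oracle(self, rng):
        # labels from a single threshold with a margin: the booster must do
        # at least as well as the best single split found by exhaustive search
        # margin wide relative to histogram bin width, so binning cannot
        # merge points across the class boundary
        x = rng.normal(size=2000)
        x = x[np.abs(x - 0.3) > 1.0][:200]
        y = (x > 0.3).astype(int)
        model = train_boosted(x[:, None], y, backend="gbm_light")
        acc = np.mean(model.predict(x[:, None]) == y)
        best = 0.0
        for t in np.sort(x):
            for sign in (1, -1):
                pred = (sign * (x - t) > 0).astype(int)
                best = max(best, np.mean(pred == y))
        assert acc >= best - 1e-12


class TestCrossValidate:
    def test_constant_features_give_majority_rate(self):
        X = np.ones((30, 3))
        y = np.array([0] * 20 + [1] * 10)
        rep = cross_validate(X, y, LearnerSpec(kind="knn", knn_k=5), k_folds=5, seed=0)
        assert rep.mean_accuracy == pytest.approx(20 / 30, abs=0.02)

    def test_perfectly_separable_knn1_is_exact(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        rep = cross_validate(X, y, LearnerSpec(kind="knn", knn_k=1), k_folds=5, seed=0)
        assert rep.mean_accuracy == 1.0

    def test_same_seed_identical_report(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        r1 = cross_validate(X, y, LearnerSpec(kind="lda"), k_folds=4, seed=3)
        r2 = cross_validate(X, y, LearnerSpec(kind="lda"), k_folds=4, seed=3)
        assert r1.fold_accuracies == r2.fold_accuracies
        for a, b in zip(r1.confusions, r2.confusions):
            np.testing.assert_array_equal(a, b)

    def test_fold_partition_disjoint_exhaustive_stratified(self, rng):
        y = np.array([0] * 18 + [1] * 12)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        X = rng.normal(size=(30, 2))
        seen = []
        for _, test_idx in skf.split(X, y):
            seen.extend(test_idx)
            counts = np.bincount(y[test_idx], minlength=2)
            # per-fold class ratio within 1 of proportional
            assert abs(counts[0] - 18 / 5) <= 1
            assert abs(counts[1] - 12 / 5) <= 1
        assert sorted(seen) == list(range(30))

    def test_confusions_sum_to_fold_sizes(self, rng):
        X = rng.normal(size=(25, 2))
        y = np.array([0] * 15 + [1] * 10)
        rep = cross_validate(X, y, LearnerSpec(kind="knn", knn_k=3), k_folds=5, seed=0)
        assert [int(c.sum()) for c in rep.confusions] == [5] * 5

    def test_class_smaller_than_folds_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ValueError, match="fewer than k_folds"):
            cross_validate(X, y, LearnerSpec(kind="knn", knn_k=2), k_folds=5, seed=0)


class TestEvaluateTasks:
    def test_runs_both_tasks_and_tags_reports(self, rng):
        n = 45
        labels = np.repeat([1, 2, 3], n // 3)
        X = rng.normal(size=(n, 4)) + labels[:, None]
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(4)])
        df["label"] = labels
        df.attrs["stream"] = "HbO"
        df.attrs["feature_set"] = "classical"
        reports = evaluate_tasks(df, [LearnerSpec(kind="knn"), LearnerSpec(kind="lda")], k_folds=5)
        assert {r.task for r in reports} == {"MD", "SN"}
        assert len(reports) == 4
        frame = reports_frame(reports)
        assert set(frame.columns) == {"task", "stream", "feature_set", "learner", "fold", "accuracy"}
        assert len(frame) == 4 * 5
        assert (frame["accuracy"] <= 1).all() and (frame["accuracy"] >= 0).all()

    def test_unknown_learner_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            LearnerSpec(kind="svm")
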