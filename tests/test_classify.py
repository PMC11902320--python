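"""SVM classifier: features, kernel, dual solver, splitting, CV, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placidoscan import classify as C
from placidoscan import phantom


def _blob_data(rng, n_per_class=20, d=4, sep=4.0):
    X = np.vstack([
        rng.normal(0.0, 1.0, (n_per_class, d)),
        rng.normal(sep, 1.0, (n_per_class, d)),
    ])
    y = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)])
    return X, y


class TestBuildFeatures:
    def test_eye_vector_length_is_twice_ring_count(self, healthy_maps):
        rmap, _, r_mm, d_map = healthy_maps
        _, vec = C.build_features(rmap, d_map, "eye000", "healthy")
        assert vec.shape == (18,)

    def test_healthy_vector_near_43_with_tiny_spread(self, healthy_maps):
        rmap, _, _, d_map = healthy_maps
        _, vec = C.build_features(rmap, d_map, "eye000", "healthy")
        assert np.all(np.abs(vec[:9] - 43.0) < 0.5)
        assert np.all(vec[9:] < 0.5)

    def test_cone_vector_shows_steepening_and_spread(self, healthy_maps, cone_maps):
        rmap_h, _, _, d_h = healthy_maps
        rmap_c, _, _, d_c = cone_maps
        _, vec_h = C.build_features(rmap_h, d_h, "h", "healthy")
        _, vec_c = C.build_features(rmap_c, d_c, "c", "diseased")
        assert vec_c[:9].max() > 43.0 + 1.0
        assert vec_c[9:].max() > vec_h[9:].max() + 1.0

    def test_record_schema(self, healthy_maps):
        rmap, _, r_mm, d_map = healthy_maps
        records, _ = C.build_features(rmap, d_map, "eye000", "healthy", r_mm_map=r_mm)
        assert len(records) == 9 * 24
        assert set(["eye_id", "ring", "sector_deg", "diopter", "label"]) <= set(records.columns)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            C.build_features(np.full((2, 4), np.nan), np.full((2, 4), np.nan), "e", "healthy")


class TestGaussianKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=6)
        assert C.gaussian_kernel(x, x, 2.0) == 1.0

    def test_distance_sigma_gives_inverse_e(self):
        x = np.zeros(3)
        z = np.array([2.0, 0.0, 0.0])
        assert C.gaussian_kernel(x, z, 2.0) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_gram_matrix_positive_semidefinite(self, rng):
        X = rng.normal(size=(10, 5))
        gram = np.array([[C.gaussian_kernel(a, b, 1.5) for b in X] for a in X])
        assert np.allclose(gram, gram.T)
        assert np.linalg.eigvalsh(gram).min() >= -1e-8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            C.gaussian_kernel(np.zeros(3), np.zeros(4), 1.0)


class TestTrainSvm:
    def test_separable_toy_set_is_fit_exactly(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        model = C.train_svm(X, y, C.SvmParams(C=10.0, sigma=2.0))
        pred, _ = C.predict(model, X)
        assert np.array_equal(pred, y)
        assert np.all(model.alpha > 0)

    def test_dual_feasibility(self, rng):
        X, y = _blob_data(rng)
        params = C.SvmParams(C=1.0)
        model = C.train_svm(X, y, params)
        assert np.all(model.alpha >= 0)
        assert np.all(model.alpha <= params.C + 1e-9)
        assert abs(np.sum(model.alpha * model.y)) <= 1e-6

    def test_agrees_with_reference_dual_solver(self, rng):
        from sklearn.svm import SVC

        X, y = _blob_data(rng, n_per_class=20, d=3, sep=2.0)
        sigma = 2.0
        model = C.train_svm(X, y, C.SvmParams(C=1.0, sigma=sigma))
        Xs = (X - model.feature_mean) / model.feature_sd
        ref = SVC(C=1.0, gamma=1.0 / sigma**2).fit(Xs, y)

        grid = rng.normal(0.0, 2.0, size=(200, 3)) + np.array([1.0, 1.0, 1.0])
        ours, _ = C.predict(model, grid * model.feature_sd + model.feature_mean)
        theirs = ref.predict(grid)
        assert np.mean(ours == theirs) >= 0.95

    def test_duplicated_data_keeps_decision_boundary(self, rng):
        X, y = _blob_data(rng, n_per_class=10, d=2, sep=5.0)
        grid = rng.uniform(-2, 7, size=(100, 2))
        m1 = C.train_svm(X, y, C.SvmParams(C=10.0, sigma=3.0))
        m2 = C.train_svm(np.vstack([X, X]), np.concatenate([y, y]),
                         C.SvmParams(C=10.0, sigma=3.0))
        p1, _ = C.predict(m1, grid)
        p2, _ = C.predict(m2, grid)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            C.train_svm(X, np.ones(10))


class TestPredict:
    def test_kkt_on_free_support_vectors(self, rng):
        X, y = _blob_data(rng, n_per_class=15, d=3, sep=2.0)
        params = C.SvmParams(C=1.0, sigma=2.5)
        model = C.train_svm(X, y, params)
        free = (model.alpha > 1e-6) & (model.alpha < params.C - 1e-6)
        if free.any():
            sv_orig = model.support_vectors * model.feature_sd + model.feature_mean
            _, f = C.predict(model, sv_orig[free])
            assert np.max(np.abs(f - model.y[free])) <= 1e-3

    def test_cluster_sanity(self, rng):
        # healthy eyes near 43 D, keratoconic near 50 D
        X = np.vstack([rng.normal(43.0, 0.5, (20, 9)), rng.normal(50.0, 0.5, (20, 9))])
        y = np.concatenate([np.ones(20), -np.ones(20)])
        model = C.train_svm(X, y)
        pred, _ = C.predict(model, rng.normal(43.0, 0.5, (5, 9)))
        assert np.all(pred == 1)

    def test_tie_goes_to_healthy(self):
        # two symmetric support vectors cancel exactly at the midpoint
        model = C.SvmModel(
            support_vectors=np.array([[-1.0], [1.0]]),
            alpha=np.array([1.0, 1.0]),
            y=np.array([1.0, -1.0]),
            b=0.0,
            params=C.SvmParams(sigma=1.0),
            sigma=1.0,
            feature_mean=np.zeros(1),
            feature_sd=np.ones(1),
            n_train=2,
        )
        labels, f = C.predict(model, np.array([[0.0]]))
        assert f[0] == 0.0 and labels[0] == 1

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _blob_data(rng, n_per_class=5, d=3)
        model = C.train_svm(X, y)
        with pytest.raises(ValueError):
            C.predict(model, np.zeros((1, 4)))


class TestSplit:
    def test_hundred_eyes_split_60_40(self):
        ids = np.array([f"e{i}" for i in range(100)])
        labels = np.array(["healthy"] * 50 + ["diseased"] * 50)
        train, test, folds = C.split_data(ids, labels, C.SplitSpec(seed=3))
        assert len(train) == 60 and len(test) == 40
        assert len(set(train) & set(test)) == 0

    def test_folds_partition_training_portion(self):
        ids = np.array([f"e{i}" for i in range(100)])
        labels = np.array(["healthy", "diseased"] * 50)
        train, test, folds = C.split_data(ids, labels, C.SplitSpec(seed=1))
        assert len(folds) == 10
        pooled = np.concatenate(folds)
        assert sorted(pooled) == sorted(train)
        assert len(set(pooled)) == len(pooled)
        # no test eye ever appears in a CV fold
        assert not set(pooled) & set(test)

    def test_deterministic_given_seed(self):
        ids = np.array([f"e{i}" for i in range(40)])
        labels = np.array(["healthy", "diseased"] * 20)
        a = C.split_data(ids, labels, C.SplitSpec(seed=9, n_folds=5))
        b = C.split_data(ids, labels, C.SplitSpec(seed=9, n_folds=5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_few_eyes_rejected(self):
        ids = np.array([f"e{i}" for i in range(10)])
        labels = np.array(["healthy", "diseased"] * 5)
        with pytest.raises(ValueError, match="too few"):
            C.split_data(ids, labels, C.SplitSpec(n_folds=10))


class TestCrossValidate:
    def _table(self, rng, sep):
        X, y = _blob_data(rng, n_per_class=15, d=4, sep=sep)
        ids = np.array([f"e{i}" for i in range(30)])
        labels = np.where(y > 0, "healthy", "diseased")
        _, _, folds = C.split_data(ids, labels, C.SplitSpec(train_frac=0.99, n_folds=10, seed=0))
        return X, y, ids, folds

    def test_ten_validation_scores_reported(self, rng):
        X, y, ids, folds = self._table(rng, sep=6.0)
        cv = C.cross_validate(X, y, ids, folds)
        assert len(cv.fold_scores) == 10

    def test_separable_data_validates_perfectly(self, rng):
        X, y, ids, folds = self._table(rng, sep=8.0)
        cv = C.cross_validate(X, y, ids, folds)
        assert max(cv.mean_scores.values()) == 100.0
        assert np.mean(cv.fold_scores) == 100.0

    def test_shuffled_labels_validate_at_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = np.array([1.0, -1.0] * 30)
        ids = np.array([f"e{i}" for i in range(60)])
        labels = np.where(y > 0, "healthy", "diseased")
        _, _, folds = C.split_data(ids, labels, C.SplitSpec(train_frac=0.99, n_folds=10, seed=0))
        cv = C.cross_validate(X, y, ids, folds)
        # average over the grid: picking the max would add selection bias
        assert abs(np.mean(list(cv.mean_scores.values())) - 50.0) <= 15.0


class TestMetrics:
    def test_reported_headline_confusion_matrix(self):
        # TP=49 FN=2 TN=48 FP=1: sens 49/51, spec 48/49, acc 97/100
        report = C.EvalReport(tp=49, tn=48, fp=1, fn=2)
        assert report.sensitivity == pytest.approx(96.08, abs=0.005)
        assert report.specificity == pytest.approx(97.96, abs=0.005)
        assert report.accuracy == pytest.approx(97.0, abs=1e-9)

    def test_all_correct_gives_100(self):
        pred = np.array([1, 1, -1, -1])
        report = C.evaluate_metrics(pred, pred)
        for v in (report.sensitivity, report.specificity, report.accuracy, report.npv, report.ppv):
            assert v == 100.0

    def test_symmetric_case_gives_50(self):
        report = C.EvalReport(tp=25, tn=25, fp=25, fn=25)
        for v in (report.sensitivity, report.specificity, report.accuracy, report.npv, report.ppv):
            assert v == 50.0

    def test_diseased_is_positive_class(self):
        # one healthy eye (+1) called diseased (-1): a false positive
        report = C.evaluate_metrics(np.array([-1]), np.array([1]))
        assert report.fp == 1 and report.tp == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            C.evaluate_metrics(np.array([]), np.array([]))

    @given(
        tp=st.integers(0, 500), tn=st.integers(0, 500),
        fp=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_metric_identities(self, tp, tn, fp, fn):
        total = tp + tn + fp + fn
        if total == 0:
            return
        r = C.EvalReport(tp=tp, tn=tn, fp=fp, fn=fn)
        assert r.accuracy * total == pytest.approx(100.0 * (tp + tn))
        if tp + fn:
            assert r.sensitivity == pytest.approx(100.0 * tp / (tp + fn))
        if tn + fp:
            assert r.specificity == pytest.approx(100.0 * tn / (tn + fp))
        if tn + fn:
            assert r.npv == pytest.approx(100.0 * tn / (tn + fn))
        if tp + fp:
            assert r.ppv == pytest.approx(100.0 * tp / (tp + fp))


class TestModelSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        X, y = _blob_data(rng, n_per_class=8, d=3)
        model = C.train_svm(X, y, C.SvmParams(C=2.0))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = C.SvmModel.from_json(path)
        grid = rng.normal(size=(20, 3))
        _, f1 = C.predict(model, grid)
        _, f2 = C.predict(loaded, grid)
        assert np.allclose(f1, f2)


def test_feature_table_fixture_is_linearly_separable(rng):
    table = phantom.generate_feature_table(
        20,
        {"healthy": {"mean_d": 43.0, "sd_d": 0.5, "frac": 0.5},
         "diseased": {"mean_d": 50.0, "sd_d": 0.5, "frac": 0.5}},
        seed=4,
    )
    eye = table.groupby(["eye_id", "label"])["diopter"].mean().reset_index()
    X = eye[["diopter"]].to_numpy()
    y = np.where(eye["label"] == "healthy", 1.0, -1.0)
    model = C.train_svm(X, y, C.SvmParams(kernel="linear", C=10.0))
    pred, _ = C.predict(model, X)
    assert np.array_equal(pred, y)
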