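import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from pulsewave import stress_model as sm
from pulsewave import synthetic as syn


@pytest.fixture(scope="module")
def labeled_default():
    return syn.generate_labeled_dataset(n_subjects=10,
                                        windows_per_subject_per_class=12,
                                        seed=1)


@pytest.fixture(scope="module")
def fitted_default(labeled_default):
    return sm.train_pipeline(labeled_default, seed=1)


def blobs(n=60, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n, 6))
    X1 = rng.normal(sep, 1.0, size=(n, 6))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    subj = np.arange(2 * n) % 8
    return sm.LabeledDataset(X, y, subj)


class TestSMOTE:
    def test_balanced_input_unchanged(self):
        d = blobs(40)
        out = sm.oversample_minority(d, seed=0)
        assert np.bincount(out.labels).tolist() == [40, 40]

    def test_counts_equalized(self):
        d = blobs(50)
        sub = d.subset(np.arange(len(d)) < 80)  # 50 majority / 30 minority
        out = sm.oversample_minority(sub, seed=0)
        assert np.bincount(out.labels).tolist() == [50, 50]
        # original rows preserved verbatim
        assert np.allclose(out.features[:80], sub.features)

    def test_synthetic_rows_in_minority_box(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(size=(70, 6)), rng.normal(5, 1, size=(30, 6))])
        y = np.array([0] * 70 + [1] * 30)
        Xo, yo = sm.smote(X, y, seed=3)
        new = Xo[100:]
        lo, hi = X[y == 1].min(0), X[y == 1].max(0)
        assert np.all(new >= lo - 1e-9) and np.all(new <= hi + 1e-9)

    def test_deterministic(self):
        d = blobs(50)
        sub = d.subset(np.arange(len(d)) < 80)
        a = sm.oversample_minority(sub, seed=7)
        b = sm.oversample_minority(sub, seed=7)
        assert np.array_equal(a.features, b.features)

    def test_tiny_minority_rejected_with_minimum_named(self):
        X = np.random.default_rng(0).normal(size=(14, 6))
        y = np.array([0] * 10 + [1] * 4)
        with pytest.raises(ValueError, match="at least 6"):
            sm.smote(X, y, seed=0)


class TestDummyBaseline:
    def test_perfect_when_test_matches_majority(self):
        assert sm.dummy_baseline([0, 0, 1], [0, 0, 0]) == 1.0

    def test_count_ratio(self):
        y_test = np.array([0] * 64 + [1] * 36)
        assert sm.dummy_baseline([0, 0, 0, 1], y_test) == pytest.approx(0.64)

    def test_tie_resolves_to_zero(self):
        assert sm.dummy_baseline([0, 1], [0]) == 1.0
        assert sm.dummy_baseline([0, 1], [1]) == 0.0


class TestPipeline:
    def test_separable_blobs_fit_perfectly(self):
        d = blobs()
        pipe = sm.build_pipeline(sm.PipelineSpec())
        pipe.fit(d.features, d.labels)
        assert np.mean(pipe.predict(d.features) == d.labels) == 1.0

    def test_full_pca_equals_no_pca_for_svm(self, labeled_default):
        d = labeled_default
        no_pca = sm.build_pipeline(sm.PipelineSpec(), seed=0)
        full_pca = sm.build_pipeline(
            sm.PipelineSpec(use_pca=True, n_components=6), seed=0
        )
        no_pca.fit(d.features, d.labels)
        full_pca.fit(d.features, d.labels)
        assert np.array_equal(no_pca.predict(d.features),
                              full_pca.predict(d.features))

    def test_scaler_fitted_on_train_only(self, labeled_default):
        d = labeled_default
        half = len(d) // 2
        train, test = d.features[:half], d.features[half:]
        pipe = sm.build_pipeline(sm.PipelineSpec())
        pipe.fit(train, d.labels[:half])
        scaler: StandardScaler = pipe.named_steps["scaler"]
        assert np.allclose(scaler.mean_, train.mean(0))
        assert not np.allclose(scaler.mean_, test.mean(0))

    def test_unknown_component_listed(self):
        with pytest.raises(ValueError, match="valid"):
            sm.PipelineSpec(classifier="boosted_ferns")


class TestCrossValidation:
    def test_fold_proportions_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 6))
        y = np.array([0] * 64 + [1] * 36)
        d = sm.LabeledDataset(X, y, np.arange(100) % 10)
        from sklearn.model_selection import StratifiedShuffleSplit

        splitter = StratifiedShuffleSplit(n_splits=5, test_size=0.25,
                                          random_state=0)
        for _, te in splitter.split(X, y):
            assert abs(int(np.sum(y[te] == 0)) - 16) <= 1

    def test_same_seed_same_scores(self, labeled_default):
        a = sm.cross_validate(labeled_default, sm.PipelineSpec(), seed=5)
        b = sm.cross_validate(labeled_default, sm.PipelineSpec(), seed=5)
        assert a.equals(b)

    def test_shuffled_labels_near_chance(self, labeled_default):
        rng = np.random.default_rng(9)
        accs = []
        for rep in range(5):
            y = rng.permutation(labeled_default.labels)
            d = sm.LabeledDataset(labeled_default.features, y,
                                  labeled_default.subject_ids)
            cv = sm.cross_validate(d, sm.PipelineSpec(), n_splits=3, seed=rep)
            accs.append(cv["accuracy"].mean())
        assert 0.4 <= np.mean(accs) <= 0.75


class TestGridSearch:
    def test_single_point_grid(self, labeled_default):
        best, table = sm.grid_search(
            labeled_default, {"classifier_params.C": [1.0]}, n_splits=2, seed=0
        )
        assert best.params_dict()["C"] == 1.0
        assert len(table) == 1

    def test_table_size_is_grid_product(self, labeled_default):
        _, table = sm.grid_search(
            labeled_default,
            {"classifier_params.C": [0.1, 1.0], "scaler": ["standard", "minmax"]},
            n_splits=2,
            seed=0,
        )
        assert len(table) == 4

    def test_strictly_better_combination_selected(self):
        # informative dimension on a tiny scale, noise dimensions huge:
        # without scaling a regularized linear SVM cannot use it
        rng = np.random.default_rng(4)
        n = 80
        X = np.zeros((2 * n, 6))
        X[:, 0] = np.r_[rng.normal(-0.01, 0.004, n), rng.normal(0.01, 0.004, n)]
        X[:, 1:] = rng.normal(0, 100.0, size=(2 * n, 5))
        d = sm.LabeledDataset(X, np.r_[np.zeros(n, int), np.ones(n, int)],
                              np.arange(2 * n) % 8)
        best, table = sm.grid_search(
            d, {"scaler": ["none", "standard"]}, n_splits=3, seed=0
        )
        accs = table.set_index("param:scaler")["mean_accuracy"]
        assert accs["standard"] > accs["none"]
        assert best.scaler == "standard"


class TestEvaluate:
    def test_perfect_predictions(self):
        d = blobs()
        train = d.subset(d.subject_ids < 6)
        test = d.subset(d.subject_ids >= 6)
        model = sm.train_pipeline(train, seed=0)
        rep = sm.evaluate(model, test)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0
        assert rep.fp == 0 and rep.fn == 0

    def test_metric_formulas_by_hand(self):
        rep = sm.EvalReport(accuracy=11 / 14, f1=0.8, tn=5, fp=2, fn=1, tp=6)
        precision, recall = 6 / 8, 6 / 7
        assert rep.accuracy == pytest.approx((5 + 6) / 14)
        assert rep.f1 == pytest.approx(
            2 * precision * recall / (precision + recall)
        )

    def test_subject_overlap_rejected(self):
        d = blobs()
        model = sm.train_pipeline(d, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            sm.evaluate(model, d)


class TestFlattenedSVM:
    def test_export_shapes_and_values(self, fitted_default):
        params = sm.export_linear_svm(fitted_default)
        assert params.d == 6
        scaler = fitted_default.pipeline.named_steps["scaler"]
        clf = fitted_default.pipeline.named_steps["classifier"]
        assert np.allclose(params.u, scaler.mean_)
        assert np.allclose(params.p, 1.0 / scaler.scale_)
        assert np.allclose(params.w, clf.coef_.ravel())
        assert params.c == pytest.approx(-clf.intercept_[0])
        # 3d + 1 numbers total
        assert params.w.size + params.u.size + params.p.size + 1 == 19

    def test_wrong_pipeline_shape_rejected(self, labeled_default):
        model = sm.train_pipeline(
            labeled_default, sm.PipelineSpec(scaler="minmax"), seed=0
        )
        with pytest.raises(ValueError, match="standard scaler"):
            sm.export_linear_svm(model)

    def test_round_trip_agreement(self, fitted_default, labeled_default):
        params = sm.export_linear_svm(fitted_default)
        rng = np.random.default_rng(12)
        lo = labeled_default.features.min(0)
        hi = labeled_default.features.max(0)
        X = rng.uniform(lo, hi, size=(1000, 6))
        for x in X:
            score = params.w @ (params.p * (x - params.u))
            if abs(score - params.c) > 1e-6:
                assert sm.embedded_infer(params, x) == int(
                    fitted_default.predict(x[None])[0]
                )

    def test_single_vs_double_precision(self, fitted_default, labeled_default):
        params = sm.export_linear_svm(fitted_default)
        rng = np.random.default_rng(13)
        lo = labeled_default.features.min(0)
        hi = labeled_default.features.max(0)
        X = rng.uniform(lo, hi, size=(1000, 6))
        for x in X:
            score = params.w @ (params.p * (x - params.u))
            if abs(score - params.c) > 1e-4:
                assert sm.embedded_infer(params, x, "single") == sm.embedded_infer(
                    params, x, "double"
                )

    def test_zero_weights_below_threshold(self):
        params = sm.LinearSVMParams(
            w=np.zeros(6), c=0.5, u=np.zeros(6), p=np.ones(6)
        )
        assert sm.embedded_infer(params, np.ones(6)) == 0

    def test_toy_hand_arithmetic(self):
        params = sm.LinearSVMParams(
            w=np.array([1.0, 1.0]), c=0.0, u=np.zeros(2), p=np.ones(2)
        )
        assert sm.embedded_infer(params, np.array([1.0, -2.0])) == 0
        assert sm.embedded_infer(params, np.array([1.0, 2.0])) == 1

    def test_exact_equality_labels_zero(self):
        params = sm.LinearSVMParams(
            w=np.array([1.0]), c=1.0, u=np.zeros(1), p=np.ones(1)
        )
        assert sm.embedded_infer(params, np.array([1.0])) == 0

    def test_json_round_trip(self, fitted_default, tmp_path):
        params = sm.export_linear_svm(fitted_default)
        path = tmp_path / "model.json"
        sm.save_params(params, path, metadata={"seed": 1})
        loaded = sm.load_params(path)
        rng = np.random.default_rng(14)
        X = rng.normal(800, 200, size=(100, 6))
        for x in X:
            assert sm.embedded_infer(loaded, x) == sm.embedded_infer(params, x)


class TestParameterRecovery:
    def test_holdout_accuracy_on_default_regime(self):
        accs = []
        for seed in range(5):
            data = syn.generate_labeled_dataset(
                n_subjects=15, windows_per_subject_per_class=20, seed=seed
            )
            subjects = np.unique(data.subject_ids)
            held = np.random.default_rng(seed).choice(subjects, 3, replace=False)
            mask = ~np.isin(data.subject_ids, held)
            model = sm.train_pipeline(data.subset(mask), seed=seed)
            accs.append(sm.evaluate(model, data.subset(~mask)).accuracy)
        assert np.mean(accs) >= 0.90
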