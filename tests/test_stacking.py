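"""Stacked-ensemble construction: tuning, meta-features, training, I/O."""

import io

import joblib
import numpy as np
import pytest

import hmmstack as hs
from hmmstack.features import N_FEATURES, FeatureMatrix, feature_names
from hmmstack.stacking import make_estimator

AA = hs.STANDARD_AA


def _tiny_fm(rng, n=24, shift=2.0, n_signal=10):
    """A 420-feature matrix with a mean shift on the first n_signal features."""
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.normal(size=(n, N_FEATURES))
    X[y == 1, :n_signal] += shift
    return FeatureMatrix(ids=[f"s{i}" for i in range(n)], X=X, y=y,
                         names=feature_names(AA))


class TestConfig:
    def test_named_combinations(self):
        assert tuple(s.name for s in hs.StackConfig("SM1").base_specs) == \
            ("KNN", "LR", "DT", "SVM_RBF")
        assert len(hs.StackConfig("SM5").base_specs) == 6

    def test_unknown_combination_rejected(self):
        with pytest.raises(ValueError, match="SM1"):
            hs.StackConfig(combination="SM9")

    def test_empty_base_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            hs.StackConfig(combination="custom", base_specs=[])

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown base learner"):
            hs.BaseLearnerSpec("MLP")


class TestTuning:
    def test_single_point_grid_returned(self, rng):
        fm = _tiny_fm(rng)
        spec = hs.tune_base_learner(
            hs.BaseLearnerSpec("KNN"), fm, {"n_neighbors": [3]}, cv_folds=3
        )
        assert spec.hyperparameters == {"n_neighbors": 3} and spec.tuned

    def test_tie_broken_by_first_in_grid(self, rng):
        # strongly separated data: every k is 100% accurate, first must win
        fm = _tiny_fm(rng, shift=6.0, n_signal=N_FEATURES)
        spec = hs.tune_base_learner(
            hs.BaseLearnerSpec("KNN"), fm, {"n_neighbors": [1, 3, 5]}, cv_folds=3
        )
        assert spec.hyperparameters["n_neighbors"] == 1

    def test_selected_point_maximizes_cv_accuracy(self, rng):
        """Exhaustive re-evaluation: the chosen k attains the grid maximum."""
        from sklearn.model_selection import StratifiedKFold

        fm = _tiny_fm(rng, n=30, shift=1.0)
        grid = {"n_neighbors": [1, 5, 15]}
        spec = hs.tune_base_learner(hs.BaseLearnerSpec("KNN"), fm, grid,
                                    cv_folds=3, seed=4)
        skf = StratifiedKFold(3, shuffle=True, random_state=4)
        accs = {}
        for k in grid["n_neighbors"]:
            fold_accs = []
            for tr, te in skf.split(fm.X, fm.y):
                est = make_estimator(
                    hs.BaseLearnerSpec("KNN", {"n_neighbors": k}), 4, True)
                est.fit(fm.X[tr], fm.y[tr])
                fold_accs.append(np.mean(est.predict(fm.X[te]) == fm.y[te]))
            accs[k] = np.mean(fold_accs)
        assert accs[spec.hyperparameters["n_neighbors"]] == max(accs.values())

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            hs.tune_base_learner(hs.BaseLearnerSpec("KNN"), _tiny_fm(rng), {})


class TestMetaFeatures:
    def test_shape_is_n_by_four_for_sm1(self, rng):
        fm = _tiny_fm(rng, n=20)
        Z = hs.generate_meta_features(hs.StackConfig("SM1").base_specs, fm,
                                      n_folds=5, seed=0)
        assert Z.X.shape == (20, 4)
        assert ((Z.X >= 0) & (Z.X <= 1)).all()

    def test_deterministic_given_seed(self, rng):
        fm = _tiny_fm(rng, n=20)
        specs = hs.StackConfig("SM2").base_specs
        Z1 = hs.generate_meta_features(specs, fm, 4, seed=9)
        Z2 = hs.generate_meta_features(specs, fm, 4, seed=9)
        np.testing.assert_array_equal(Z1.X, Z2.X)

    def test_out_of_fold_probabilities_do_not_leak(self, rng):
        """A full-depth tree memorizes its training fold perfectly, so with
        label-independent features any fit to the labels must come from
        leakage; out-of-fold accuracy stays near chance."""
        n = 40
        X = rng.normal(size=(n, N_FEATURES))
        y = np.array([1, 0] * (n // 2))  # labels carry no signal
        fm = FeatureMatrix(ids=[f"s{i}" for i in range(n)], X=X, y=y,
                           names=feature_names(AA))
        Z = hs.generate_meta_features([hs.BaseLearnerSpec("DT")], fm, 5, seed=1)
        oof_acc = np.mean((Z.X[:, 0] >= 0.5).astype(int) == y)
        assert 0.2 <= oof_acc <= 0.8

    def test_memorizing_learner_on_separable_data(self, rng):
        fm = _tiny_fm(rng, n=16, shift=6.0, n_signal=N_FEATURES)
        Z = hs.generate_meta_features([hs.BaseLearnerSpec("KNN",
                                                          {"n_neighbors": 1})],
                                      fm, n_folds=8, seed=0)
        assert np.mean((Z.X[:, 0] >= 0.5).astype(int) == fm.y) >= 0.9

    def test_too_small_class_rejected(self, rng):
        fm = _tiny_fm(rng, n=8)
        with pytest.raises(ValueError, match="stratify"):
            hs.generate_meta_features(hs.StackConfig("SM1").base_specs, fm,
                                      n_folds=5, seed=0)


@pytest.fixture(scope="module")
def model(separable_features):
    return hs.train_stacked(hs.StackConfig("SM1", seed=3), separable_features)


class TestTrainPredict:
    def test_training_accuracy_at_least_best_base(self, model,
                                                  separable_features):
        fm = separable_features
        stack_acc = np.mean(hs.predict(model, fm) == fm.y)
        for spec in model.config.base_specs:
            est = make_estimator(spec, 3, True)
            est.fit(fm.X, fm.y)
            base_acc = np.mean(est.predict(fm.X) == fm.y)
            assert stack_acc >= base_acc - 1e-12

    def test_probabilities_in_unit_interval_and_separated(self, model,
                                                          separable_features):
        fm = separable_features
        proba = hs.predict_proba(model, fm)
        assert ((proba >= 0) & (proba <= 1)).all()
        assert proba[fm.y == 1].mean() > proba[fm.y == 0].mean()

    def test_single_row_input(self, model, separable_features):
        fm = separable_features
        one = FeatureMatrix(ids=[fm.ids[0]], X=fm.X[:1], names=fm.names)
        assert hs.predict_proba(model, one).shape == (1,)

    def test_feature_count_mismatch_named(self, model, rng):
        bad = FeatureMatrix(ids=["x"], X=rng.normal(size=(1, 10)))
        with pytest.raises(ValueError, match="mismatch"):
            hs.predict_proba(model, bad)

    def test_threshold_semantics(self, model, separable_features):
        fm = separable_features
        proba = hs.predict_proba(model, fm)
        np.testing.assert_array_equal(
            hs.predict(model, fm, 0.5), (proba >= 0.5).astype(int))
        n_strict = hs.predict(model, fm, 0.9).sum()
        n_loose = hs.predict(model, fm, 0.1).sum()
        assert n_strict <= n_loose
        with pytest.raises(ValueError, match="threshold"):
            hs.predict(model, fm, 1.5)

    def test_boundary_probability_is_positive(self):
        # label = 1 iff probability >= threshold, checked at the boundary
        assert (np.array([0.5]) >= 0.5).astype(int)[0] == 1

    def test_same_seed_gives_byte_identical_model(self, separable_features):
        fm = separable_features
        blobs = []
        for _ in range(2):
            model = hs.train_stacked(hs.StackConfig("SM1", seed=42), fm)
            buf = io.BytesIO()
            joblib.dump(model, buf)
            blobs.append(buf.getvalue())
        assert blobs[0] == blobs[1]

    def test_fingerprint_records_training_shape(self, model,
                                                separable_features):
        fp = model.training_fingerprint
        assert fp["n"] == len(separable_features)
        assert fp["n_positive"] + fp["n_negative"] == fp["n"]
        assert fp["seed"] == 3


class TestModelIO:
    def test_round_trip_predictions_identical(self, tmp_path, rng,
                                              separable_features):
        model = hs.train_stacked(hs.StackConfig("SM3", seed=1, n_meta_folds=3),
                                 separable_features)
        path = tmp_path / "m.joblib"
        hs.save_model(model, path)
        loaded = hs.load_model(path)
        probe = FeatureMatrix(ids=[f"q{i}" for i in range(10)],
                              X=rng.normal(size=(10, N_FEATURES)),
                              names=separable_features.names)
        np.testing.assert_array_equal(hs.predict_proba(model, probe),
                                      hs.predict_proba(loaded, probe))
        assert loaded.training_fingerprint == model.training_fingerprint

    def test_truncated_file_rejected(self, tmp_path, separable_features):
        model = hs.train_stacked(hs.StackConfig("SM3", seed=1, n_meta_folds=3),
                                 separable_features)
        path = tmp_path / "m.joblib"
        hs.save_model(model, path)
        (tmp_path / "bad.joblib").write_bytes(path.read_bytes()[:100])
        with pytest.raises(ValueError):
            hs.load_model(tmp_path / "bad.joblib")

    def test_non_model_file_rejected(self, tmp_path):
        joblib.dump({"something": 1}, tmp_path / "other.joblib")
        with pytest.raises(ValueError, match="not an hmmstack model"):
            hs.load_model(tmp_path / "other.joblib")
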