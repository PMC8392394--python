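import numpy as np
import pytest

from mirhairpin import (
    ConfigurationError,
    FeatureMatrix,
    TrainingError,
    apply_scaler,
    default_gamma,
    fit_scaler,
    generalized_variance,
    load_model,
    predict,
    predict_sequences,
    save_model,
    train_pipeline,
)
from mirhairpin.model import train_svm


class TestScaler:
    def test_zscore_identity_on_training_matrix(self, rng):
        X = rng.normal(size=(50, 8)) * 3 + 1
        params = fit_scaler(X)
        Xs = apply_scaler(params, X)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_maps_to_zero(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        Xs = apply_scaler(fit_scaler(X), X)
        np.testing.assert_allclose(Xs[:, 1], 0.0)

    def test_row_equal_to_training_mean_maps_to_zero(self, rng):
        X = rng.normal(size=(30, 5))
        params = fit_scaler(X)
        row = apply_scaler(params, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(row, 0.0, atol=1e-12)

    def test_saved_scaler_uses_training_statistics_only(self, rng):
        X_train = rng.normal(size=(40, 4))
        X_test = rng.normal(size=(10, 4)) + 100.0
        params = fit_scaler(X_train)
        expected = (X_test - X_train.mean(axis=0)) / X_train.std(axis=0)
        np.testing.assert_allclose(apply_scaler(params, X_test), expected)

    def test_needs_two_rows(self):
        with pytest.raises(TrainingError):
            fit_scaler(np.ones((1, 3)))

    def test_column_count_mismatch(self, rng):
        params = fit_scaler(rng.normal(size=(10, 4)))
        with pytest.raises(ConfigurationError):
            apply_scaler(params, rng.normal(size=(3, 5)))


class TestDefaultGamma:
    def test_direct_substitution(self):
        assert default_gamma(193, 1.0) == pytest.approx(1 / 193)
        assert default_gamma(1, 2.0) == pytest.approx(0.5)

    def test_matches_independent_variance_path(self, rng):
        X = rng.normal(size=(60, 12)) * 2
        Xs = apply_scaler(fit_scaler(X), X)
        sigma2 = generalized_variance(Xs)
        # recompute column variances longhand
        recomputed = float(np.mean([np.mean((Xs[:, j] - Xs[:, j].mean()) ** 2)
                                    for j in range(Xs.shape[1])]))
        assert sigma2 == pytest.approx(recomputed)
        assert default_gamma(12, sigma2) == pytest.approx(1 / (12 * sigma2))

    def test_degenerate_variance_raises(self):
        with pytest.raises(TrainingError):
            default_gamma(5, 0.0)


class TestTrainSvm:
    def test_separable_toy_data_reaches_training_accuracy_one(self, rng):
        X = np.vstack([rng.normal(size=(25, 2)) - 4, rng.normal(size=(25, 2)) + 4])
        y = np.array([0] * 25 + [1] * 25)
        svm, C, gamma, record = train_svm(X, y, grid_C=[1.0, 10.0],
                                          grid_gamma=[0.1, 1.0], folds=3, seed=0)
        assert (svm.predict(X) == y).all()
        assert any(cell["cv_auc"] == 1.0 for cell in record)

    def test_label_permuted_null_cv_auc_near_half(self, rng):
        X = rng.normal(size=(120, 10))
        y = rng.permutation([0] * 60 + [1] * 60)
        _, _, _, record = train_svm(X, y, grid_C=[1.0], grid_gamma=[0.1],
                                    folds=5, seed=1)
        assert 0.35 <= record[0]["cv_auc"] <= 0.65

    def test_same_seed_and_grid_select_same_cell(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.array([0, 1] * 20)
        X[y == 1] += 1.0
        sel = [train_svm(X, y, grid_C=[0.5, 2.0, 8.0], grid_gamma=[0.05, 0.2],
                         folds=4, seed=3)[1:3] for _ in range(2)]
        assert sel[0] == sel[1]

    def test_tie_broken_toward_smaller_c_then_gamma(self, rng):
        # perfectly separable -> every cell ties at AUC 1; smallest must win
        X = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 10])
        y = np.array([0] * 10 + [1] * 10)
        _, C, gamma, _ = train_svm(X, y, grid_C=[8.0, 0.5], grid_gamma=[1.0, 0.01],
                                   folds=2, seed=0)
        assert (C, gamma) == (0.5, 0.01)

    def test_single_class_raises(self, rng):
        with pytest.raises(TrainingError):
            train_svm(rng.normal(size=(10, 3)), np.ones(10), folds=2, seed=0)

    def test_nan_features_named(self, rng):
        X = rng.normal(size=(10, 3))
        X[0, 1] = np.nan
        with pytest.raises(TrainingError):
            train_svm(X, np.array([0, 1] * 5), folds=2, seed=0)


@pytest.fixture(scope="module")
def pipeline_model(small_benchmark):
    pos_pairs, neg_pairs = small_benchmark
    return train_pipeline(pos_pairs, neg_pairs, grid_C=[1.0, 8.0],
                          grid_gamma=None, folds=3, seed=17)


class TestPipelinePredict:
    def test_training_points_recovered_on_separable_data(
            self, pipeline_model, small_benchmark):
        pos_pairs, neg_pairs = small_benchmark
        _, _, labels = predict_sequences(pipeline_model, pos_pairs + neg_pairs)
        acc = np.mean(labels == [1] * len(pos_pairs) + [0] * len(neg_pairs))
        assert acc > 0.9

    def test_duplicated_rows_get_identical_scores(
            self, pipeline_model, small_benchmark):
        item = small_benchmark[0][0]
        _, scores, _ = predict_sequences(pipeline_model, [item, item])
        assert scores[0] == scores[1]

    def test_scores_co_monotone_with_decision_values(
            self, pipeline_model, small_benchmark, trained_tables):
        from mirhairpin import featurize_many

        pos_pairs, neg_pairs = small_benchmark
        fm = featurize_many(pos_pairs + neg_pairs, pipeline_model.tables)
        dv = pipeline_model.decision_values(fm)
        scores, labels = predict(pipeline_model, fm)
        order_dv = np.argsort(dv, kind="stable")
        order_sc = np.argsort(scores, kind="stable")
        np.testing.assert_array_equal(order_dv, order_sc)
        np.testing.assert_array_equal(labels, (dv >= 0).astype(int))

    def test_manifest_mismatch_is_refused(self, pipeline_model, small_benchmark,
                                          trained_tables):
        from mirhairpin import featurize_many

        fm = featurize_many(small_benchmark[0][:3], trained_tables)
        fm.manifest_version = "other-version"
        with pytest.raises(ConfigurationError):
            predict(pipeline_model, fm)

    def test_save_load_round_trip_predictions(self, tmp_path, pipeline_model,
                                              small_benchmark):
        pos_pairs, neg_pairs = small_benchmark
        items = pos_pairs[:5] + neg_pairs[:5]
        save_model(pipeline_model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        _, s1, _ = predict_sequences(pipeline_model, items)
        _, s2, _ = predict_sequences(loaded, items)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_prediction_does_not_mutate_fitted_state(self, pipeline_model,
                                                     small_benchmark):
        mu_before = pipeline_model.scaler.mu.copy()
        prov_before = pipeline_model.tables.position_specific.provenance
        entries_before = pipeline_model.tables.position_specific.entries.copy()
        predict_sequences(pipeline_model, small_benchmark[1][:5])
        np.testing.assert_array_equal(pipeline_model.scaler.mu, mu_before)
        assert pipeline_model.tables.position_specific.provenance == prov_before
        np.testing.assert_array_equal(
            pipeline_model.tables.position_specific.entries, entries_before)

    def test_empty_class_raises(self, small_benchmark):
        with pytest.raises(TrainingError):
            train_pipeline(small_benchmark[0], [], seed=0)
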