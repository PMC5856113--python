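import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.model_selection import KFold, cross_val_score

from grasspix.labelling import PixelDataset
from grasspix.model import (
    BoostedPixelClassifier,
    Hyperparams,
    cross_validate,
    feature_importance,
    grid_search,
    load_model,
    save_model,
    split_dataset,
    train_classifier,
)


class TestSplitDataset:
    def test_survey_scale_partition_sizes(self):
        n = 342_626
        data = PixelDataset(np.zeros((n, 10)), np.ones(n, dtype=int))
        train, test = split_dataset(data, 0.75, seed=0)
        assert train.n == 256_969  # floor(0.75 · 342,626)
        assert test.n == 85_657

    def test_smallest_nondegenerate_case(self, rng):
        data = PixelDataset(rng.random((4, 10)), rng.integers(1, 7, 4))
        train, test = split_dataset(data, 0.75, seed=3)
        assert (train.n, test.n) == (3, 1)

    def test_same_seed_replays_different_seed_differs(self, rng):
        data = PixelDataset(rng.random((200, 10)), rng.integers(1, 7, 200))
        a1, b1 = split_dataset(data, 0.75, seed=11)
        a2, b2 = split_dataset(data, 0.75, seed=11)
        assert np.array_equal(a1.features, a2.features)
        assert np.array_equal(b1.labels, b2.labels)
        a3, _ = split_dataset(data, 0.75, seed=12)
        assert not np.array_equal(a1.features, a3.features)

    def test_partition_restores_input_multiset(self, rng):
        data = PixelDataset(rng.random((101, 10)), rng.integers(1, 7, 101))
        train, test = split_dataset(data, 0.6, seed=5)
        merged = np.vstack([train.features, test.features])
        assert np.array_equal(
            np.sort(merged, axis=0), np.sort(data.features, axis=0)
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(n=st.integers(2, 400), frac_pct=st.integers(1, 99))
    def test_sizes_exact_for_any_fraction(self, n, frac_pct):
        frac = frac_pct / 100
        data = PixelDataset(np.zeros((n, 10)), np.ones(n, dtype=int))
        n_train = int(np.floor(frac * n))
        if n_train < 1 or n - n_train < 1:
            with pytest.raises(ValueError, match="empty partition"):
                split_dataset(data, frac, seed=0)
            return
        train, test = split_dataset(data, frac, seed=0)
        assert train.n == n_train
        assert train.n + test.n == n

    def test_too_small_rejected(self):
        data = PixelDataset(np.zeros((1, 10)), np.ones(1, dtype=int))
        with pytest.raises(ValueError, match="at least 2"):
            split_dataset(data, 0.75, seed=0)


class TestTrainClassifier:
    def test_defaults_are_the_tuned_values(self):
        hp = Hyperparams()
        assert (hp.n_estimators, hp.learning_rate, hp.max_depth) == (100, 0.1, 3)

    def test_single_class_predicts_that_class(self, rng):
        data = PixelDataset(rng.random((30, 10)), np.full(30, 2))
        model = train_classifier(data, seed=0)
        assert np.all(model.predict(rng.random((12, 10))) == 2)

    def test_separable_classes_reach_perfect_training_accuracy(
        self, separable_data
    ):
        model = train_classifier(separable_data, seed=0)
        pred = model.predict(separable_data.features)
        assert np.mean(pred == separable_data.labels) == 1.0

    def test_fixed_seed_is_bit_reproducible(self, separable_data, rng):
        probe = rng.random((50, 10))
        p1 = train_classifier(separable_data, seed=4).predict_proba(probe)
        p2 = train_classifier(separable_data, seed=4).predict_proba(probe)
        assert np.array_equal(p1, p2)

    def test_empty_training_set_rejected(self):
        data = PixelDataset(np.zeros((0, 10)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            train_classifier(data, seed=0)


class TestCrossValidate:
    def test_separable_data_scores_one_with_zero_std(self, separable_data):
        cv = cross_validate(Hyperparams(n_estimators=20), separable_data,
                            k=4, seed=0)
        assert cv.mean_accuracy == 1.0
        assert cv.std_accuracy == 0.0

    def test_mean_std_consistent_with_fold_vector(self, separable_data):
        cv = cross_validate(Hyperparams(n_estimators=10), separable_data,
                            k=3, seed=1)
        assert cv.mean_accuracy == pytest.approx(np.mean(cv.fold_accuracies))
        assert cv.std_accuracy == pytest.approx(np.std(cv.fold_accuracies))

    def test_matches_sklearn_fold_loop(self, rng):
        # independent oracle: sklearn cross_val_score over the same folds
        feats = rng.random((150, 10))
        labels = rng.integers(1, 4, 150)
        feats[:, 0] += labels * 0.3  # weak signal so folds differ
        data = PixelDataset(feats, labels)
        hp = Hyperparams(n_estimators=15)
        cv = cross_validate(hp, data, k=5, seed=9)
        ref = cross_val_score(
            BoostedPixelClassifier(n_estimators=15, random_state=9),
            feats, labels, cv=KFold(5, shuffle=True, random_state=9),
        )
        assert np.allclose(cv.fold_accuracies, ref)

    def test_k_larger_than_n_rejected(self, rng):
        data = PixelDataset(rng.random((5, 10)), rng.integers(1, 7, 5))
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(Hyperparams(), data, k=10, seed=0)


class TestGridSearch:
    def test_singleton_grid_returns_it(self, separable_data):
        only = Hyperparams(n_estimators=10)
        best, table = grid_search(separable_data, (only,), k=3, seed=0)
        assert best == only
        assert len(table) == 1

    def test_winner_matches_explicit_reevaluation(self, rng):
        feats = rng.random((120, 10))
        labels = rng.integers(1, 4, 120)
        feats[:, 1] += labels * 0.4
        data = PixelDataset(feats, labels)
        grid = (Hyperparams(n_estimators=5, max_depth=2),
                Hyperparams(n_estimators=40, max_depth=3))
        best, table = grid_search(data, grid, k=3, seed=2)
        means = [cross_validate(hp, data, k=3, seed=2).mean_accuracy
                 for hp in grid]
        assert best == grid[int(np.argmax(means))]
        assert np.allclose(table["mean_accuracy"], means)
        # winner never scores below any other grid point
        assert table["mean_accuracy"].max() == pytest.approx(
            table.loc[
                (table.n_estimators == best.n_estimators)
                & (table.max_depth == best.max_depth),
                "mean_accuracy",
            ].iloc[0]
        )

    def test_ties_break_to_cheapest_model(self, separable_data):
        # both grid points reach accuracy 1.0 on separable data
        grid = (Hyperparams(n_estimators=50, max_depth=5),
                Hyperparams(n_estimators=10, max_depth=2))
        best, _ = grid_search(separable_data, grid, k=3, seed=0)
        assert best.n_estimators == 10

    def test_empty_grid_rejected(self, separable_data):
        with pytest.raises(ValueError, match="nonempty"):
            grid_search(separable_data, (), k=3, seed=0)


class TestFeatureImportance:
    def test_scores_sum_to_one(self, separable_data):
        model = train_classifier(separable_data, seed=0)
        assert sum(feature_importance(model).values()) == pytest.approx(1.0)

    def test_single_informative_feature_dominates(self, rng):
        feats = rng.random((400, 10))
        labels = np.where(feats[:, 0] < 0.5, 1, 6)
        model = train_classifier(PixelDataset(feats, labels), seed=0)
        scores = feature_importance(model)
        assert max(scores, key=scores.get) == "hue"

    def test_untrained_model_rejected(self):
        with pytest.raises(Exception):
            feature_importance(BoostedPixelClassifier())


class TestPersistence:
    def test_round_trip_preserves_predictions(self, separable_data, tmp_path, rng):
        model = train_classifier(separable_data, seed=0)
        path = tmp_path / "model.xgb.json"
        save_model(model, path)
        loaded = load_model(path)
        probe = rng.random((40, 10))
        assert np.array_equal(model.predict(probe), loaded.predict(probe))
        assert loaded.feature_names_ == model.feature_names_

    def test_feature_schema_mismatch_refused(self, separable_data, tmp_path):
        import json

        model = train_classifier(separable_data, seed=0)
        path = tmp_path / "model.xgb.json"
        save_model(model, path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text())
        meta["feature_names"][0] = "bogus"
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="schema"):
            load_model(path)
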