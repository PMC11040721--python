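"""Resampling, grid-searched classifiers, masked loss and the multi-output net."""

import numpy as np
import pandas as pd
import pytest

import fingertox as ft


def imbalanced_data(seed=0, n=100, n_pos=10, d=4):
    rng = np.random.default_rng(seed)
    X = rng.random((n, d))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    return X, y


class TestResampleBalance:
    def test_down_sampling_matches_minority_size(self):
        X, y = imbalanced_data()
        Xr, yr = ft.resample_balance(X, y, "down", seed=1)
        assert (yr == 1).sum() == (yr == 0).sum() == 10

    def test_up_sampling_matches_majority_size(self):
        X, y = imbalanced_data()
        Xr, yr = ft.resample_balance(X, y, "up", seed=2)
        assert (yr == 1).sum() == (yr == 0).sum() == 90
        # majority rows are never fabricated
        assert len(np.unique(Xr[yr == 0], axis=0)) <= 90

    def test_smote_points_lie_between_their_parents(self):
        X, y = imbalanced_data(n_pos=20)
        Xr, yr = ft.resample_balance(X, y, "smote", k_neighbors=5, seed=3)
        synth = Xr[len(X):]
        assert (yr[len(X):] == 1).all()
        minority = X[y == 1]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()

    def test_feature_dimension_preserved(self):
        X, y = imbalanced_data(d=7)
        for method in ("down", "up", "smote"):
            Xr, _ = ft.resample_balance(X, y, method, seed=4)
            assert Xr.shape[1] == 7

    def test_single_class_rejected(self):
        X = np.random.random((10, 3))
        with pytest.raises(ValueError, match="both classes"):
            ft.resample_balance(X, np.zeros(10), "down")

    def test_tiny_minority_reduces_k_with_warning(self):
        X, y = imbalanced_data(n_pos=3)
        with pytest.warns(UserWarning, match="k="):
            Xr, yr = ft.resample_balance(X, y, "smote", k_neighbors=5, seed=5)
        assert (yr == 1).sum() == (yr == 0).sum()


class TestToxicityClassifier:
    def test_separable_data_reaches_perfect_cv_auc(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.integers(0, 2, size=(200, 5)).astype(float))
        y = X[0]  # label equals the first feature
        clf = ft.train_single_output(
            X, y, "logistic", folds=np.arange(200) % 5, random_state=0
        )
        assert clf.best_score_ == pytest.approx(1.0)

    def test_constant_features_give_chance_auc(self):
        rng = np.random.default_rng(11)
        X = np.ones((200, 3))
        y = rng.integers(0, 2, 200)
        clf = ft.train_single_output(
            X, y, "logistic", folds=np.arange(200) % 5, random_state=1
        )
        assert clf.best_score_ == pytest.approx(0.5, abs=0.15)

    def test_missing_labels_dropped_before_training(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.integers(0, 2, size=(120, 4)).astype(float))
        y = X[0].copy()
        y.iloc[:30] = np.nan
        clf = ft.train_single_output(
            X, y, "logistic", folds=np.arange(120) % 4, random_state=2
        )
        assert clf.best_score_ == pytest.approx(1.0)

    def test_tied_grid_points_resolve_to_first_in_order(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.integers(0, 2, size=(100, 3)).astype(float))
        y = X[0]
        clf = ft.train_single_output(
            X,
            y,
            "logistic",
            grid={"C": [1.0, 1.0 + 1e-12]},
            folds=np.arange(100) % 4,
            random_state=3,
        )
        assert clf.best_params_ == {"C": 1.0}

    def test_empty_grid_rejected(self):
        X, y = imbalanced_data()
        with pytest.raises(ValueError, match="empty"):
            ft.train_single_output(X, y, "logistic", grid=[])

    def test_missing_feature_column_raises_by_name(self, fingerprints_small):
        y = fingerprints_small.iloc[:, 0]
        clf = ft.train_single_output(
            fingerprints_small, y, "logistic", folds=np.arange(len(y)) % 3
        )
        with pytest.raises(ValueError, match="fp_000"):
            clf.score(fingerprints_small.drop(columns=["fp_000"]))


class TestMaskedBce:
    def test_hand_computed_case(self):
        loss = ft.masked_bce([0.8, 0.2, 0.9], [1.0, 0.0, np.nan])
        assert loss == pytest.approx(-(np.log(0.8) + np.log(0.8)) / 2)
        assert loss == pytest.approx(0.2231, abs=1e-4)

    def test_reduces_to_plain_bce_without_missing_labels(self):
        rng = np.random.default_rng(20)
        p = rng.uniform(0.01, 0.99, size=(8, 4))
        y = rng.integers(0, 2, size=(8, 4)).astype(float)
        plain = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert abs(ft.masked_bce(p, y) - plain) <= 1e-12

    def test_all_missing_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no observed"):
            assert ft.masked_bce([[0.5]], [[np.nan]]) == 0.0

    def test_gradient_zero_at_missing_and_matches_finite_differences(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.1, 0.9, size=(3, 4))
        y = rng.integers(0, 2, size=(3, 4)).astype(float)
        y[0, 1] = np.nan
        y[2, 3] = np.nan
        grad = ft.masked_bce_grad(p, y)
        assert grad[0, 1] == 0.0 and grad[2, 3] == 0.0
        eps = 1e-6
        for i in range(3):
            for j in range(4):
                bumped = p.copy()
                bumped[i, j] += eps
                fd = (ft.masked_bce(bumped, y) - ft.masked_bce(p, y)) / eps
                assert grad[i, j] == pytest.approx(fd, abs=1e-4)


class TestMaskedMLP:
    def test_training_reduces_masked_loss(self, fingerprints_small, labels_small):
        net = ft.train_multi_output(
            fingerprints_small,
            labels_small,
            hidden_layer_sizes=(16,),
            max_epochs=30,
            early_stopping=False,
            random_state=0,
        )
        log = net.training_log_
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_outputs_are_probabilities_per_assay(
        self, fingerprints_small, labels_small
    ):
        net = ft.train_multi_output(
            fingerprints_small, labels_small, max_epochs=10, random_state=1
        )
        proba = net.predict_proba(fingerprints_small)
        assert proba.shape == (len(fingerprints_small), labels_small.shape[1])
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_deterministic_given_seed(self, fingerprints_small, labels_small):
        nets = [
            ft.train_multi_output(
                fingerprints_small, labels_small, max_epochs=10, random_state=7
            )
            for _ in range(2)
        ]
        np.testing.assert_allclose(
            nets[0].predict_proba(fingerprints_small),
            nets[1].predict_proba(fingerprints_small),
        )

    def test_regularizers_smoke(self, fingerprints_small, labels_small):
        net = ft.train_multi_output(
            fingerprints_small,
            labels_small,
            hidden_layer_sizes=(16, 16),
            dropout=0.2,
            batch_norm=True,
            max_epochs=15,
            random_state=2,
        )
        proba = net.predict_proba(fingerprints_small)
        assert np.isfinite(proba).all()

    def test_assay_with_no_observed_labels_rejected(self, fingerprints_small):
        labels = pd.DataFrame(
            np.nan, index=fingerprints_small.index, columns=["a"]
        )
        labels.iloc[:10, 0] = 1.0
        bad = labels.copy()
        bad["b"] = np.nan
        with pytest.raises(ValueError, match="b"):
            ft.train_multi_output(fingerprints_small, bad, max_epochs=2)


class TestPredictScores:
    def test_batch_equals_single_row(self, fingerprints_small, labels_small):
        net = ft.train_multi_output(
            fingerprints_small, labels_small, max_epochs=5, random_state=3
        )
        batch = ft.predict_scores(net, fingerprints_small.iloc[:5])
        single = ft.predict_scores(net, fingerprints_small.iloc[[2]])
        np.testing.assert_allclose(batch.iloc[2].to_numpy(), single.iloc[0].to_numpy())

    def test_extra_columns_ignored_by_name(self, fingerprints_small, labels_small):
        y = labels_small.iloc[:, 0]
        clf = ft.train_single_output(
            fingerprints_small, y, "logistic", folds=np.arange(len(y)) % 3
        )
        extra = fingerprints_small.copy()
        extra["unrelated"] = 1.0
        shuffled = extra[list(extra.columns[::-1])]
        np.testing.assert_allclose(
            ft.predict_scores(clf, fingerprints_small).to_numpy(),
            ft.predict_scores(clf, shuffled).to_numpy(),
        )
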