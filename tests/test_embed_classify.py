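"""Reducer and classifier contracts: PCA against a direct SVD oracle,
separability preservation, CV-scheme invariants, grid structure and the
permutation-null calibration at small scale."""

import numpy as np
import pandas as pd
import pytest

from gaitclass.classification import (
    CVScheme,
    DEFAULT_CLASSIFIERS,
    decision_surface,
    evaluate_grid,
    fit_predict,
    make_classifier,
    split,
)
from gaitclass.embedding import reduce_features, transform_out_of_sample
from gaitclass.features import FEATURE_COLUMNS


def _blobs(n_per_class=100, separation=10.0, n_features=6, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b = rng.normal(separation, 1.0, size=(n_per_class, n_features))
    X = np.vstack([a, b])
    y = np.array(["healthy"] * n_per_class + ["ataxic"] * n_per_class)
    return X, y


class TestReduce:
    def test_pca_recovers_rank2_plane(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 6))
        scores = rng.normal(size=(80, 2))
        X = scores @ basis  # exactly rank 2
        result = reduce_features(X, "PCA", seed=0)
        reconstructed = result.model.inverse_transform(result.coordinates)
        np.testing.assert_allclose(reconstructed, X, atol=1e-10)

    def test_pca_matches_direct_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        coords = reduce_features(X, "PCA", seed=0).coordinates
        centred = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        oracle = centred @ vt[:2].T
        for k in range(2):  # per-component sign is arbitrary
            assert np.allclose(coords[:, k], oracle[:, k], atol=1e-8) or np.allclose(
                coords[:, k], -oracle[:, k], atol=1e-8
            )

    @pytest.mark.parametrize("method", ["PCA", "TSNE", "UMAP"])
    def test_separated_blobs_stay_separable(self, method):
        """Two 10-sigma blobs remain 1-NN separable after each reduction."""
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.model_selection import cross_val_score

        X, y = _blobs(seed=3)
        coords = reduce_features(X, method, seed=4).coordinates
        score = cross_val_score(
            KNeighborsClassifier(n_neighbors=1), coords, y, cv=5
        ).mean()
        assert score == 1.0

    @pytest.mark.parametrize("method", ["PCA", "TSNE", "UMAP"])
    def test_deterministic_under_seed(self, method):
        X, _ = _blobs(n_per_class=30, seed=5)
        c1 = reduce_features(X, method, seed=6).coordinates
        c2 = reduce_features(X, method, seed=6).coordinates
        np.testing.assert_array_equal(c1, c2)

    def test_unknown_method_rejected(self):
        X, _ = _blobs(n_per_class=10)
        with pytest.raises(ValueError, match="unknown reducer"):
            reduce_features(X, "NMF", seed=0)

    def test_out_of_sample_placement_lands_near_class(self):
        X, y = _blobs(n_per_class=60, seed=7)
        result = reduce_features(X, "TSNE", seed=8)
        new = np.vstack([np.zeros(6), np.full(6, 10.0)])
        placed = transform_out_of_sample(result, new)
        blob_a = result.coordinates[:60].mean(axis=0)
        blob_b = result.coordinates[60:].mean(axis=0)
        assert np.linalg.norm(placed[0] - blob_a) < np.linalg.norm(placed[0] - blob_b)
        assert np.linalg.norm(placed[1] - blob_b) < np.linalg.norm(placed[1] - blob_a)


class TestSplit:
    def _table(self, n=100, n_participants=10, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["participant_id"] = [f"P{i % n_participants}" for i in range(n)]
        df["label"] = np.where(np.arange(n) % 2 == 0, "ataxic", "healthy")
        return df

    def test_holdout_60_40_stratified(self):
        table = self._table(100)
        [(train, test)] = split(table, CVScheme("holdout_60_40", seed=1))
        assert len(train) == 60 and len(test) == 40
        train_pos = (table.iloc[train]["label"] == "ataxic").mean()
        test_pos = (table.iloc[test]["label"] == "ataxic").mean()
        assert abs(train_pos - test_pos) <= 0.05

    def test_logo_one_fold_per_participant(self):
        table = self._table(86, n_participants=43)
        folds = split(table, CVScheme("leave_one_group_out"))
        assert len(folds) == 43

    def test_logo_no_participant_straddles_folds(self):
        table = self._table(60, n_participants=6)
        for train, test in split(table, CVScheme("leave_one_group_out")):
            train_ids = set(table.iloc[train]["participant_id"])
            test_ids = set(table.iloc[test]["participant_id"])
            assert not train_ids & test_ids

    def test_logo_single_participant_rejected(self):
        table = self._table(10, n_participants=1)
        with pytest.raises(ValueError):
            split(table, CVScheme("leave_one_group_out"))


class TestFitPredict:
    def test_1nn_memorises_training_set(self):
        X, y = _blobs(n_per_class=20, separation=1.0)
        preds = fit_predict(
            "Nearest Neighbors", (X, y), X, seed=0, hyperparams={"n_neighbors": 1}
        )
        assert (preds == y).all()

    def test_single_class_training_gives_constant_predictions(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array(["healthy"] * 10)
        preds = fit_predict("Random Forest", (X, y), X, seed=0)
        assert (preds == "healthy").all()

    def test_random_forest_on_separated_blobs(self):
        X, y = _blobs(n_per_class=100, separation=10.0, seed=9)
        rng = np.random.default_rng(10)
        order = rng.permutation(len(X))
        train, test = order[:140], order[140:]
        preds = fit_predict("Random Forest", (X[train], y[train]), X[test], seed=0)
        assert (preds == y[test]).mean() >= 0.99

    def test_unknown_classifier_lists_registry(self):
        with pytest.raises(ValueError, match="registry"):
            fit_predict("Perceptron", (np.zeros((4, 2)), np.array(["a"] * 4)), np.zeros((1, 2)), 0)

    def test_registry_has_the_ten_table_classifiers(self):
        assert len(DEFAULT_CLASSIFIERS) == 10
        assert "Quadratic" not in DEFAULT_CLASSIFIERS


@pytest.fixture(scope="module")
def blob_table():
    X, y = _blobs(n_per_class=60, separation=10.0, seed=11)
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS[:6])
    df["label"] = y
    df["participant_id"] = [f"P{i % 12}" for i in range(len(df))]
    df["severity"] = 0.0
    return df


class TestEvaluateGrid:
    def test_grid_structure_and_metric_ranges(self, blob_table):
        evaluation = evaluate_grid(
            blob_table,
            FEATURE_COLUMNS[:6],
            reducers=("PCA",),
            classifiers=["Random Forest", "Naive Bayes"],
            seed=1,
        )
        assert len(evaluation.cells) == 2
        for cell in evaluation.cells:
            assert cell.error is None
            for value in (cell.accuracy, cell.sensitivity, cell.specificity):
                assert 0 <= value <= 1

    def test_grid_deterministic_under_seed(self, blob_table):
        kwargs = dict(
            feature_cols=FEATURE_COLUMNS[:6],
            reducers=("PCA", "TSNE"),
            classifiers=["Random Forest"],
            seed=5,
        )
        a = evaluate_grid(blob_table, **kwargs).to_frame()
        b = evaluate_grid(blob_table, **kwargs).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_label_permutation_null_accuracy(self, blob_table):
        """With permuted labels no cell should beat chance beyond binomial
        99.9% bounds."""
        rng = np.random.default_rng(20)
        null_table = blob_table.copy()
        null_table["label"] = rng.permutation(null_table["label"].to_numpy())
        evaluation = evaluate_grid(
            null_table,
            FEATURE_COLUMNS[:6],
            reducers=("PCA",),
            classifiers=["Random Forest", "Logistic Regression", "Nearest Neighbors"],
            seed=2,
        )
        n_test = len(evaluation.cells[0].truths)
        bound = 3.29 * np.sqrt(0.25 / n_test)
        for cell in evaluation.cells:
            assert abs(cell.accuracy - 0.5) <= bound + 1e-9

    def test_strict_mode_fits_on_training_rows_only(self, blob_table):
        evaluation = evaluate_grid(
            blob_table,
            FEATURE_COLUMNS[:6],
            reducers=("PCA",),
            classifiers=["Nearest Neighbors"],
            seed=3,
            mode="strict",
        )
        assert evaluation.cells[0].accuracy == 1.0
        assert "leakage_warning" not in evaluation.provenance

    def test_joint_mode_carries_leakage_warning(self, blob_table):
        evaluation = evaluate_grid(
            blob_table,
            FEATURE_COLUMNS[:6],
            reducers=("PCA",),
            classifiers=["Naive Bayes"],
            seed=4,
            mode="joint",
        )
        assert "leakage_warning" in evaluation.provenance

    def test_cell_failure_flagged_not_fatal(self, blob_table):
        evaluation = evaluate_grid(
            blob_table,
            FEATURE_COLUMNS[:6],
            reducers=("PCA",),
            classifiers=["Random Forest"],
            seed=5,
            balancing="smote",
            # force SMOTE failure: k too large for the balanced-ish classes
            # is not triggerable here, so break the classifier hyperparams
            classifier_hyperparams={"Random Forest": {"n_estimators": -1}},
        )
        assert evaluation.cells[0].error is not None


class TestDecisionSurface:
    def test_grid_resolution_and_labels(self):
        X, y = _blobs(n_per_class=40, separation=8.0, seed=12)
        coords = reduce_features(X, "PCA", seed=0).coordinates
        clf = make_classifier("Nearest Neighbors", 0)
        clf.fit(coords, y)
        xx, yy, labels = decision_surface(clf, coords, grid_resolution=50)
        assert xx.shape == yy.shape == labels.shape == (50, 50)
        assert set(np.unique(labels)) <= {"ataxic", "healthy"}

    def test_linear_svm_boundary_is_straight(self):
        """Boundary nodes of a linear SVM surface lie on one straight line."""
        X, y = _blobs(n_per_class=50, separation=6.0, seed=13)
        coords = reduce_features(X, "PCA", seed=0).coordinates
        clf = make_classifier("Linear SVM", 0)
        clf.fit(coords, y)
        xx, yy, labels = decision_surface(clf, coords, grid_resolution=200)
        binary = (labels == "ataxic").astype(int)
        edges = np.nonzero(np.diff(binary, axis=1) != 0)
        bx = xx[edges[0], edges[1]]
        by = yy[edges[0], edges[1]]
        assert len(bx) > 20
        # total-least-squares collinearity: first principal axis of the
        # boundary nodes carries >99% of their variance
        pts = np.column_stack([bx, by])
        pts = pts - pts.mean(axis=0)
        s = np.linalg.svd(pts, compute_uv=False)
        assert s[0] ** 2 / (s**2).sum() > 0.99

    def test_untrained_classifier_rejected(self):
        clf = make_classifier("Random Forest", 0)
        with pytest.raises(ValueError, match="trained"):
            decision_surface(clf, np.zeros((10, 2)))

    def test_1nn_training_points_keep_their_labels(self):
        rng = np.random.default_rng(14)
        coords = rng.uniform(-1, 1, size=(20, 2))
        y = np.array(["ataxic", "healthy"] * 10)
        clf = make_classifier("Nearest Neighbors", 0, {"n_neighbors": 1})
        clf.fit(coords, y)
        _, _, labels = decision_surface(clf, coords, grid_resolution=400)
        xs = np.linspace(coords[:, 0].min() - 0.05 * 2, coords[:, 0].max() + 0.05 * 2, 400)
        ys = np.linspace(coords[:, 1].min() - 0.05 * 2, coords[:, 1].max() + 0.05 * 2, 400)
        for point, label in zip(coords, y):
            i = np.argmin(np.abs(ys - point[1]))
            j = np.argmin(np.abs(xs - point[0]))
            assert labels[i, j] == label
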