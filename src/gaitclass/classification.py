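"""Shallow classifiers, cross-validation schemes and the reducer x
classifier evaluation grid.

The registry holds the ten classifiers of the results tables (logistic
regression; linear, polynomial and RBF SVMs; naive Bayes; k-NN; decision
tree; random forest; a one-hidden-layer neural network; AdaBoost), plus an
optional quadratic discriminant.  Two validation schemes are supported: a
stratified 60/40 holdout and leave-one-group-out with the participant as
the group, which prevents subject-level leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneGroupOut, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .balancing import balance
from .embedding import REDUCERS, reduce_features, transform_out_of_sample
from .evaluation import ConfusionMetrics, confusion_metrics
from .scaling import fit_scaler

__all__ = [
    "CLASSIFIER_REGISTRY",
    "CVScheme",
    "CellResult",
    "EvaluationMatrix",
    "make_classifier",
    "fit_predict",
    "split",
    "evaluate_grid",
    "decision_surface",
]


def _registry() -> dict[str, Callable[[int, dict], Any]]:
    return {
        "Logistic Regression": lambda seed, hp: LogisticRegression(
            max_iter=1000, random_state=seed, **hp
        ),
        "Linear SVM": lambda seed, hp: SVC(
            kernel="linear", random_state=seed, **hp
        ),
        "Poly SVM": lambda seed, hp: SVC(
            kernel="poly", random_state=seed, **{"degree": 3, **hp}
        ),
        "RBF SVM": lambda seed, hp: SVC(kernel="rbf", random_state=seed, **hp),
        "Naive Bayes": lambda seed, hp: GaussianNB(**hp),
        "Nearest Neighbors": lambda seed, hp: KNeighborsClassifier(
            **{"n_neighbors": 5, **hp}
        ),
        "Decision Tree": lambda seed, hp: DecisionTreeClassifier(
            random_state=seed, **hp
        ),
        "Random Forest": lambda seed, hp: RandomForestClassifier(
            random_state=seed, **{"n_estimators": 100, **hp}
        ),
        "Neural Net": lambda seed, hp: MLPClassifier(
            random_state=seed, **{"hidden_layer_sizes": (100,), "max_iter": 500, **hp}
        ),
        "AdaBoost": lambda seed, hp: AdaBoostClassifier(
            random_state=seed, **{"n_estimators": 50, **hp}
        ),
        # listed in the methods but absent from all results tables; kept
        # out of the default grid
        "Quadratic": lambda seed, hp: QuadraticDiscriminantAnalysis(**hp),
    }


CLASSIFIER_REGISTRY = _registry()

#: The ten classifiers of the results tables, in table order.
DEFAULT_CLASSIFIERS = [name for name in CLASSIFIER_REGISTRY if name != "Quadratic"]


def make_classifier(name: str, seed: int, hyperparams: dict | None = None):
    if name not in CLASSIFIER_REGISTRY:
        raise ValueError(
            f"unknown classifier {name!r}; registry: {sorted(CLASSIFIER_REGISTRY)}"
        )
    return CLASSIFIER_REGISTRY[name](seed, dict(hyperparams or {}))


def fit_predict(
    classifier_name: str,
    train: tuple[np.ndarray, np.ndarray],
    test: np.ndarray,
    seed: int,
    hyperparams: dict | None = None,
) -> np.ndarray:
    """Train the named classifier and predict one label per test row."""
    X_train, y_train = train
    clf = make_classifier(classifier_name, seed, hyperparams)
    if len(np.unique(y_train)) < 2:
        # degenerate single-class training data: constant prediction
        return np.full(len(test), np.asarray(y_train)[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        clf.fit(X_train, y_train)
    return clf.predict(np.asarray(test))


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: 60/40 stratified holdout or LOGO by participant."""

    kind: str = "holdout_60_40"
    seed: int = 0
    stratify: bool = True
    group_key: str = "participant_id"

    def __post_init__(self) -> None:
        if self.kind not in ("holdout_60_40", "leave_one_group_out"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")


def split(
    table: pd.DataFrame, scheme: CVScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Row-index folds: one 60/40 fold, or one LOGO fold per participant."""
    idx = np.arange(len(table))
    if scheme.kind == "holdout_60_40":
        labels = table["label"].to_numpy()
        train, test = train_test_split(
            idx,
            test_size=0.4,
            random_state=scheme.seed,
            stratify=labels if scheme.stratify else None,
        )
        return [(np.sort(train), np.sort(test))]
    groups = table[scheme.group_key].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("leave-one-group-out requires at least 2 participants")
    logo = LeaveOneGroupOut()
    return [
        (train, test) for train, test in logo.split(idx, groups=groups)
    ]


@dataclass
class CellResult:
    """One (reducer, classifier) cell: pooled predictions and metrics."""

    reducer: str
    classifier: str
    truths: np.ndarray
    predictions: np.ndarray
    metrics: ConfusionMetrics
    error: str | None = None

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    @property
    def sensitivity(self) -> float:
        return self.metrics.sensitivity

    @property
    def specificity(self) -> float:
        return self.metrics.specificity


@dataclass
class EvaluationMatrix:
    """Reducer x classifier grid of :class:`CellResult`."""

    cells: list[CellResult]
    scheme: CVScheme
    mode: str
    provenance: dict[str, Any] = field(default_factory=dict)

    def cell(self, reducer: str, classifier: str) -> CellResult:
        for c in self.cells:
            if c.reducer == reducer and c.classifier == classifier:
                return c
        raise KeyError((reducer, classifier))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reducer": c.reducer,
                    "classifier": c.classifier,
                    "accuracy": c.accuracy,
                    "sensitivity": c.sensitivity,
                    "specificity": c.specificity,
                    "error": c.error or "",
                }
                for c in self.cells
            ]
        )

    def accuracy_grid(self) -> pd.DataFrame:
        """Classifier x reducer accuracy table (the headline grid layout)."""
        frame = self.to_frame()
        return frame.pivot(index="classifier", columns="reducer", values="accuracy")

    def mean_accuracy(self) -> float:
        valid = [c.accuracy for c in self.cells if c.error is None]
        if not valid:
            return float("nan")
        return float(np.mean(valid))


def _cell_seed(base_seed: int, reducer: str, classifier: str) -> int:
    mix = sum(ord(ch) * (i + 1) for i, ch in enumerate(reducer + "|" + classifier))
    return (base_seed * 99991 + mix) % (2**31)


def evaluate_grid(
    feature_table: pd.DataFrame,
    feature_cols: list[str],
    reducers: tuple[str, ...] = REDUCERS,
    classifiers: list[str] | None = None,
    scheme: CVScheme | None = None,
    seed: int = 0,
    scaling: str = "zscore",
    balancing: str = "smote",
    mode: str = "joint",
    positive_class: str = "ataxic",
    reducer_hyperparams: dict[str, dict] | None = None,
    classifier_hyperparams: dict[str, dict] | None = None,
) -> EvaluationMatrix:
    """Evaluate every (reducer, classifier) combination.

    Pipeline per cell: scale features, embed to 2-D, split, balance the
    training rows, train, pool test predictions over folds, compute
    accuracy/sensitivity/specificity.  In ``joint`` mode scaler and reducer
    are fitted on all rows before splitting (leaky but replicates the
    visual-embedding workflow; flagged in provenance); in ``strict`` mode
    they are fitted on training rows only.  Individual cell failures are
    recorded, never aborting the grid.
    """
    if mode not in ("joint", "strict"):
        raise ValueError("mode must be 'joint' or 'strict'")
    scheme = scheme or CVScheme(seed=seed)
    classifiers = classifiers if classifiers is not None else list(DEFAULT_CLASSIFIERS)
    reducer_hyperparams = reducer_hyperparams or {}
    classifier_hyperparams = classifier_hyperparams or {}

    X = feature_table[feature_cols].to_numpy(dtype=float)
    y = feature_table["label"].to_numpy()
    folds = split(feature_table, scheme)

    cells: list[CellResult] = []
    for reducer in reducers:
        joint_embedding = None
        if mode == "joint":
            scaled = fit_scaler(X, scaling)
            joint_embedding = reduce_features(
                scaled.matrix,
                reducer,
                seed=_cell_seed(seed, reducer, "_embed"),
                hyperparams=reducer_hyperparams.get(reducer),
            )
        for classifier in classifiers:
            cell_seed = _cell_seed(seed, reducer, classifier)
            truths: list[np.ndarray] = []
            preds: list[np.ndarray] = []
            try:
                for fold_i, (train_idx, test_idx) in enumerate(folds):
                    if mode == "joint":
                        emb_train = joint_embedding.coordinates[train_idx]
                        emb_test = joint_embedding.coordinates[test_idx]
                    else:
                        scaled = fit_scaler(X[train_idx], scaling)
                        fold_embedding = reduce_features(
                            scaled.matrix,
                            reducer,
                            seed=cell_seed + fold_i,
                            hyperparams=reducer_hyperparams.get(reducer),
                        )
                        emb_train = fold_embedding.coordinates
                        emb_test = transform_out_of_sample(
                            fold_embedding, scaled.transform(X[test_idx])
                        )
                    train_df = pd.DataFrame(emb_train, columns=["dim1", "dim2"])
                    train_df["label"] = y[train_idx]
                    balanced = balance(
                        train_df, balancing, seed=cell_seed + 7 * fold_i
                    ).table
                    X_bal = balanced[["dim1", "dim2"]].to_numpy(dtype=float)
                    y_bal = balanced["label"].to_numpy()
                    preds.append(
                        fit_predict(
                            classifier,
                            (X_bal, y_bal),
                            emb_test,
                            seed=cell_seed,
                            hyperparams=classifier_hyperparams.get(classifier),
                        )
                    )
                    truths.append(y[test_idx])
                truths_all = np.concatenate(truths)
                preds_all = np.concatenate(preds)
                metrics = confusion_metrics(truths_all, preds_all, positive_class)
                cells.append(
                    CellResult(reducer, classifier, truths_all, preds_all, metrics)
                )
            except Exception as err:  # flagged cell, grid continues
                cells.append(
                    CellResult(
                        reducer,
                        classifier,
                        np.empty(0),
                        np.empty(0),
                        ConfusionMetrics(0, 0, 0, 0, np.nan, np.nan, np.nan),
                        error=f"{type(err).__name__}: {err}",
                    )
                )
    provenance = {
        "scaling": scaling,
        "balancing": balancing,
        "mode": mode,
        "seed": seed,
        "scheme": scheme.kind,
        "n_rows": len(feature_table),
    }
    if mode == "joint":
        provenance["leakage_warning"] = (
            "embedding and scaling fitted on all segments before the split; "
            "test rows influenced the embedding (optimistic)"
        )
    return EvaluationMatrix(cells=cells, scheme=scheme, mode=mode, provenance=provenance)


def decision_surface(
    classifier,
    embedding_coords: np.ndarray,
    grid_resolution: int = 200,
    margin: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label a dense rectangular grid over the embedding's bounding box.

    Returns ``(xx, yy, labels)``: coordinate meshes of shape
    ``(grid_resolution, grid_resolution)`` and the classifier's label at
    each node.  Raises if the classifier is untrained.
    """
    coords = np.asarray(embedding_coords, dtype=float)
    if not hasattr(classifier, "classes_"):
        raise ValueError("classifier must be trained before plotting a surface")
    mins = coords.min(axis=0)
    maxs = coords.max(axis=0)
    span = maxs - mins
    lo = mins - margin * span
    hi = maxs + margin * span
    xx, yy = np.meshgrid(
        np.linspace(lo[0], hi[0], grid_resolution),
        np.linspace(lo[1], hi[1], grid_resolution),
    )
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    labels = np.asarray(classifier.predict(nodes)).reshape(xx.shape)
    return xx, yy, labels
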