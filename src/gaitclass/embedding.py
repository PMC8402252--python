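"""Dimensionality reduction of the six-feature space to 2-D.

Three reducers are compared: PCA (centred, not scaled, via SVD), t-SNE and
UMAP, all to exactly two components for visualisation and downstream 2-D
classification.

t-SNE has no native out-of-sample transform.  Two modes are therefore
provided for cross-validated evaluation:

* ``joint`` ("paper mode") — the embedding is fitted on *all* segments
  before the train/test split.  This mirrors how such visual-embedding
  studies are commonly run, but lets test rows influence the embedding;
  reports produced in this mode carry a leakage warning.
* ``strict`` — the reducer is fitted on training rows only; test rows are
  placed by the fitted transform (PCA, UMAP) or, for t-SNE, by a
  distance-weighted average of their 5 nearest training points'
  embedding coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

__all__ = ["REDUCERS", "EmbeddingResult", "reduce_features", "transform_out_of_sample"]

REDUCERS = ("PCA", "TSNE", "UMAP")

DEFAULT_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "PCA": {},
    "TSNE": {"perplexity": 30.0},
    "UMAP": {"n_neighbors": 15, "min_dist": 0.1},
}


@dataclass
class EmbeddingResult:
    """2-D coordinates plus the fitted model handle (when transformable)."""

    method: str
    coordinates: np.ndarray
    seed: int
    hyperparams: dict[str, Any]
    model: Any = None
    training_data: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("embedding coordinates must be (n, 2)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("embedding coordinates must be finite")
        self.coordinates = coords


def reduce_features(
    X: np.ndarray,
    method: str,
    seed: int,
    hyperparams: dict[str, Any] | None = None,
) -> EmbeddingResult:
    """Embed ``X`` (n x p) into 2-D with the named reducer, deterministically
    under ``seed``.  Requires at least 10 rows."""
    X = np.asarray(X, dtype=float)
    if method not in REDUCERS:
        raise ValueError(f"unknown reducer {method!r}; choose from {REDUCERS}")
    if X.ndim != 2 or len(X) < 10:
        raise ValueError("embedding requires a 2-D matrix with >= 10 rows")
    params = dict(DEFAULT_HYPERPARAMS[method])
    if hyperparams:
        params.update(hyperparams)

    if method == "PCA":
        model = PCA(n_components=2, svd_solver="full", random_state=seed, **params)
        coords = model.fit_transform(X)
    elif method == "TSNE":
        params["perplexity"] = min(params["perplexity"], (len(X) - 1) / 3)
        model = TSNE(
            n_components=2, random_state=seed, init="pca", **params
        )
        coords = model.fit_transform(X)
        model = None  # no out-of-sample transform; kNN placement used instead
    else:  # UMAP
        import umap  # deferred: numba-jitted import is slow

        model = umap.UMAP(n_components=2, random_state=seed, **params)
        with warnings.catch_warnings():
            # fixed random_state forces single-threaded layout; expected
            warnings.filterwarnings("ignore", message=".*n_jobs value.*random_state.*")
            coords = model.fit_transform(X)
    return EmbeddingResult(
        method=method,
        coordinates=np.asarray(coords, dtype=float),
        seed=seed,
        hyperparams=params,
        model=model,
        training_data=X.copy(),
    )


def transform_out_of_sample(
    result: EmbeddingResult, X_new: np.ndarray, k: int = 5
) -> np.ndarray:
    """Place new rows in a fitted embedding.

    PCA and UMAP use their native transforms.  t-SNE points are placed at
    the inverse-distance-weighted average of the embedding coordinates of
    their ``k`` nearest training rows (in feature space).
    """
    X_new = np.asarray(X_new, dtype=float)
    if result.model is not None:
        return np.asarray(result.model.transform(X_new), dtype=float)
    if result.training_data is None:
        raise ValueError("embedding lacks training data for kNN placement")
    k = min(k, len(result.training_data))
    nn = NearestNeighbors(n_neighbors=k).fit(result.training_data)
    distances, indices = nn.kneighbors(X_new)
    weights = 1.0 / (distances + 1e-12)
    weights /= weights.sum(axis=1, keepdims=True)
    return np.einsum("ij,ijk->ik", weights, result.coordinates[indices])
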