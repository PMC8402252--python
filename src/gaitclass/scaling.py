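"""Feature scaling: min-max rescaling, mean normalisation, z-score.

Each scaler is fitted on a matrix (training rows only when a split is
declared) and stores its per-feature parameters so the same affine map can
be applied to held-out data.  A zero-range/zero-SD feature cannot be
scaled; by convention that column is mapped to zeros and a warning is
emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCALING_METHODS",
    "ScaledFeatureMatrix",
    "fit_scaler",
    "rescale_minmax",
    "mean_normalize",
    "standardize",
    "scale_features",
]

SCALING_METHODS = ("rescale", "mean_norm", "zscore", "none")


@dataclass
class ScaledFeatureMatrix:
    """Scaled matrix plus the fitted per-feature parameters.

    ``transform`` applies the stored parameters to new rows (held-out
    data); ``matrix`` is the scaled training data itself.
    """

    matrix: np.ndarray
    scaling_method: str
    center: np.ndarray
    scale: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = (X - self.center) / self.scale
        out[:, self.degenerate] = 0.0
        return out


def fit_scaler(X: np.ndarray, method: str) -> ScaledFeatureMatrix:
    """Fit one of the scaling methods and return the scaled matrix.

    rescale:   (x - min) / (max - min), output in [0, 1]
    mean_norm: (x - mean) / (max - min), output mean 0
    zscore:    (x - mean) / sd, output mean 0 and sd 1 (population sd)
    none:      identity
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains NaN/Inf")
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}; choose from {SCALING_METHODS}")

    n_features = X.shape[1]
    if method == "none":
        return ScaledFeatureMatrix(
            matrix=X.copy(),
            scaling_method="none",
            center=np.zeros(n_features),
            scale=np.ones(n_features),
            degenerate=np.zeros(n_features, dtype=bool),
        )

    col_min, col_max = X.min(axis=0), X.max(axis=0)
    col_mean = X.mean(axis=0)
    if method == "rescale":
        center, scale = col_min, col_max - col_min
    elif method == "mean_norm":
        center, scale = col_mean, col_max - col_min
    else:  # zscore
        center, scale = col_mean, X.std(axis=0)

    degenerate = scale == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant feature column(s) set to zero "
            f"under {method} scaling",
            stacklevel=2,
        )
    safe_scale = np.where(degenerate, 1.0, scale)
    fitted = ScaledFeatureMatrix(
        matrix=np.empty(0),
        scaling_method=method,
        center=center,
        scale=safe_scale,
        degenerate=degenerate,
    )
    fitted.matrix = fitted.transform(X)
    return fitted


def rescale_minmax(X: np.ndarray) -> ScaledFeatureMatrix:
    return fit_scaler(X, "rescale")


def mean_normalize(X: np.ndarray) -> ScaledFeatureMatrix:
    return fit_scaler(X, "mean_norm")


def standardize(X: np.ndarray) -> ScaledFeatureMatrix:
    return fit_scaler(X, "zscore")


def scale_features(X: np.ndarray, method: str) -> ScaledFeatureMatrix:
    """Dispatch by method name (see :data:`SCALING_METHODS`)."""
    return fit_scaler(X, method)
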