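"""Class balancing of segment feature tables.

Four strategies equalise the two class counts before classifier training:
majority subsampling, minority oversampling (verbatim duplicates),
oversampling with Gaussian feature noise, and SMOTE (synthetic minority
rows interpolated between nearest minority neighbours).  Every output row
carries a provenance flag so synthetic rows are never mistaken for
measurements; balancing is meant for training folds only — the evaluation
pipeline asserts that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "BALANCING_METHODS",
    "BalancedFeatureMatrix",
    "subsample_majority",
    "oversample_minority",
    "oversample_noise",
    "smote",
    "balance",
]

BALANCING_METHODS = ("subsample", "oversample", "noise", "smote", "none")
PROVENANCE = "provenance"


@dataclass
class BalancedFeatureMatrix:
    """Balanced table with per-row provenance flags."""

    table: pd.DataFrame
    balancing_method: str

    def __post_init__(self) -> None:
        if PROVENANCE not in self.table.columns:
            raise ValueError("balanced table must carry a provenance column")

    def class_counts(self, label_col: str = "label") -> dict[str, int]:
        return self.table[label_col].value_counts().to_dict()


def _classes(table: pd.DataFrame, label_col: str) -> tuple[str, str, int, int]:
    counts = table[label_col].value_counts()
    if len(counts) != 2:
        raise ValueError(f"balancing requires exactly 2 classes, got {len(counts)}")
    minority, majority = counts.index[-1], counts.index[0]
    return minority, majority, int(counts.iloc[-1]), int(counts.iloc[0])


def _with_provenance(table: pd.DataFrame, flag: str = "original") -> pd.DataFrame:
    out = table.copy()
    out[PROVENANCE] = flag
    return out


def _feature_columns(table: pd.DataFrame, feature_cols: list[str] | None) -> list[str]:
    if feature_cols is not None:
        return feature_cols
    skip = {"participant_id", "label", "severity", PROVENANCE}
    return [c for c in table.columns if c not in skip and pd.api.types.is_numeric_dtype(table[c])]


def subsample_majority(
    table: pd.DataFrame, seed: int, label_col: str = "label"
) -> BalancedFeatureMatrix:
    """Sample the majority class without replacement down to minority size."""
    minority, majority, n_min, n_maj = _classes(table, label_col)
    out = _with_provenance(table)
    if n_min == n_maj:
        return BalancedFeatureMatrix(out.reset_index(drop=True), "subsample")
    rng = np.random.default_rng(seed)
    maj_rows = out[out[label_col] == majority]
    keep = rng.choice(maj_rows.index.to_numpy(), size=n_min, replace=False)
    result = pd.concat([out[out[label_col] == minority], out.loc[np.sort(keep)]])
    return BalancedFeatureMatrix(result.reset_index(drop=True), "subsample")


def oversample_minority(
    table: pd.DataFrame, seed: int, label_col: str = "label"
) -> BalancedFeatureMatrix:
    """Duplicate minority rows (with replacement) up to majority size."""
    minority, majority, n_min, n_maj = _classes(table, label_col)
    if n_min == 0:
        raise ValueError("minority class is empty")
    out = _with_provenance(table)
    if n_min == n_maj:
        return BalancedFeatureMatrix(out.reset_index(drop=True), "oversample")
    rng = np.random.default_rng(seed)
    min_rows = out[out[label_col] == minority]
    picks = rng.choice(min_rows.index.to_numpy(), size=n_maj - n_min, replace=True)
    dupes = out.loc[picks].copy()
    dupes[PROVENANCE] = "duplicated"
    result = pd.concat([out, dupes])
    return BalancedFeatureMatrix(result.reset_index(drop=True), "oversample")


def oversample_noise(
    table: pd.DataFrame,
    seed: int,
    noise_scale: float = 0.1,
    label_col: str = "label",
    feature_cols: list[str] | None = None,
) -> BalancedFeatureMatrix:
    """Oversample the minority and perturb the added rows with Gaussian
    noise of per-feature SD ``noise_scale * column SD``."""
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    base = oversample_minority(table, seed, label_col)
    out = base.table
    cols = _feature_columns(table, feature_cols)
    added = out[PROVENANCE] == "duplicated"
    if noise_scale > 0 and added.any():
        rng = np.random.default_rng(seed + 1)
        sd = table[cols].to_numpy(dtype=float).std(axis=0)
        noise = rng.normal(0.0, 1.0, size=(int(added.sum()), len(cols))) * (
            noise_scale * sd
        )
        out.loc[added, cols] = out.loc[added, cols].to_numpy(dtype=float) + noise
        out.loc[added, PROVENANCE] = "noise"
    return BalancedFeatureMatrix(out, "noise")


def smote(
    table: pd.DataFrame,
    seed: int,
    k_neighbors: int = 5,
    label_col: str = "label",
    feature_cols: list[str] | None = None,
) -> BalancedFeatureMatrix:
    """Synthetic minority oversampling: each synthetic row is
    ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``, ``x`` a random
    minority row and ``x_nn`` one of its ``k_neighbors`` nearest minority
    neighbours (Euclidean on the feature columns)."""
    minority, majority, n_min, n_maj = _classes(table, label_col)
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    out = _with_provenance(table)
    if n_min == n_maj:
        return BalancedFeatureMatrix(out.reset_index(drop=True), "smote")
    cols = _feature_columns(table, feature_cols)
    min_rows = out[out[label_col] == minority]
    X = min_rows[cols].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, neighbor_idx = nn.kneighbors(X)  # column 0 is the point itself

    rng = np.random.default_rng(seed)
    synth = []
    for _ in range(n_maj - n_min):
        i = int(rng.integers(n_min))
        j = int(neighbor_idx[i, 1 + rng.integers(k_neighbors)])
        u = rng.uniform()
        synth.append(X[i] + u * (X[j] - X[i]))
    synth_df = pd.DataFrame(synth, columns=cols)
    for col in out.columns:
        if col not in cols:
            if col == PROVENANCE:
                synth_df[col] = "smote"
            elif col == label_col:
                synth_df[col] = minority
            else:
                synth_df[col] = min_rows[col].iloc[0]
    synth_df = synth_df[out.columns]
    result = pd.concat([out, synth_df])
    return BalancedFeatureMatrix(result.reset_index(drop=True), "smote")


def balance(
    table: pd.DataFrame,
    method: str,
    seed: int,
    label_col: str = "label",
    **kwargs,
) -> BalancedFeatureMatrix:
    """Dispatch by method name (see :data:`BALANCING_METHODS`)."""
    if method == "none":
        return BalancedFeatureMatrix(
            _with_provenance(table).reset_index(drop=True), "none"
        )
    if method == "subsample":
        return subsample_majority(table, seed, label_col)
    if method == "oversample":
        return oversample_minority(table, seed, label_col)
    if method == "noise":
        return oversample_noise(table, seed, label_col=label_col, **kwargs)
    if method == "smote":
        return smote(table, seed, label_col=label_col, **kwargs)
    raise ValueError(f"unknown balancing method {method!r}; choose from {BALANCING_METHODS}")
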