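"""Confusion-matrix metrics, severity-separation statistics and report rendering.

Sensitivity is recall on the ataxic (positive) class, specificity recall on
the healthy class.  Reported accuracies are pooled over all test
predictions rather than averaged per fold, which is robust to the unequal
fold sizes of leave-one-group-out validation.

The severity report quantifies how well a 2-D embedding orders segments by
clinical severity: the rank correlation between severity and the
projection onto the embedding's severity-discriminant direction, and the
ratio of between- to within-severity-tertile mean pairwise distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMetrics",
    "SeverityReport",
    "confusion_metrics",
    "severity_report",
    "render_reports",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_metrics(truths, predictions, positive_class: str = "ataxic") -> ConfusionMetrics:
    """Counts and proportions of a binary confusion matrix.

    Raises on empty input; if the positive class is absent from the truths,
    sensitivity is undefined and signalled explicitly.
    """
    truths = np.asarray(truths)
    predictions = np.asarray(predictions)
    if len(truths) == 0:
        raise ValueError("cannot compute metrics on empty input")
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    pos_truth = truths == positive_class
    pos_pred = predictions == positive_class
    tp = int(np.sum(pos_truth & pos_pred))
    fn = int(np.sum(pos_truth & ~pos_pred))
    fp = int(np.sum(~pos_truth & pos_pred))
    tn = int(np.sum(~pos_truth & ~pos_pred))
    if tp + fn == 0:
        raise ValueError(
            f"positive class {positive_class!r} absent from truths: sensitivity undefined"
        )
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return ConfusionMetrics(tp, fp, tn, fn, accuracy, sensitivity, specificity)


@dataclass
class SeverityReport:
    """Severity-separation statistics of a 2-D embedding."""

    coordinates: np.ndarray
    severities: np.ndarray
    rank_correlation: float
    group_distance_ratio: float

    def to_dict(self) -> dict:
        return {
            "rank_correlation": self.rank_correlation,
            "group_distance_ratio": self.group_distance_ratio,
            "n": int(len(self.severities)),
        }


def _discriminant_projection(coords: np.ndarray, severities: np.ndarray) -> np.ndarray:
    """Project onto the direction that best predicts severity (least squares
    on standardized coordinates)."""
    Z = (coords - coords.mean(axis=0)) / np.where(
        coords.std(axis=0) == 0, 1.0, coords.std(axis=0)
    )
    target = severities - severities.mean()
    w, *_ = np.linalg.lstsq(Z, target, rcond=None)
    norm = np.linalg.norm(w)
    if norm == 0:
        return Z[:, 0]
    return Z @ (w / norm)


def severity_report(embedding_coords, severities) -> SeverityReport:
    """Quantify severity separation in a 2-D embedding.

    Rank correlation: Spearman's rho between per-segment severity and the
    projection onto the embedding's first discriminant direction.
    Group-distance ratio: mean pairwise distance between severity tertiles
    divided by the mean within-tertile distance (> 1 means graded groups
    occupy distinct regions).
    """
    coords = np.asarray(embedding_coords, dtype=float)
    severities = np.asarray(severities, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("embedding must be (n, 2)")
    if len(coords) != len(severities):
        raise ValueError("one severity per embedded segment required")
    if len(np.unique(severities)) < 3:
        raise ValueError("no severity variation: need >= 3 distinct severities")

    projection = _discriminant_projection(coords, severities)
    rho = float(stats.spearmanr(projection, severities).statistic)

    tertiles = np.quantile(severities, [1 / 3, 2 / 3])
    group = np.digitize(severities, tertiles)
    dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    same = group[:, None] == group[None, :]
    iu = np.triu_indices(len(coords), k=1)
    within = dists[iu][same[iu]]
    between = dists[iu][~same[iu]]
    if len(within) == 0 or len(between) == 0:
        raise ValueError("tertile grouping degenerate")
    ratio = float(between.mean() / within.mean())
    return SeverityReport(coords, severities, rho, ratio)


def render_reports(
    evaluation,
    severity: SeverityReport | None,
    out_dir: str | Path,
    embeddings: dict[str, np.ndarray] | None = None,
    embedding_meta: pd.DataFrame | None = None,
    surfaces: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    config_hash: str = "unconfigured",
) -> dict[str, Path]:
    """Write the tabular report bundle; byte-stable under a fixed seed.

    Emits one Name/Accuracy/Sensitivity/Specificity table per reducer, the
    classifier x reducer accuracy grid, per-reducer embedding scatter data,
    optional decision-surface grids, the severity statistics and a JSON run
    manifest carrying the config hash.  Raises (writing nothing) when the
    evaluation grid is empty.
    """
    if evaluation is None or not evaluation.cells:
        raise ValueError("cannot render reports from an empty evaluation matrix")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    written: dict[str, Path] = {}
    frame = evaluation.to_frame()
    float_fmt = "%.6f"

    for reducer in sorted(frame["reducer"].unique()):
        sub = frame[frame["reducer"] == reducer][
            ["classifier", "accuracy", "sensitivity", "specificity"]
        ].rename(columns={"classifier": "Name"})
        path = out_dir / f"metrics_{reducer}.csv"
        _write_csv(sub, path, config_hash, float_fmt)
        written[f"metrics_{reducer}"] = path

    grid = evaluation.accuracy_grid().reset_index()
    path = out_dir / "grid_accuracy.csv"
    _write_csv(grid, path, config_hash, float_fmt)
    written["grid_accuracy"] = path

    if embeddings:
        for method, coords in sorted(embeddings.items()):
            df = pd.DataFrame(coords, columns=["dim1", "dim2"])
            if embedding_meta is not None:
                df = pd.concat(
                    [embedding_meta.reset_index(drop=True), df], axis=1
                )
            path = out_dir / f"embedding_{method}.csv"
            _write_csv(df, path, config_hash, float_fmt)
            written[f"embedding_{method}"] = path

    if surfaces:
        for name, (xx, yy, labels) in sorted(surfaces.items()):
            df = pd.DataFrame(
                {
                    "x": xx.ravel(),
                    "y": yy.ravel(),
                    "label": np.asarray(labels).ravel(),
                }
            )
            safe = name.replace(" ", "_")
            path = out_dir / f"surface_{safe}.csv"
            _write_csv(df, path, config_hash, float_fmt)
            written[f"surface_{safe}"] = path

    manifest = {
        "config_hash": config_hash,
        "scheme": evaluation.scheme.kind,
        "mode": evaluation.mode,
        "provenance": evaluation.provenance,
        "mean_accuracy": evaluation.mean_accuracy(),
        "severity": severity.to_dict() if severity is not None else None,
        "files": {key: p.name for key, p in written.items()},
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["run_manifest"] = manifest_path
    return written


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, float_fmt: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format=float_fmt)
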