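"""End-to-end pipeline: simulate -> preprocess -> features -> scale/balance
-> reduce -> classify -> report.

Each stage is an importable function; :func:`run_pipeline` chains them under
one :class:`~gaitclass.config.RunConfig`, logging stage timings and row
counts, and emits a report bundle whose files carry the config hash.
Reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from .classification import CVScheme, decision_surface, evaluate_grid, make_classifier
from .config import RunConfig
from .embedding import reduce_features
from .evaluation import render_reports, severity_report
from .features import FEATURE_COLUMNS, features_table
from .io import write_cohort, write_features, write_segment_manifest
from .preprocess import (
    detect_foot_contacts,
    detect_turns,
    segment_straight_walks,
    subsample_to_60hz,
)
from .scaling import fit_scaler
from .synthetic import apply_severity, generate_cohort

logger = logging.getLogger("gaitclass")

__all__ = [
    "simulate_stage",
    "preprocess_stage",
    "features_stage",
    "evaluate_stage",
    "run_pipeline",
]


def simulate_stage(config: RunConfig):
    cohort = generate_cohort(
        n_healthy=config.cohort.n_healthy,
        n_ataxic=config.cohort.n_ataxic,
        severity_range=(config.cohort.severity_min, config.cohort.severity_max),
        base_params=config.gait_params(),
        effect_sizes=config.effects(),
        seed=config.seed,
    )
    logger.info("simulate: %d recordings", len(cohort))
    return cohort


def preprocess_stage(config: RunConfig, recordings):
    """Subsample, detect turns and contacts, cut straight segments."""
    pp = config.preprocess
    segments = []
    for recording in recordings:
        recording = subsample_to_60hz(recording)
        contacts = detect_foot_contacts(
            recording,
            contact_height_fraction=pp.contact_height_fraction,
            speed_threshold=pp.speed_threshold,
        )
        turns = detect_turns(
            recording,
            window_s=pp.window_s,
            heading_rate_threshold_deg_s=pp.heading_rate_threshold_deg_s,
        )
        segments.extend(
            segment_straight_walks(recording, turns, contacts, pp.min_contacts)
        )
    logger.info("preprocess: %d segments", len(segments))
    return segments


def features_stage(config: RunConfig, segments) -> pd.DataFrame:
    table = features_table(segments)
    logger.info("features: %d rows", len(table))
    return table


def evaluate_stage(config: RunConfig, feature_table: pd.DataFrame):
    scheme = CVScheme(kind=config.cv_scheme, seed=config.seed)
    evaluation = evaluate_grid(
        feature_table,
        FEATURE_COLUMNS,
        reducers=tuple(config.reducers),
        classifiers=config.classifiers,
        scheme=scheme,
        seed=config.seed,
        scaling=config.scaling,
        balancing=config.balancing,
        mode=config.leakage_mode,
        reducer_hyperparams=config.reducer_hyperparams,
        classifier_hyperparams=config.classifier_hyperparams,
    )
    logger.info("evaluate: %d cells, mean accuracy %.3f",
                len(evaluation.cells), evaluation.mean_accuracy())
    return evaluation


def run_pipeline(config: RunConfig, write_intermediate: bool = False) -> dict:
    """Execute the full flow and write the report bundle to config.out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    cohort = timed("simulate", simulate_stage, config)
    recordings = [rec for rec, _ in cohort]
    if write_intermediate:
        write_cohort(cohort, out_dir / "recordings")
    segments = timed("preprocess", preprocess_stage, config, recordings)
    if write_intermediate:
        write_segment_manifest(segments, out_dir / "segments.csv")
    table = timed("features", features_stage, config, segments)
    write_features(table, out_dir / "features.csv")
    evaluation = timed("evaluate", evaluate_stage, config, table)

    # embeddings for scatter reports + severity separation on the surface reducer
    scaled = fit_scaler(table[FEATURE_COLUMNS].to_numpy(float), config.scaling)
    embeddings = {}
    for method in config.reducers:
        embeddings[method] = reduce_features(
            scaled.matrix, method, seed=config.seed
        ).coordinates

    severity = None
    if table["severity"].nunique() >= 3 and config.surface_reducer in embeddings:
        severity = severity_report(
            embeddings[config.surface_reducer], table["severity"].to_numpy(float)
        )

    surfaces = {}
    surf_coords = embeddings.get(config.surface_reducer)
    if surf_coords is not None:
        for name in config.surface_classifiers:
            clf = make_classifier(name, config.seed)
            clf.fit(surf_coords, table["label"].to_numpy())
            surfaces[f"{config.surface_reducer}_{name}"] = decision_surface(
                clf, surf_coords, grid_resolution=100
            )

    meta = table[["participant_id", "label", "severity"]]
    written = timed(
        "report",
        lambda: render_reports(
            evaluation,
            severity,
            out_dir,
            embeddings=embeddings,
            embedding_meta=meta,
            surfaces=surfaces,
            config_hash=config.hash,
        ),
    )
    config.to_yaml(out_dir / "run_config.yaml")
    logger.info("pipeline timings: %s", timings)
    return {
        "config_hash": config.hash,
        "n_recordings": len(recordings),
        "n_segments": len(segments),
        "evaluation": evaluation,
        "severity": severity,
        "files": written,
        "timings": timings,
        "feature_table": table,
    }
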