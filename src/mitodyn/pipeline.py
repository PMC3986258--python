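"""End-to-end orchestration: movie → labels → events → features →
forest → traces, with all artifacts written to an output directory."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .classify import class_error_curve, importance_ranking, stump_boundary, train_forest
from .config import RunConfig
from .dynamics import pre_event_traces
from .events import classify_events, events_to_table
from .io import Movie, write_label_stack, write_manifest, write_tables
from .morphometry import feature_table
from .segmentation import segment_movie


def run_pipeline(movie: Movie, config: RunConfig | None = None, prefilter=None) -> dict:
    """Run segmentation, event detection and morphometry in memory."""
    config = config or RunConfig()
    labels, models = segment_movie(movie, config, prefilter)
    events, anomalies = classify_events(labels, config)
    features = feature_table(events, labels, movie, config)
    return {
        "labels": labels,
        "threshold_models": models,
        "events": events,
        "anomalies": anomalies,
        "features": features,
    }


def run_all(
    movie: Movie,
    out_dir: str | Path,
    config: RunConfig | None = None,
    min_training_rows: int = 50,
) -> dict:
    """Full pipeline with artifacts written to ``out_dir``.

    Always writes the labeled mask stack, ``threshold.json``,
    ``events.csv``, ``features.csv`` and ``manifest.json``.  When the
    feature table has at least ``min_training_rows`` rows and both
    classes, also trains the forest and writes ``importance.csv``,
    ``forest_summary.json``, ``stumps.csv`` and ``error_curve.csv``; when
    qualifying 1→2 / 2→1 events exist, writes ``traces.csv``.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_pipeline(movie, config)

    write_label_stack([lf.labels for lf in result["labels"]], out_dir / "labels.tif")
    thresholds = [
        {
            "frame": t,
            "mode_sqrt": m.mode_sqrt,
            "sigma_sqrt": m.sigma_sqrt,
            "lower_limit_sqrt": m.lower_limit_sqrt,
            "lower_limit_raw": m.lower_limit_raw,
        }
        for t, m in enumerate(result["threshold_models"])
    ]
    (out_dir / "threshold.json").write_text(json.dumps(thresholds, indent=2) + "\n")
    events_df = events_to_table(result["events"])
    write_tables(events_df, result["features"], out_dir)
    write_manifest(out_dir, config, config.random_seed)

    features = result["features"]
    trainable = (
        len(features) >= min_training_rows and features["call"].nunique() == 2
    )
    if trainable:
        model = train_forest(features, config)
        importance = importance_ranking(model)
        importance.to_csv(out_dir / "importance.csv", index=False)
        curve = class_error_curve(model)
        curve.to_csv(out_dir / "error_curve.csv", index=False)
        stumps = []
        for name in ("perimeter_um", "solidity"):
            try:
                b = stump_boundary(features[name].to_numpy(), features["call"].to_numpy(), name)
                stumps.append(dataclasses.asdict(b))
            except ValueError:
                pass
        pd.DataFrame(stumps).to_csv(out_dir / "stumps.csv", index=False)
        summary = {
            "oob_error": model.oob_error,
            "class_errors": model.class_errors,
            "n_trees": model.n_trees,
            "split_candidates": config.rf_split_candidates,
            "seed": config.random_seed,
            "n_rows": int(len(features)),
        }
        (out_dir / "forest_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        result["forest"] = model
        result["importance"] = importance

    try:
        traces = pre_event_traces(result["events"], result["labels"], config)
        traces.summary.to_csv(out_dir / "traces.csv", index=False)
        result["traces"] = traces
    except ValueError:
        pd.DataFrame(
            columns=["offset", "call", "mean_P_ratio", "se_P", "mean_S_ratio", "se_S", "n"]
        ).to_csv(out_dir / "traces.csv", index=False)
    return result
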