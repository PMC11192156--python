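"""End-to-end orchestration of the scan -> features -> forest workflow.

Thin, composable steps shared by the CLI and the test suite.  Every stage
is deterministic given the run configuration, and ``run_all`` writes a
manifest (config hash, seeds, package versions) next to its artifacts so a
run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
from dataclasses import asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifier import ForestConfig, TrainedForest, predict_species, save_model, train_forest
from .consensus import consensus_and_discrepancy, pair_replicates, species_counts
from .evaluation import evaluate
from .features import RESPONSE_COLUMN, assemble_table, split_train_test
from .morphometry import MEASUREMENT_COLUMNS, measure_scan
from .scanio import ScanImage, ScanMetadata, parse_tag, read_scan
from .segmentation import binarize, label_particles
from .synthgen import SimulationConfig, generate_dataset, write_dataset

__all__ = [
    "DEFAULT_CONFIG",
    "config_hash",
    "measure_image",
    "measure_directory",
    "consensus_from_calls",
    "run_all",
]

DEFAULT_CONFIG: Dict = {
    "dpi": 600.0,
    "polarity": "dark_on_light",
    "threshold": "none",  # binary scanner output; or "otsu" / "fixed:N"
    "min_area_mm2": 0.2,
    "train_fraction": 0.8,
    "split_seed": 0,
    "group_by_batch": False,
    "ntree": 500,
    "mtry": None,
    "forest_seed": 0,
    "ci_level": 0.95,
    "include_positional": True,
    "simulation": {"n_seeds": 600, "rng_seed": 0},
}


def validate_config(config: Dict) -> Dict:
    """Merge onto defaults; unknown keys are schema violations."""
    merged = {**DEFAULT_CONFIG, **(config or {})}
    unknown = sorted(set(merged) - set(DEFAULT_CONFIG))
    if unknown:
        raise KeyError(f"unknown config field(s): {unknown}")
    sim_unknown = sorted(
        set(merged.get("simulation") or {})
        - {
            "n_seeds", "rng_seed", "seeds_per_scan", "debris_rate",
            "dpi", "canvas_px",
        }
    )
    if sim_unknown:
        raise KeyError(f"unknown config field(s): simulation.{sim_unknown}")
    return merged


def config_hash(config: Dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _binarize_from_config(image: ScanImage, threshold: str) -> np.ndarray:
    if threshold.startswith("fixed:"):
        return binarize(image, "fixed", float(threshold.split(":", 1)[1]))
    return binarize(image, threshold)


def measure_image(
    image: ScanImage,
    threshold: str = "none",
    min_area_mm2: float = 0.2,
) -> pd.DataFrame:
    """Segment one scan and measure every surviving particle."""
    mask = _binarize_from_config(image, threshold)
    particles = label_particles(
        mask,
        min_area_mm2=min_area_mm2,
        pixel_size_mm=image.pixel_size_mm(),
        source_tag=image.source_tag,
    )
    records = measure_scan(particles, image)
    rows = [r.to_dict() for r in records]
    cols = MEASUREMENT_COLUMNS + ["tag"]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    # Skew/Kurt are None on binary scans; keep measurement columns float so
    # concatenation across scans stays dtype-stable
    df[MEASUREMENT_COLUMNS] = df[MEASUREMENT_COLUMNS].astype(float)
    return df


def measure_directory(
    scan_dir: str,
    threshold: str = "none",
    min_area_mm2: float = 0.2,
    dpi_override: Optional[float] = None,
    polarity: str = "dark_on_light",
) -> pd.DataFrame:
    """Measure every TIFF/PNG scan in a directory into one feature frame."""
    paths = sorted(
        p
        for pat in ("*.tif", "*.tiff", "*.png")
        for p in glob.glob(os.path.join(scan_dir, pat))
    )
    if not paths:
        raise FileNotFoundError(f"no scan files found in {scan_dir}")
    frames = []
    for path in paths:
        image = read_scan(path, dpi_override=dpi_override, polarity=polarity)
        df = measure_image(image, threshold, min_area_mm2)
        if not df.empty:
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS + ["tag"])
    return pd.concat(frames, ignore_index=True)


def consensus_from_calls(calls: pd.DataFrame, class_labels: Sequence[str]) -> pd.DataFrame:
    """Reconcile predicted per-seed calls into per-batch consensus rows.

    ``calls`` needs ``tag`` and ``predicted`` columns; batches and replicate
    indices come from parsing the tags.
    """
    metas = {tag: parse_tag(tag) for tag in calls["tag"].unique()}
    pairs, unpaired = pair_replicates(list(metas.values()))
    rows = []
    for m1, m2 in pairs:
        c1 = species_counts(
            calls.loc[calls["tag"] == m1.source_tag, "predicted"].tolist(), class_labels
        )
        c2 = species_counts(
            calls.loc[calls["tag"] == m2.source_tag, "predicted"].tolist(), class_labels
        )
        rep = consensus_and_discrepancy(c1, c2, batch_id=m1.batch_id)
        for s in class_labels:
            rows.append(
                {
                    "batch_id": rep.batch_id,
                    "species": s,
                    "count_rep1": rep.counts_rep1[s],
                    "count_rep2": rep.counts_rep2[s],
                    "consensus_mean": rep.consensus_counts[s],
                    "consensus_int": rep.consensus_integer[s],
                    "discrepancy_abs": rep.discrepancy_abs,
                    "discrepancy_rel": rep.discrepancy_rel,
                }
            )
    for m in unpaired:
        counts = species_counts(
            calls.loc[calls["tag"] == m.source_tag, "predicted"].tolist(), class_labels
        )
        for s in class_labels:
            rows.append(
                {
                    "batch_id": m.batch_id + "_unpaired",
                    "species": s,
                    "count_rep1": counts[s],
                    "count_rep2": np.nan,
                    "consensus_mean": counts[s],
                    "consensus_int": counts[s],
                    "discrepancy_abs": np.nan,
                    "discrepancy_rel": np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_all(config: Dict, out_dir: str) -> Dict:
    """simulate -> segment -> measure -> split -> train -> predict ->
    evaluate -> consensus; returns a summary dict and writes all artifacts
    plus ``manifest.json`` under ``out_dir``."""
    cfg = validate_config(config)
    os.makedirs(out_dir, exist_ok=True)
    data_dir = os.path.join(out_dir, "data")

    sim_kwargs = dict(cfg["simulation"] or {})
    if "canvas_px" in sim_kwargs:
        sim_kwargs["canvas_px"] = tuple(sim_kwargs["canvas_px"])
    if "seeds_per_scan" in sim_kwargs:
        sim_kwargs["seeds_per_scan"] = tuple(sim_kwargs["seeds_per_scan"])
    sim = SimulationConfig(dpi=cfg["dpi"], **sim_kwargs)
    dataset = generate_dataset(sim)
    write_dataset(dataset, data_dir)

    features = measure_directory(
        data_dir,
        threshold=cfg["threshold"],
        min_area_mm2=cfg["min_area_mm2"],
        polarity=cfg["polarity"],
    )
    features.to_csv(os.path.join(out_dir, "features.csv"), index=False)

    records_df = features
    from .morphometry import MeasurementRecord  # local to avoid cycle at import

    records = [
        MeasurementRecord(**{k: (None if pd.isna(v) else v) for k, v in row.items()})
        for row in records_df.to_dict(orient="records")
    ]
    table = assemble_table(records, include_positional=cfg["include_positional"])
    table.to_csv(os.path.join(out_dir, "table.csv"), index=False)

    train, test = split_train_test(
        table,
        train_fraction=cfg["train_fraction"],
        rng_seed=cfg["split_seed"],
        group_by_batch=cfg["group_by_batch"],
    )
    forest_cfg = ForestConfig(
        ntree=cfg["ntree"], mtry=cfg["mtry"], rng_seed=cfg["forest_seed"]
    )
    model = train_forest(train, forest_cfg)
    save_model(model, os.path.join(out_dir, "model.joblib"))

    calls_test = predict_species(model, test)
    calls_test = pd.concat(
        [test[["tag", RESPONSE_COLUMN]].reset_index(drop=True), calls_test.reset_index(drop=True)],
        axis=1,
    )
    calls_test.to_csv(os.path.join(out_dir, "calls_test.csv"), index=False)

    report = evaluate(
        calls_test[RESPONSE_COLUMN].tolist(),
        calls_test["predicted"].tolist(),
        model.class_labels,
        ci_level=cfg["ci_level"],
    )
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        fh.write(report.to_json())

    calls_all = predict_species(model, table)
    calls_all = pd.concat(
        [table[["tag"]].reset_index(drop=True), calls_all.reset_index(drop=True)], axis=1
    )
    calls_all.to_csv(os.path.join(out_dir, "calls_all.csv"), index=False)
    consensus = consensus_from_calls(calls_all, model.class_labels)
    consensus.to_csv(os.path.join(out_dir, "consensus.csv"), index=False)

    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seedscan_version": __version__,
        "artifacts": [
            "features.csv", "table.csv", "calls_test.csv", "calls_all.csv",
            "report.json", "consensus.csv", "model.joblib",
        ],
        "oob_error": model.oob_error,
        "test_accuracy": report.accuracy,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
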