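"""Run configuration and the end-to-end pipeline.

A RunConfig carries every tunable the method exposes: the neighborhood size
K = 20, the seven default distance measures, 3-fold cross-validation for the
grid search, elimination rates 0.1-0.4, t-SNE perplexity 30 and PCA target
dimension 30.  Configs serialize to a flat ``key = value`` text format, and
every artifact the pipeline writes embeds the config hash and seed for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import (cluster_integration, confidence_model, feature_extraction,
               io_preprocess, neighborhood)
from .distance_measures import SELECTED_MEASURES


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the method's standard values."""

    K: int = 20
    measures: Tuple[str, ...] = SELECTED_MEASURES
    cv_folds: int = 3
    rf_grid: Dict[str, list] = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in confidence_model.DEFAULT_GRID.items()})
    elimination_rates: Tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    perplexity: float = 30.0
    pca_dims: int = 30
    test_ratio: float = 0.2
    detection_cutoffs: Tuple[int, ...] = (100, 50, 10)
    algorithms: Tuple[str, ...] = ("kmeans", "dbscan")
    seed: int = 0

    def to_text(self) -> str:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, dict):
                value = json.dumps(value)
            elif isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        parsed = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "measures":
                parsed[key] = tuple(value.split(","))
            elif key == "algorithms":
                parsed[key] = tuple(value.split(","))
            elif key == "rf_grid":
                grid = json.loads(value)
                parsed[key] = {k: [None if v is None else v for v in vals]
                               for k, vals in grid.items()}
            elif key == "elimination_rates":
                parsed[key] = tuple(float(v) for v in value.split(","))
            elif key == "detection_cutoffs":
                parsed[key] = tuple(int(v) for v in value.split(","))
            elif key in ("perplexity", "test_ratio"):
                parsed[key] = float(value)
            elif key in ("K", "cv_folds", "pca_dims", "seed"):
                parsed[key] = int(value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**parsed)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())

    @property
    def hash(self) -> str:
        return hashlib.sha1(self.to_text().encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"embedconf config={config.hash} seed={config.seed}"


def run_pipeline(config: RunConfig, counts: io_preprocess.ExpressionMatrix,
                 labels, outdir, embedding: Optional[io_preprocess.Embedding] = None
                 ) -> Dict:
    """normalize -> embed -> ground truth -> features -> train/predict ->
    detect -> cluster, writing artifacts under ``outdir``.

    Any failing stage aborts with the stage name and cause, except that a
    single (algorithm, rate) clustering combination that cannot be tuned
    (e.g. DBSCAN finding no density knee) is recorded in the report as an
    error entry rather than discarding the rest of the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    stamp = _provenance(config)
    config.save(outdir / "config.txt")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    normalized = stage("normalize", lambda: io_preprocess.cpm_log_normalize(counts))
    if embedding is None:
        embedding = stage("embed", lambda: io_preprocess.tsne_embed(
            normalized, perplexity=config.perplexity, seed=config.seed))
    io_preprocess.write_embedding(embedding, outdir / "embedding.tsv",
                                  header_comment=stamp)

    def _ground_truth():
        idx = neighborhood.knn_index(embedding.coords, config.K)
        return neighborhood.ground_truth_confidence(idx, labels)

    def _stamped_csv(frame: pd.DataFrame, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {stamp}\n")
            frame.to_csv(fh, index=False)

    gt = stage("ground_truth", _ground_truth)
    _stamped_csv(pd.DataFrame({
        "cell_id": counts.cell_ids,
        "confidence": gt.scores,
        "erroneous": gt.erroneous,
    }), outdir / "ground_truth.csv")

    features = stage("features", lambda: feature_extraction.extract_features(
        normalized, embedding, measures=config.measures, K=config.K))

    split = io_preprocess.train_test_split(counts.n_cells, config.test_ratio,
                                           config.seed)

    def _train():
        return confidence_model.train(
            features.rows(split.train_indices), gt.scores[split.train_indices],
            cv_folds=config.cv_folds, grid=config.rf_grid, seed=config.seed,
            metadata={"config": config.hash})

    model = stage("train", _train)
    confidence_model.save_model(model, outdir / "model.joblib")
    scores = stage("predict", lambda: confidence_model.predict(model, features))
    _stamped_csv(pd.DataFrame({"cell_id": counts.cell_ids,
                               "confidence": scores}),
                 outdir / "predicted_scores.csv")

    cutoffs = [c for c in config.detection_cutoffs if c <= counts.n_cells]
    detection = stage("detect", lambda: confidence_model.evaluate_detection(
        scores, gt.erroneous, cutoffs=cutoffs))
    (outdir / "detection.json").write_text(json.dumps({
        "provenance": stamp,
        "cutoffs": detection.cutoffs,
        "detected": detection.detected,
        "total_erroneous": detection.total_erroneous,
    }, indent=2))

    pca_dims = min(config.pca_dims, min(normalized.values.shape))
    points = stage("pca", lambda: io_preprocess.pca_reduce(
        normalized, n_components=pca_dims, seed=config.seed))

    clustering: Dict[str, Dict] = {}
    for algorithm in config.algorithms:
        for rate in config.elimination_rates:
            key = f"{algorithm}_rate_{rate}"
            try:
                report = cluster_integration.run_confidence_clustering(
                    points, scores, labels, algorithm, rate, seed=config.seed)
                clustering[key] = {"conditions": report.conditions,
                                   "params": report.params}
            except (ValueError, RuntimeError) as exc:
                clustering[key] = {"error": str(exc)}
    (outdir / "clustering.json").write_text(json.dumps(
        {"provenance": stamp, "reports": clustering}, indent=2))

    return {
        "ground_truth": gt,
        "scores": scores,
        "detection": detection,
        "clustering": clustering,
        "split": split,
        "model": model,
    }
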