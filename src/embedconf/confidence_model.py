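"""Random-forest confidence regression and erroneous-sample detection.

The regressor learns the map from neighborhood distance features to the
label-consistency confidence target.  Hyperparameters are chosen by grid
search with k-fold cross-validation scored by mean squared error, then the
winner is refit on all training rows.  Detection performance is summarized
as the number of truly erroneous samples among the lowest-scored 100/50/10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold

from .feature_extraction import FeatureMatrix
from .neighborhood import rank_ascending

_FORMAT_VERSION = 1

#: Default hyperparameter grid; fully overridable at the call site.
DEFAULT_GRID: Dict[str, list] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 10, 20],
    "min_samples_leaf": [1, 5],
}


@dataclass
class TrainedModel:
    """A fitted confidence regressor plus the metadata needed to apply it."""

    estimator: RandomForestRegressor
    chosen_hyperparameters: Dict
    cv_folds: int
    feature_layout: List[str]
    metadata: Dict = field(default_factory=dict)


@dataclass
class DetectionReport:
    """Truly erroneous samples found among the lowest-scored c, per cutoff c."""

    cutoffs: List[int]
    detected: List[int]
    total_erroneous: int

    def as_dict(self) -> Dict[str, int]:
        out = {f"lowest_{c}": d for c, d in zip(self.cutoffs, self.detected)}
        out["total_erroneous"] = self.total_erroneous
        return out


def train(features: FeatureMatrix, targets, cv_folds: int = 3,
          grid: Optional[Dict[str, list]] = None, seed: int = 0,
          metadata: Optional[Dict] = None) -> TrainedModel:
    """Grid-searched RF regression of confidence targets on distance features."""
    targets = np.asarray(targets, dtype=float)
    n = features.values.shape[0]
    if targets.shape[0] != n:
        raise ValueError(f"{targets.shape[0]} targets for {n} feature rows")
    if np.any(targets < 0) or np.any(targets > 1):
        raise ValueError("targets must lie in [0, 1]")
    if n < cv_folds:
        raise ValueError(f"n={n} smaller than cv_folds={cv_folds}")
    grid = DEFAULT_GRID if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid is empty")
    search = GridSearchCV(
        RandomForestRegressor(random_state=seed),
        param_grid=grid,
        cv=KFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        scoring="neg_mean_squared_error",
        n_jobs=None,
        refit=True,
    )
    search.fit(features.values, targets)
    return TrainedModel(
        estimator=search.best_estimator_,
        chosen_hyperparameters=dict(search.best_params_),
        cv_folds=cv_folds,
        feature_layout=list(features.layout),
        metadata=dict(metadata or {}, seed=seed),
    )


def predict(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Predicted confidence scores, clipped to [0, 1]."""
    if list(features.layout) != model.feature_layout:
        for have, want in zip(features.layout, model.feature_layout):
            if have != want:
                raise ValueError(
                    f"feature layout mismatch at column {have!r} "
                    f"(model expects {want!r})"
                )
        raise ValueError(
            f"feature layout mismatch: {len(features.layout)} columns vs "
            f"{len(model.feature_layout)} expected"
        )
    return np.clip(model.estimator.predict(features.values), 0.0, 1.0)


def evaluate_detection(scores, erroneous,
                       cutoffs: Sequence[int] = (100, 50, 10)) -> DetectionReport:
    """Count true erroneous samples among the c lowest-scored, for each cutoff.

    Ties in the scores are resolved by sample index (stable ascending rank).
    """
    scores = np.asarray(scores, dtype=float)
    erroneous = np.asarray(erroneous, dtype=bool)
    if scores.shape[0] != erroneous.shape[0]:
        raise ValueError("scores and erroneous flags differ in length")
    n = scores.shape[0]
    for c in cutoffs:
        if c > n:
            raise ValueError(f"cutoff {c} exceeds n={n}")
    order = rank_ascending(scores)
    detected = [int(erroneous[order[:c]].sum()) for c in cutoffs]
    return DetectionReport(cutoffs=list(cutoffs), detected=detected,
                           total_erroneous=int(erroneous.sum()))


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "format_version": _FORMAT_VERSION,
            "estimator": model.estimator,
            "chosen_hyperparameters": model.chosen_hyperparameters,
            "cv_folds": model.cv_folds,
            "feature_layout": model.feature_layout,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt/truncated pickle
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an embedconf model file")
    if payload["format_version"] != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {_FORMAT_VERSION})"
        )
    return TrainedModel(
        estimator=payload["estimator"],
        chosen_hyperparameters=payload["chosen_hyperparameters"],
        cv_folds=payload["cv_folds"],
        feature_layout=payload["feature_layout"],
        metadata=payload["metadata"],
    )
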