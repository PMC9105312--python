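"""Cost-weighted AdaBoost tree ensemble, grid search and feature importance.

The detector is a boosted ensemble of depth-limited decision trees
(AdaBoost for binary classification).  Class imbalance and the asymmetric
operating cost of alarms are handled through a misclassification cost for
false positives: non-seizure samples enter boosting with weight ``fp_cost``
(>= 1), so mislabeling background as ictal is penalized ``fp_cost`` times
more than missing an ictal sample; the false-negative cost stays at 1.

The hyperparameter grid search scores each combination at the *event* level
on held-out folds and selects by: highest mean sensitivity, then lowest mean
false-positive count, then — for computational economy — higher learning
rate, then fewer weak learners.  That rule is a total order, so the winner
is unique.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .dataset import FEATURE_NAMES, FeatureGrid, NormalizationParams, zscore_apply

__all__ = [
    "GTBMParams",
    "ModelBundle",
    "train",
    "predict",
    "grid_search",
    "importance",
    "default_param_grid",
    "reduced_param_grid",
    "save_bundle",
    "load_bundle",
]

BUNDLE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GTBMParams:
    """Boosting hyperparameters; ``fp_cost`` is the false-positive
    misclassification cost multiplier (false negatives stay at cost 1)."""

    learning_rate: float = 0.1
    n_learners: int = 100
    max_depth: int = 2
    fp_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.n_learners <= 0 or self.max_depth <= 0:
            raise ValueError("learning_rate, n_learners and max_depth must be positive")
        if self.fp_cost < 1:
            raise ValueError("fp_cost must be >= 1")


@dataclass
class ModelBundle:
    """Trained ensemble plus the stored normalization and feature schema.

    Predictions on unstandardized data are impossible by construction: the
    bundle standardizes inputs itself with its stored parameters.
    """

    ensemble: AdaBoostClassifier
    params: GTBMParams
    norm: NormalizationParams
    feature_names: tuple[str, ...] = FEATURE_NAMES


def default_param_grid() -> list[GTBMParams]:
    """The 600-combination search space (5 x 4 x 5 x 6).

    A deliberately large factorial search; the specific grid values are this
    package's choice.
    """
    return [
        GTBMParams(lr, nl, md, fc)
        for lr, nl, md, fc in product(
            (0.05, 0.1, 0.2, 0.5, 1.0),
            (50, 100, 200, 500),
            (1, 2, 3, 5, 10),
            (1.0, 2.0, 5.0, 10.0, 20.0, 50.0),
        )
    ]


def reduced_param_grid() -> list[GTBMParams]:
    """Desk-scale 24-combination grid (2 x 2 x 2 x 3) for fast end-to-end runs."""
    return [
        GTBMParams(lr, nl, md, fc)
        for lr, nl, md, fc in product((0.1, 0.5), (50, 150), (1, 3), (1.0, 5.0, 20.0))
    ]


def train(
    X: np.ndarray,
    y: np.ndarray,
    params: GTBMParams,
    norm: NormalizationParams,
    seed: int = 0,
) -> ModelBundle:
    """Fit the cost-weighted AdaBoost ensemble on standardized training rows.

    ``X`` must already be standardized with ``norm`` (the harnesses do this);
    ``norm`` is stored in the bundle so prediction re-applies it.  The
    false-positive cost enters as initial observation weights: weight
    ``fp_cost`` on negatives, 1 on positives.
    """
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    weights = np.where(y == 0, params.fp_cost, 1.0)
    ensemble = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=params.max_depth, random_state=seed),
        n_estimators=params.n_learners,
        learning_rate=params.learning_rate,
        random_state=seed,
    )
    ensemble.fit(np.asarray(X, dtype=float), y, sample_weight=weights)
    return ModelBundle(ensemble=ensemble, params=params, norm=norm)


def predict(bundle: ModelBundle, grid: FeatureGrid | pd.DataFrame) -> np.ndarray:
    """Binary labels on the 2-s grid.

    Features are aligned by name (column order is irrelevant) and
    standardized with the bundle's stored parameters; rows with no valid
    feature at all are predicted 0.
    """
    if isinstance(grid, FeatureGrid):
        X_df, valid = grid.features, grid.valid
    else:
        X_df, valid = grid, None
    missing = set(bundle.feature_names) - set(X_df.columns)
    if missing:
        raise KeyError(f"feature columns missing: {sorted(missing)}")
    X = zscore_apply(bundle.norm, X_df, valid)
    out = bundle.ensemble.predict(X).astype(int)
    if valid is not None:
        none_valid = ~valid[list(bundle.feature_names)].to_numpy(dtype=bool).any(axis=1)
        out[none_valid] = 0
    return out


def grid_search(
    folds: Sequence,
    grid: Iterable[GTBMParams],
    eval_fn: Callable[[GTBMParams, object], tuple[float, float]],
    return_table: bool = True,
) -> tuple[GTBMParams, pd.DataFrame]:
    """Select hyperparameters by mean event-level fold scores.

    ``eval_fn(params, fold) -> (sensitivity, fp_count)`` trains and scores
    one combination on one fold.  Selection order: max mean sensitivity,
    min mean FP, max learning rate, min number of learners.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    if not folds:
        raise ValueError("grid search needs at least one fold")
    rows = []
    for params in grid:
        sens, fps = zip(*(eval_fn(params, fold) for fold in folds))
        rows.append(
            {
                **asdict(params),
                "mean_sensitivity": float(np.mean(sens)),
                "mean_fp": float(np.mean(fps)),
            }
        )
    table = pd.DataFrame(rows)
    best_i = max(
        range(len(grid)),
        key=lambda i: (
            rows[i]["mean_sensitivity"],
            -rows[i]["mean_fp"],
            grid[i].learning_rate,
            -grid[i].n_learners,
        ),
    )
    return grid[best_i], (table if return_table else pd.DataFrame())


def importance(bundles: ModelBundle | Sequence[ModelBundle]) -> pd.Series:
    """Gini impurity-decrease feature importances, averaged over trees.

    For a list of bundles (e.g. the models of all cross-validation folds of
    one participant) the scores are additionally averaged across bundles.
    Scores are nonnegative with a floor at 0.
    """
    if isinstance(bundles, ModelBundle):
        bundles = [bundles]
    mats = []
    for b in bundles:
        mats.append(np.maximum(b.ensemble.feature_importances_, 0.0))
    scores = np.mean(mats, axis=0)
    return pd.Series(scores, index=list(bundles[0].feature_names), name="importance")


# ---------------------------------------------------------------------------
# Persistence: versioned archive with an explicit feature schema; refuses to
# load on schema mismatch.


def save_bundle(path: str | Path, bundle: ModelBundle) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    schema = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "feature_names": list(bundle.feature_names),
        "params": asdict(bundle.params),
    }
    (path / "schema.json").write_text(json.dumps(schema, indent=2))
    joblib.dump(
        {"ensemble": bundle.ensemble, "norm": bundle.norm}, path / "model.joblib"
    )


def load_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    schema = json.loads((path / "schema.json").read_text())
    if schema.get("schema_version") != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"bundle schema version {schema.get('schema_version')} not supported"
        )
    if tuple(schema["feature_names"]) != tuple(FEATURE_NAMES):
        raise ValueError("bundle feature schema does not match this package's features")
    blobs = joblib.load(path / "model.joblib")
    return ModelBundle(
        ensemble=blobs["ensemble"],
        params=GTBMParams(**schema["params"]),
        norm=blobs["norm"],
        feature_names=tuple(schema["feature_names"]),
    )
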