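"""Gradient-boosted tree regression, cross-validation and feature selection.

The final predictor is a LightGBM regression ensemble run with library
default hyperparameters (single-threaded and seeded for determinism).
Recursive feature elimination is implemented as an explicit elimination
loop over the ensemble's split-gain importances, removing 10% of the
remaining features per round (clamped so every requested size on the path
is hit exactly); RFECV scores every size on the elimination path by k-fold
cross-validation and keeps the best, breaking ties toward fewer features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import lightgbm
import numpy as np
from lightgbm import LGBMRegressor
from sklearn.model_selection import KFold

from . import __version__ as _pkg_version
from .descriptors import FeatureMatrix
from .errors import DataError, FeatureError, ModelIOError
from .metrics import EvaluationReport, evaluate

logger = logging.getLogger(__name__)

#: Default number of retained features for the final model.
DEFAULT_FINAL_SIZE = 200

#: Default candidate sizes for the RFE per-size comparison ("all" = the
#: full feature count, appended at call time).
DEFAULT_TARGET_SIZES = (50, 100, 200, 300, 500, 1000, 2000, 3000)

#: Fraction of remaining features removed per elimination round.
RFE_STEP_FRACTION = 0.1

_ARTIFACT_FORMAT = 1


def _default_params(seed: int) -> dict:
    # library defaults, pinned single-thread + deterministic for
    # reproducible artifacts
    return {
        "random_state": seed,
        "n_jobs": 1,
        "deterministic": True,
        "force_row_wise": True,
        "verbose": -1,
    }


@dataclass
class TrainedStabilityModel:
    """A fitted ensemble plus the ordered feature contract it requires."""

    ensemble: LGBMRegressor
    selected_features: list[str]
    config: dict = field(default_factory=dict)
    descriptor_config_hash: str | None = None

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        return predict(self, X)


@dataclass
class SelectionResult:
    """Outcome of recursive feature elimination.

    ``ranked_features`` lists every feature, survivors first (ordered by
    final importance) followed by eliminated features in reverse
    elimination order, so ``ranked_features[:s]`` is the surviving set at
    any size ``s`` on the elimination path.
    """

    ranked_features: list[str]
    chosen_size: int
    per_size_scores: dict[int, EvaluationReport] = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        return self.ranked_features[: self.chosen_size]

    def scores_frame(self):
        import pandas as pd

        rows = {
            size: rep.to_dict() for size, rep in sorted(self.per_size_scores.items())
        }
        return pd.DataFrame(rows).T.rename_axis("n_features")


def _check_training_inputs(X: FeatureMatrix, y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.n_records:
        raise DataError(
            f"{X.n_records} feature rows but {y.shape[0]} target values"
        )
    if X.n_records < 10:
        raise DataError("training requires at least 10 rows")
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite target values")
    if not np.all(np.isfinite(X.values)):
        raise DataError("non-finite feature values")
    return y


def train(
    X: FeatureMatrix,
    y,
    params: dict | None = None,
    seed: int = 0,
    descriptor_config_hash: str | None = None,
) -> TrainedStabilityModel:
    """Fit a gradient-boosted regression ensemble on a feature matrix.

    Hyperparameters are the library defaults unless overridden in
    ``params``; the fit is deterministic for a fixed seed (single thread).
    """
    y = _check_training_inputs(X, y)
    merged = _default_params(seed)
    merged.update(params or {})
    est = LGBMRegressor(**merged)
    est.fit(X.values, y)
    return TrainedStabilityModel(
        ensemble=est,
        selected_features=list(X.feature_names),
        config={"params": merged, "seed": seed, "n_train": X.n_records},
        descriptor_config_hash=descriptor_config_hash,
    )


def predict(model: TrainedStabilityModel, X: FeatureMatrix) -> np.ndarray:
    """Predict Tm (°C) for each row; columns are aligned by name.

    Missing feature columns are an error listing the missing names; extra
    columns are ignored after explicit reordering to the model's contract.
    """
    index = set(X.feature_names)
    missing = [n for n in model.selected_features if n not in index]
    if missing:
        raise FeatureError(
            f"feature matrix is missing {len(missing)} model features: {missing[:10]}"
        )
    aligned = X.subset(model.selected_features)
    preds = model.ensemble.predict(aligned.values)
    return np.asarray(preds, dtype=float)


def kfold_cv(
    X: FeatureMatrix,
    y,
    k: int = 10,
    seed: int = 0,
    params: dict | None = None,
    with_classes: bool = False,
    return_predictions: bool = False,
):
    """k-fold cross-validation; metrics on the pooled out-of-fold predictions.

    Each record is predicted exactly once by a model that never saw it.
    """
    y = _check_training_inputs(X, y)
    if k < 2:
        raise DataError("k must be >= 2")
    if k > X.n_records:
        raise DataError(f"k={k} exceeds the number of records ({X.n_records})")
    oof = np.full(X.n_records, np.nan)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    merged = _default_params(seed)
    merged.update(params or {})
    for train_idx, test_idx in splitter.split(X.values):
        est = LGBMRegressor(**merged)
        est.fit(X.values[train_idx], y[train_idx])
        oof[test_idx] = est.predict(X.values[test_idx])
    assert np.all(np.isfinite(oof))
    report = evaluate(oof, y, with_classes=with_classes)
    if return_predictions:
        return report, oof
    return report


def _importances(X: FeatureMatrix, y: np.ndarray, seed: int, params: dict | None) -> np.ndarray:
    merged = _default_params(seed)
    merged.update(params or {})
    est = LGBMRegressor(**merged)
    est.fit(X.values, y)
    return np.asarray(est.feature_importances_, dtype=float)


def _elimination_path(
    X: FeatureMatrix,
    y: np.ndarray,
    sizes: list[int],
    seed: int,
    params: dict | None,
) -> list[str]:
    """Run recursive elimination down to min(sizes); return the full ranking.

    Each round refits the ensemble on the surviving features and drops the
    ``RFE_STEP_FRACTION`` least important (at least one), clamped so the
    path lands exactly on every requested size. Ties in importance are
    broken by original column order for determinism.
    """
    surviving = list(X.feature_names)
    eliminated: list[str] = []
    checkpoints = sorted(set(sizes), reverse=True)
    floor = checkpoints[-1]
    while len(surviving) > floor:
        sub = X.subset(surviving)
        imp = _importances(sub, y, seed, params)
        n_drop = max(1, int(RFE_STEP_FRACTION * len(surviving)))
        next_stop = max((s for s in checkpoints if s < len(surviving)), default=floor)
        n_drop = min(n_drop, len(surviving) - next_stop)
        # stable argsort: least important first, original order breaks ties
        order = np.argsort(imp, kind="stable")
        drop_idx = set(order[:n_drop].tolist())
        eliminated.extend(surviving[j] for j in sorted(drop_idx, key=lambda j: imp[j]))
        surviving = [f for j, f in enumerate(surviving) if j not in drop_idx]
    # order survivors by final importance, most important first
    sub = X.subset(surviving)
    imp = _importances(sub, y, seed, params)
    order = np.argsort(-imp, kind="stable")
    ranked = [surviving[j] for j in order] + eliminated[::-1]
    assert len(ranked) == X.n_features and len(set(ranked)) == X.n_features
    return ranked


def rfe_select(
    X: FeatureMatrix,
    y,
    target_sizes: list[int] | None = None,
    seed: int = 0,
    cv: int | None = 3,
    params: dict | None = None,
) -> SelectionResult:
    """Recursive feature elimination with per-size cross-validated scores.

    ``target_sizes`` defaults to {50, 100, 200, 300, 500, 1000, 2000, 3000,
    all}, restricted to the available feature count. With ``cv=None`` the
    elimination path is computed without scoring and the smallest requested
    size is chosen (used for a fixed stop criterion). Otherwise the chosen
    size is the one with the best cross-validated PCC, ties broken toward
    the smaller size.
    """
    y = _check_training_inputs(X, y)
    p = X.n_features
    if target_sizes is None:
        sizes = sorted({s for s in DEFAULT_TARGET_SIZES if s < p} | {p})
    else:
        if not target_sizes:
            raise DataError("target_sizes must not be empty")
        if max(target_sizes) > p:
            raise DataError(
                f"requested size {max(target_sizes)} exceeds feature count {p}"
            )
        sizes = sorted(set(target_sizes))
    ranked = _elimination_path(X, y, sizes, seed, params)
    per_size: dict[int, EvaluationReport] = {}
    if cv is not None:
        for s in sizes:
            per_size[s] = kfold_cv(X.subset(ranked[:s]), y, k=cv, seed=seed, params=params)
        chosen = _best_size(per_size)
    else:
        chosen = sizes[0]
    logger.info("RFE chose %d features from sizes %s", chosen, sizes)
    return SelectionResult(ranked, chosen, per_size)


def select_final(
    X: FeatureMatrix,
    y,
    n_features: int = DEFAULT_FINAL_SIZE,
    seed: int = 0,
    params: dict | None = None,
) -> SelectionResult:
    """RFE to the default final-model stop criterion (a fixed feature count)."""
    n_features = min(n_features, X.n_features)
    return rfe_select(X, y, target_sizes=[n_features], seed=seed, cv=None, params=params)


def _best_size(per_size: dict[int, EvaluationReport]) -> int:
    # best CV PCC; smaller size wins ties
    return min(per_size, key=lambda s: (-per_size[s].pcc, s))


def rfecv_select(
    X: FeatureMatrix,
    y,
    cv: int = 3,
    seed: int = 0,
    min_size: int = 1,
    params: dict | None = None,
) -> SelectionResult:
    """RFE inside a cross-validation loop to find the optimal feature count.

    Every size on the 10%-step elimination path (plus the full set) is
    scored with ``cv``-fold cross-validation; the best PCC wins, ties
    toward the smaller size. Default ``cv`` is 3.
    """
    y = _check_training_inputs(X, y)
    if cv < 2:
        raise DataError("cv must be >= 2")
    # path sizes from p down to min_size with 10% steps
    sizes = []
    s = X.n_features
    while s > min_size:
        sizes.append(s)
        s -= max(1, int(RFE_STEP_FRACTION * s))
    sizes.append(max(s, min_size))
    sizes = sorted(set(sizes))
    ranked = _elimination_path(X, y, sizes, seed, params)
    per_size = {
        s: kfold_cv(X.subset(ranked[:s]), y, k=cv, seed=seed, params=params)
        for s in sizes
    }
    chosen = _best_size(per_size)
    logger.info("RFECV chose %d features (cv=%d)", chosen, cv)
    return SelectionResult(ranked, chosen, per_size)


# ---------------------------------------------------------------------------
# Baseline algorithm bake-off
# ---------------------------------------------------------------------------

def _baseline_estimators(seed: int) -> dict:
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.svm import LinearSVR
    from sklearn.tree import DecisionTreeRegressor

    estimators = {
        "decision_tree": lambda: DecisionTreeRegressor(random_state=seed),
        "random_forest": lambda: RandomForestRegressor(random_state=seed, n_jobs=1),
        "linear_svr": lambda: LinearSVR(random_state=seed),
        "gbrt": lambda: GradientBoostingRegressor(random_state=seed),
        "lightgbm": lambda: LGBMRegressor(**_default_params(seed)),
        "mlp": lambda: MLPRegressor(
            hidden_layer_sizes=(20, 20, 20),
            activation="relu",
            solver="lbfgs",
            random_state=seed,
            max_iter=500,
        ),
    }
    try:  # optional extra; not a runtime dependency
        from xgboost import XGBRegressor

        estimators["xgboost"] = lambda: XGBRegressor(random_state=seed, n_jobs=1)
    except ImportError:  # pragma: no cover
        pass
    return estimators


def baseline_regressors(
    X: FeatureMatrix,
    y,
    algorithms: list[str] | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Cross-validate baseline algorithms on identical folds.

    Available names: decision_tree, random_forest, linear_svr, gbrt,
    lightgbm, mlp and (when installed) xgboost — each with library default
    hyperparameters (the MLP uses three hidden layers of 20 ReLU units and
    LBFGS).
    """
    y = _check_training_inputs(X, y)
    available = _baseline_estimators(seed)
    algorithms = algorithms or list(available)
    unknown = [a for a in algorithms if a not in available]
    if unknown:
        raise DataError(f"unknown algorithms: {unknown}; choose from {sorted(available)}")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X.values))
    reports: dict[str, EvaluationReport] = {}
    for name in algorithms:
        oof = np.full(X.n_records, np.nan)
        for train_idx, test_idx in folds:
            est = available[name]()
            est.fit(X.values[train_idx], y[train_idx])
            oof[test_idx] = est.predict(X.values[test_idx])
        reports[name] = evaluate(oof, y)
        logger.info("baseline %s: %s", name, reports[name])
    return reports


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedStabilityModel, path: str | Path) -> None:
    """Persist a model as a single-file bundle with version metadata."""
    payload = {
        "format": _ARTIFACT_FORMAT,
        "package_version": _pkg_version,
        "lightgbm_version": lightgbm.__version__,
        "ensemble": model.ensemble,
        "selected_features": model.selected_features,
        "config": model.config,
        "descriptor_config_hash": model.descriptor_config_hash,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedStabilityModel:
    """Load a model bundle; predictions round-trip bit-identically."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"could not read model artifact {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _ARTIFACT_FORMAT:
        raise ModelIOError(f"{path} is not a recognized model artifact")
    saved = payload.get("lightgbm_version")
    if saved is not None and saved.split(".")[0] != lightgbm.__version__.split(".")[0]:
        raise ModelIOError(
            f"artifact was written with lightgbm {saved}, "
            f"incompatible with installed {lightgbm.__version__}"
        )
    return TrainedStabilityModel(
        ensemble=payload["ensemble"],
        selected_features=list(payload["selected_features"]),
        config=dict(payload.get("config", {})),
        descriptor_config_hash=payload.get("descriptor_config_hash"),
    )
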