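"""Uniform adapter over the five-classifier suite (KNN, DT, RF, GB, XGB).

The backing implementations come from scikit-learn and xgboost; the adapter
pins the shared contract the rest of the pipeline relies on: label-preserving
fit/predict, probability rows summing to one with argmax equal to the
predicted label, column-name checking at prediction time, and determinism
under a fixed seed.  Hyperparameter tuning is an exhaustive grid search with
stratified inner cross-validation, run inside the outer training fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import ConfigError, FitError, SchemaError

MODEL_NAMES = ("KNN", "DT", "RF", "GB", "XGB")

#: modest default grids; `None` values mean "library default"
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "KNN": {"n_neighbors": [3, 5, 7, 11]},
    "DT": {"max_depth": [3, 5, 10, None]},
    "RF": {"n_estimators": [100, 300], "max_features": ["sqrt", None]},
    "GB": {"learning_rate": [0.05, 0.1, 0.3], "n_estimators": [100, 300],
           "max_depth": [2, 3, 5]},
    "XGB": {"learning_rate": [0.05, 0.1, 0.3], "n_estimators": [100, 300],
            "max_depth": [2, 3, 5], "reg_lambda": [0, 1]},
}


@dataclass
class ClassifierSpec:
    name: str
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ConfigError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")


def build_estimator(spec: ClassifierSpec):
    p = dict(spec.params)
    if spec.name == "KNN":
        # instance-based: Euclidean distance on standardized features
        knn = KNeighborsClassifier(**{"n_neighbors": 5, **p})
        return Pipeline([("scale", StandardScaler()), ("knn", knn)])
    if spec.name == "DT":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=spec.seed,
                                      n_jobs=1, **p)
    if spec.name == "GB":
        return GradientBoostingClassifier(random_state=spec.seed, **p)
    return XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0,
                         eval_metric="logloss", **p)


def _validate_params(spec: ClassifierSpec, params: dict) -> None:
    if spec.name == "KNN":
        known = KNeighborsClassifier().get_params()
    else:
        known = build_estimator(ClassifierSpec(name=spec.name, seed=spec.seed)).get_params()
    bad = [k for k in params if k not in known]
    if bad:
        raise ConfigError(f"{spec.name}: unknown hyperparameters {bad}")


@dataclass
class FittedModel:
    spec: ClassifierSpec
    estimator: object
    encoder: LabelEncoder
    feature_names: list

    @property
    def classes(self) -> np.ndarray:
        return self.encoder.classes_


def fit(spec: ClassifierSpec, X: pd.DataFrame, y) -> FittedModel:
    """Train one suite member on the given rows only."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise FitError("training data contains a single class")
    _validate_params(spec, spec.params)
    enc = LabelEncoder().fit(y)
    est = build_estimator(spec)
    est.fit(X.to_numpy(), enc.transform(y))
    return FittedModel(spec=spec, estimator=est, encoder=enc,
                       feature_names=list(X.columns))


def _check_columns(model: FittedModel, X: pd.DataFrame) -> None:
    if list(X.columns) != model.feature_names:
        raise SchemaError(
            f"prediction columns {list(X.columns)} != fitted columns "
            f"{model.feature_names}")


def predict_proba(model: FittedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Class posteriors with columns ordered by the model's label set."""
    _check_columns(model, X)
    proba = model.estimator.predict_proba(X.to_numpy())
    return pd.DataFrame(proba, columns=model.classes, index=X.index)


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted labels = argmax of the posterior (exact adapter contract)."""
    proba = predict_proba(model, X)
    return proba.columns.to_numpy()[np.argmax(proba.to_numpy(), axis=1)]


def grid_search(spec: ClassifierSpec, X: pd.DataFrame, y,
                inner_folds: int = 5, seed: Optional[int] = None) -> ClassifierSpec:
    """Exhaustive grid search by stratified inner CV on mean accuracy.

    Candidates are enumerated in the documented grid order (first key varies
    slowest); ties keep the first candidate.  Grid values are validated
    against the backend before any fitting.
    """
    grid = spec.grid or DEFAULT_GRIDS[spec.name]
    seed = spec.seed if seed is None else seed
    keys = list(grid.keys())
    candidates = [dict(zip(keys, combo))
                  for combo in itertools.product(*(grid[k] for k in keys))]
    for cand in candidates:
        _validate_params(spec, cand)
    if len(candidates) == 1:
        return ClassifierSpec(name=spec.name, params=candidates[0], grid=grid, seed=seed)

    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best_score, best_params = -np.inf, None
    for cand in candidates:
        scores = []
        for tr, te in cv.split(X, y):
            model = fit(ClassifierSpec(name=spec.name, params=cand, seed=seed),
                        X.iloc[tr], y[tr])
            scores.append(float(np.mean(predict(model, X.iloc[te]) == y[te])))
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, cand
    return ClassifierSpec(name=spec.name, params=best_params, grid=grid, seed=seed)
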