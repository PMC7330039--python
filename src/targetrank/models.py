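"""Classifier families, cross-validated tuning and per-replicate training.

Five methods are benchmarked: random forest, logistic regression, support
vector machine (with cross-validated sigmoid probability calibration),
gradient boosting machine and a small neural network (dropout 0.5, batch
normalization).  Hyperparameters are tuned by stratified 5-fold
cross-validation on the training split only, maximising AUROC; grids are
ordered simplest-first and ties keep the earliest grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datasets import LabeledDataset
from .nn import DropoutMLPClassifier

__all__ = ["METHODS", "ModelConfig", "TrainedModel", "default_grid",
           "fast_grid", "make_estimator", "tune", "fit", "train_all",
           "restrict_features"]

METHODS = ("random_forest", "logistic_regression", "svm", "gbm", "neural_net")


def default_grid(method: str) -> list[dict]:
    """Hyperparameter search spaces (simplest configuration first)."""
    if method == "random_forest":
        return [{"n_estimators": n, "max_depth": d, "max_features": f}
                for n in (100, 300, 500) for d in (3, 5, None)
                for f in ("sqrt", None)]
    if method == "logistic_regression":
        return [{}]                      # no tuning required
    if method == "svm":
        grid = [{"kernel": "linear", "C": c} for c in (0.1, 1.0, 10.0)]
        grid += [{"kernel": "rbf", "C": c, "gamma_scale": g}
                 for c in (0.1, 1.0, 10.0) for g in (0.5, 1.0, 2.0)]
        return grid
    if method == "gbm":
        return [{"learning_rate": lr, "n_estimators": n, "max_depth": d}
                for lr in (0.01, 0.1) for n in (100, 300) for d in (2, 3)]
    if method == "neural_net":
        return [{"lr": 0.003}, {"lr": 0.01}]
    raise ValueError(f"unknown method {method!r}")


def fast_grid(method: str) -> list[dict]:
    """Single sensible configuration per method (no search)."""
    return {
        "random_forest": [{"n_estimators": 300, "max_depth": None,
                           "max_features": "sqrt"}],
        "logistic_regression": [{}],
        "svm": [{"kernel": "rbf", "C": 1.0, "gamma_scale": 1.0}],
        "gbm": [{"learning_rate": 0.1, "n_estimators": 100, "max_depth": 3}],
        "neural_net": [{"lr": 0.01}],
    }[_check_method(method)]


def _check_method(method: str) -> str:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return method


@dataclass(frozen=True)
class ModelConfig:
    method: str
    grid: tuple = None            # None -> default_grid(method)
    cv_folds: int = 5
    seed: int = 0

    def points(self) -> list[dict]:
        if self.grid is None:
            return default_grid(self.method)
        pts = [dict(p) for p in self.grid]
        if not pts:
            if self.method == "logistic_regression":
                return [{}]
            raise ValueError(f"empty grid for tunable method {self.method!r}")
        return pts


def make_estimator(method: str, params: dict, seed: int = 0):
    """Instantiate one classifier; scale-sensitive methods get a scaler."""
    _check_method(method)
    params = dict(params)
    if method == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if method == "logistic_regression":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(max_iter=2000,
                                                    random_state=seed, **params))])
    if method == "svm":
        gamma_scale = params.pop("gamma_scale", None)
        if gamma_scale is None:
            svc = SVC(random_state=seed, gamma="scale", **params)
        else:
            # multiple of the 1/(n_features * X.var()) heuristic, resolved
            # at fit time by a tiny wrapper
            svc = _ScaledGammaSVC(random_state=seed, gamma_scale=gamma_scale,
                                  **params)
        # ranking needs probabilities: cross-validated sigmoid calibration
        cal = CalibratedClassifierCV(svc, method="sigmoid", cv=3,
                                     ensemble=False)
        return Pipeline([("scale", StandardScaler()), ("clf", cal)])
    if method == "gbm":
        return GradientBoostingClassifier(random_state=seed, **params)
    if method == "neural_net":
        return DropoutMLPClassifier(random_state=seed, **params)
    raise AssertionError


class _ScaledGammaSVC(SVC):
    """SVC whose RBF bandwidth is a multiple of the "scale" heuristic."""

    def __init__(self, gamma_scale=1.0, C=1.0, kernel="rbf", random_state=0):
        super().__init__(C=C, kernel=kernel, random_state=random_state)
        self.gamma_scale = gamma_scale

    def fit(self, X, y, **kw):
        X = np.asarray(X)
        var = X.var()
        self.gamma = self.gamma_scale / (X.shape[1] * var) if var > 0 else "scale"
        return super().fit(X, y, **kw)


@dataclass
class TrainedModel:
    method: str
    params: dict
    estimator: object
    feature_names: list[str]
    negative_set_index: int
    seed: int

    def predict_probability(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.feature_names].to_numpy()
        proba = self.estimator.predict_proba(x)
        pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0]) \
            if hasattr(self.estimator, "classes_") else 1
        if isinstance(self.estimator, Pipeline):
            pos_col = int(np.flatnonzero(
                self.estimator[-1].classes_ == 1)[0])
        return proba[:, pos_col]


def restrict_features(ds: LabeledDataset, columns) -> LabeledDataset:
    columns = list(columns)
    missing = [c for c in columns if c not in ds.feature_columns]
    if missing:
        raise ValueError(f"dataset lacks features {missing}")
    return LabeledDataset(ds.frame, ds.negative_set_index, columns)


def tune(train: LabeledDataset, config: ModelConfig) -> tuple[dict, pd.DataFrame]:
    """Grid search by stratified k-fold CV AUROC on the training split.

    Returns the winning parameter dict and the CV table (one row per grid
    point with its mean AUROC).  A one-point grid is returned directly
    without cross-validation.
    """
    points = config.points()
    if len(points) == 1:
        return points[0], pd.DataFrame({"params": [points[0]],
                                        "mean_auroc": [np.nan]})
    x, y = train.part("train")
    xa = x.to_numpy()
    n_min = config.cv_folds * 2
    if len(y) < n_min:
        raise ValueError(f"need >= {n_min} training rows for "
                         f"{config.cv_folds}-fold CV, got {len(y)}")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    folds = list(skf.split(xa, y))
    scores = []
    for params in points:
        fold_scores = []
        for tr, va in folds:
            est = make_estimator(config.method, params, config.seed)
            est.fit(xa[tr], y[tr])
            p = est.predict_proba(xa[va])[:, 1]
            fold_scores.append(roc_auc_score(y[va], p))
        scores.append(float(np.mean(fold_scores)))
    best = int(np.argmax(scores))      # first max wins -> simplest-first
    table = pd.DataFrame({"params": points, "mean_auroc": scores})
    return points[best], table


def fit(train: LabeledDataset, method: str, params: dict,
        seed: int = 0) -> TrainedModel:
    """Fit one classifier on the training split of one replicate."""
    x, y = train.part("train")
    if len(np.unique(y)) < 2:
        raise ValueError("training split is single-class")
    est = make_estimator(method, params, seed)
    est.fit(x.to_numpy(), y)
    return TrainedModel(method, dict(params), est, list(train.feature_columns),
                        train.negative_set_index, seed)


def train_all(datasets: list[LabeledDataset], selected_features=None,
              methods=METHODS, grids: dict | None = None, cv_folds: int = 5,
              seed: int = 0) -> dict[str, list[TrainedModel]]:
    """Tune and fit every method on every negative-set replicate.

    ``selected_features`` restricts the columns models see (None keeps all
    dataset features).  ``grids`` maps method -> explicit grid.  Returns a
    method -> list-of-TrainedModel mapping, models ordered by negative-set
    index; the tuned parameters ride along on each TrainedModel.
    """
    out: dict[str, list[TrainedModel]] = {}
    for method in methods:
        _check_method(method)
        models = []
        for ds in datasets:
            ds_m = restrict_features(ds, selected_features) \
                if selected_features is not None else ds
            sub = int(np.random.SeedSequence(
                seed, spawn_key=(401, ds.negative_set_index,
                                 METHODS.index(method))).generate_state(1)[0]
                % (2 ** 31))
            grid = None if grids is None else tuple(grids[method])
            cfg = ModelConfig(method, grid=grid, cv_folds=cv_folds, seed=sub)
            best, _ = tune(ds_m, cfg)
            models.append(fit(ds_m, method, best, sub))
        out[method] = models
    return out
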