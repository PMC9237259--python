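"""Multi-model prediction of motor behavior from hub activity and TH levels.

Five regressors are fitted on the same features: a Gaussian-identity linear
model on standardized features (GLM), extra trees (ET), random forest (RF),
gradient boosting (GBM), and extreme gradient boosting (XGB). The protocol
is one seeded 0.75:0.25 train/test split, 5-fold cross-validation inside the
training portion, held-out R-squared and RMSE, and per-feature importances
(absolute standardized coefficients for the linear model, impurity-based
importances for the tree ensembles).

Importances are reported on two scales that are both used in practice and
easy to conflate: the L1-normalized *proportion* (sums to 1) and the
max-normalized *relative* importance (largest feature = 1). RMSE across
models can likewise be L1-normalized for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .core import CohortMatrix, ValidationError

__all__ = [
    "ALGORITHMS",
    "DEFAULT_HUB_FEATURES",
    "FeatureSpec",
    "ModelFit",
    "ModelReport",
    "fit_predictors",
    "normalize_importance",
    "normalize_rmse",
    "rank_models",
]

ALGORITHMS = ("GLM", "ET", "RF", "GBM", "XGB")

#: Default features: c-Fos activity of the eight acupuncture-responsive hub
#: regions plus nigral and striatal tyrosine-hydroxylase measures.
DEFAULT_HUB_FEATURES = ("M1", "DG", "Cg1", "CA3", "VL", "PHA", "VTA", "LC",
                        "th_sn", "th_st")


@dataclass
class FeatureSpec:
    """Feature columns and the regression target (default rotarod latency)."""

    features: list[str] = field(
        default_factory=lambda: list(DEFAULT_HUB_FEATURES)
    )
    target: str = "rotarod_s"

    def __post_init__(self) -> None:
        if len(self.features) < 2:
            raise ValidationError("need at least two features")
        if self.target in self.features:
            raise ValidationError("target must not be among the features")


@dataclass
class ModelFit:
    """Metrics and importances for one fitted algorithm."""

    name: str
    r2: float
    rmse: float
    cv_scores: list[float]
    importance_raw: dict[str, float]
    importance_proportion: dict[str, float]
    importance_relative: dict[str, float]


@dataclass
class ModelReport:
    """Per-algorithm fits plus the shared protocol settings."""

    models: dict[str, ModelFit]
    features: list[str]
    target: str
    split: float
    cv_folds: int
    seed: int
    n_train: int
    n_test: int

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m.name, "r2": m.r2, "rmse": m.rmse,
             "cv_mean_r2": float(np.mean(m.cv_scores))}
            for m in self.models.values()
        ]
        return pd.DataFrame(rows).set_index("model")

    def importance_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models.values():
            for feat in self.models[m.name].importance_raw:
                rows.append({
                    "model": m.name, "feature": feat,
                    "importance_raw": m.importance_raw[feat],
                    "proportion": m.importance_proportion[feat],
                    "relative": m.importance_relative[feat],
                })
        return pd.DataFrame(rows)


def _make_estimator(name: str, seed: int):
    # fixed, documented hyperparameters: reproducibility over tuning
    if name == "GLM":
        return Pipeline([
            ("scale", StandardScaler()),
            ("ols", LinearRegression()),
        ])
    if name == "ET":
        return ExtraTreesRegressor(n_estimators=200, random_state=seed)
    if name == "RF":
        return RandomForestRegressor(n_estimators=200, random_state=seed)
    if name == "GBM":
        return GradientBoostingRegressor(n_estimators=200, random_state=seed)
    if name == "XGB":
        return XGBRegressor(n_estimators=200, random_state=seed,
                            verbosity=0, n_jobs=1)
    raise ValidationError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")


def _raw_importance(name: str, estimator, features: Sequence[str]) -> dict[str, float]:
    if name == "GLM":
        coefs = np.abs(estimator.named_steps["ols"].coef_)
    else:
        coefs = np.asarray(estimator.feature_importances_, dtype=float)
    return {f: float(c) for f, c in zip(features, coefs)}


def fit_predictors(
    cohort: CohortMatrix,
    spec: FeatureSpec | None = None,
    split: float = 0.75,
    cv_folds: int = 5,
    seed: int = 0,
    algorithms: Sequence[str] = ALGORITHMS,
    cv_on_full: bool = False,
) -> ModelReport:
    """Fit the five regressors under the shared split/CV protocol.

    ``split`` is the training fraction of the single seeded held-out split.
    Cross-validation runs inside the training portion by default
    (``cv_on_full=True`` uses all rows instead). Rows with a missing feature
    or target are dropped first.
    """
    spec = spec or FeatureSpec()
    missing = [c for c in [*spec.features, spec.target]
               if c not in cohort.data.columns]
    if missing:
        raise ValidationError(f"columns absent from cohort: {missing}")
    frame = cohort.data[[*spec.features, spec.target]].dropna()
    if len(frame) < 2 * cv_folds:
        raise ValidationError(
            f"{len(frame)} complete rows; need at least {2 * cv_folds}"
        )
    x = frame[spec.features].to_numpy(dtype=float)
    y = frame[spec.target].to_numpy(dtype=float)
    if np.std(y) == 0.0:
        raise ValidationError("target is constant; nothing to predict")

    x_train, x_test, y_train, y_test = train_test_split(
        x, y, train_size=split, random_state=seed, shuffle=True
    )
    kfold = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_x, cv_y = (x, y) if cv_on_full else (x_train, y_train)

    models: dict[str, ModelFit] = {}
    for name in algorithms:
        estimator = _make_estimator(name, seed)
        cv_scores = cross_val_score(estimator, cv_x, cv_y, cv=kfold,
                                    scoring="r2")
        estimator.fit(x_train, y_train)
        pred = estimator.predict(x_test)
        raw = _raw_importance(name, estimator, spec.features)
        if any(v > 0 for v in raw.values()):
            proportion, relative = normalize_importance(raw)
        else:
            proportion = {f: 0.0 for f in raw}
            relative = {f: 0.0 for f in raw}
        models[name] = ModelFit(
            name=name,
            r2=float(r2_score(y_test, pred)),
            rmse=float(np.sqrt(mean_squared_error(y_test, pred))),
            cv_scores=[float(s) for s in cv_scores],
            importance_raw=raw,
            importance_proportion=proportion,
            importance_relative=relative,
        )
    return ModelReport(
        models=models, features=list(spec.features), target=spec.target,
        split=split, cv_folds=cv_folds, seed=seed,
        n_train=len(x_train), n_test=len(x_test),
    )


def normalize_importance(
    raw: Mapping[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    """L1- and max-normalize a non-negative importance vector.

    Returns ``(proportion, relative)``: proportions sum to 1; relative
    importances scale the largest feature to 1. Reporting conventions vary
    between the two, and a max-normalized proportion vector reproduces
    published "relative importance" values from published percentages.
    """
    values = {k: float(v) for k, v in raw.items()}
    if any(v < 0 for v in values.values()):
        raise ValidationError("importances must be non-negative")
    total = sum(values.values())
    if total <= 0:
        raise ValidationError("all importances are zero")
    peak = max(values.values())
    proportion = {k: v / total for k, v in values.items()}
    relative = {k: v / peak for k, v in values.items()}
    return proportion, relative


def normalize_rmse(rmse_by_model: Mapping[str, float]) -> dict[str, float]:
    """L1-normalize per-model RMSEs (for comparative display)."""
    values = {k: float(v) for k, v in rmse_by_model.items()}
    if any(v < 0 for v in values.values()):
        raise ValidationError("RMSE must be non-negative")
    total = sum(values.values())
    if total <= 0:
        raise ValidationError("all RMSE values are zero")
    return {k: v / total for k, v in values.items()}


def rank_models(report: ModelReport) -> list[str]:
    """Model names by descending held-out R^2, ties broken by ascending RMSE."""
    if not report.models:
        raise ValidationError("report contains no fitted models")
    return sorted(report.models,
                  key=lambda m: (-report.models[m].r2, report.models[m].rmse))
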