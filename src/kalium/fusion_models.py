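"""PLS-fusion regressors: latent extraction chained to tuned ML regressors.

High-dimensional reflectance spectra (2101 bands) overfit flexible
regressors badly at field-campaign sample sizes. The fusion strategy fits
a PLS latent extractor on the training spectra (stopping at 75% cumulative
predictor variance), then trains a base regressor — random forest,
gradient-boosted trees or a feed-forward network — on the handful of
latent scores. Standalone baselines train the same regressors on the full
spectra instead.

Base regressors are delegated to scikit-learn and xgboost behind a thin
adapter; hyperparameters are tuned by exhaustive grid search with seeded
10-fold cross-validation maximizing R^2, ties broken by grid enumeration
order. The feed-forward network receives z-scored inputs through an
internal pipeline; tree ensembles are scale-invariant and do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .chemometrics import PLSRModel, extract_latents_by_variance
from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateTargetError,
    StateError,
    ValidationError,
)
from .spectra_io import SpectraSet

KINDS = ("random_forest", "gradient_boosted_trees", "feedforward_network")

#: full tuning grids. The forest tree-count grid is the union of the two
#: conventions in use (50-200 by 50, and 100/200/300); the per-split
#: feature rule covers sqrt, log2 and a fixed count of 10.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [50, 100, 150, 200, 300],
        "max_depth": [5, 10, 15],
        "max_features": ["sqrt", "log2", 10],
    },
    "gradient_boosted_trees": {
        "n_estimators": [100, 200, 300],
        "max_depth": [5, 10, 15],
        "learning_rate": [0.01, 0.05, 0.1],
    },
    "feedforward_network": {
        "hidden_layer_sizes": [(100,), (100, 50)],
        "alpha": [1e-4, 1e-3, 1e-2],
    },
}

#: coarse grids for sweeps where each (model, order) cell repeats the search
REDUCED_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100],
        "max_depth": [5, 10],
        "max_features": ["sqrt"],
    },
    "gradient_boosted_trees": {
        "n_estimators": [50],
        "max_depth": [3, 5],
        "learning_rate": [0.1],
    },
    "feedforward_network": {
        "hidden_layer_sizes": [(100,)],
        "alpha": [1e-3],
    },
}

GRID_PRESETS = {"default": DEFAULT_GRIDS, "reduced": REDUCED_GRIDS}


@dataclass
class RegressorSpec:
    """A base-regressor kind plus its tuning grid and CV policy."""

    kind: str
    grid: dict[str, list] | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown regressor kind {self.kind!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.kind].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ConfigurationError("tuning grid must be non-empty")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


def _make_estimator(kind: str, seed: int):
    if kind == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1)
    if kind == "gradient_boosted_trees":
        # exact split finding: deterministic and fastest at desk-scale
        # (hundreds of rows), where histogram construction dominates
        return XGBRegressor(
            random_state=seed, n_jobs=1, tree_method="exact", verbosity=0
        )
    if kind == "feedforward_network":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "net",
                    MLPRegressor(
                        activation="relu",
                        solver="adam",
                        max_iter=2000,
                        early_stopping=False,
                        random_state=seed,
                    ),
                ),
            ]
        )
    raise ConfigurationError(f"unknown regressor kind {kind!r}")


def _prepare_grid(spec: RegressorSpec, n_features: int) -> dict[str, list]:
    """Adapter-level grid fixes: prefix network params for the internal
    pipeline; clamp integer max_features to the actual feature count."""
    grid: dict[str, list] = {}
    for name, values in spec.grid.items():
        vals = list(values)
        if spec.kind == "random_forest" and name == "max_features":
            vals = [min(v, n_features) if isinstance(v, int) else v for v in vals]
            seen: list = []
            vals = [v for v in vals if not (v in seen or seen.append(v))]
        key = f"net__{name}" if spec.kind == "feedforward_network" else name
        grid[key] = vals
    return grid


def _strip_prefix(params: dict[str, Any]) -> dict[str, Any]:
    return {k.split("__", 1)[-1]: v for k, v in params.items()}


def tune_and_fit(spec: RegressorSpec, X: np.ndarray, y: np.ndarray):
    """Grid search over ``spec.grid`` with seeded shuffled K-fold CV.

    Maximizes mean CV R^2; on ties the first grid cell in enumeration
    order wins. The winning configuration is refit on all provided rows.
    Returns ``(fitted_regressor, chosen_hyperparams)``. Deterministic
    given ``spec.seed`` (single-threaded fits).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValidationError("X and y disagree on sample count")
    if X.shape[0] < spec.cv_folds:
        raise ValidationError(
            f"n={X.shape[0]} smaller than cv_folds={spec.cv_folds}"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateTargetError("constant response; tuning undefined")
    grid = _prepare_grid(spec, X.shape[1])
    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_estimator(spec.kind, spec.seed),
        grid,
        scoring="r2",
        cv=cv,
        n_jobs=1,
        refit=True,
        error_score="raise",
    )
    with warnings.catch_warnings():
        # non-converged network fits are recorded, not fatal
        warnings.simplefilter("always", ConvergenceWarning)
        search.fit(X, y)
    return search.best_estimator_, _strip_prefix(search.best_params_)


@dataclass
class FusionModel:
    """A (possibly PLS-fronted) fitted regressor bound to one derivative
    order and wavelength grid."""

    extractor: PLSRModel | None
    regressor: Any
    chosen_hyperparams: dict[str, Any]
    kind: str
    order: float
    wavelengths: np.ndarray

    @property
    def n_features_in(self) -> int:
        """Width of the regressor's input (latent count or band count)."""
        if self.extractor is not None:
            return self.extractor.n_components
        return len(self.wavelengths)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        feats = self.extractor.transform(X) if self.extractor is not None else X
        return np.asarray(self.regressor.predict(feats), dtype=float).ravel()


def fit_fusion(
    train: SpectraSet,
    kind: str,
    use_plsr: bool = True,
    threshold: float = 0.75,
    spec: RegressorSpec | None = None,
    cap: int = 30,
) -> FusionModel:
    """Fit a fusion model (or standalone baseline) on a training set.

    With ``use_plsr`` the PLS extractor is fitted on the training spectra
    by the cumulative-variance rule and the regressor is tuned on the
    latent scores; otherwise the regressor is tuned on the full spectra.
    Only the provided (training) rows are ever touched.
    """
    spec = spec or RegressorSpec(kind=kind)
    if spec.kind != kind:
        raise ConfigurationError("spec.kind disagrees with requested kind")
    X, y = train.reflectance, train.potassium
    extractor = None
    if use_plsr:
        scores, extractor = extract_latents_by_variance(X, y, threshold, cap)
        feats = scores
    else:
        feats = X
    regressor, params = tune_and_fit(spec, feats, y)
    return FusionModel(
        extractor=extractor,
        regressor=regressor,
        chosen_hyperparams=params,
        kind=kind,
        order=train.order,
        wavelengths=train.wavelengths.copy(),
    )


def predict(model: FusionModel, s: SpectraSet) -> np.ndarray:
    """Predict potassium for a spectra set at the model's derivative order."""
    if s.order != model.order:
        raise StateError(
            f"model trained at order {model.order}, got spectra at {s.order}"
        )
    if (
        s.wavelengths.shape != model.wavelengths.shape
        or not np.array_equal(s.wavelengths, model.wavelengths)
    ):
        raise AlignmentError("wavelength grid differs from the training grid")
    pred = model.predict_matrix(s.reflectance)
    if not np.all(np.isfinite(pred)):
        raise ValidationError("non-finite predictions")
    return pred
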