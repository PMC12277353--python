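"""Experiment orchestration: split, order sweep x model grid, comparison.

``run_experiment`` reproduces the full study design on any raw spectra
set: a single 4/5 - 1/5 train/validation split fixed before any
transformation, a sweep of Grünwald-Letnikov differentiation orders, and
for each order the seven candidate models — standalone PLSR (components
chosen by 10-fold CV over 1..20), standalone random forest / gradient
boosted trees / feed-forward network on the full spectra, and the three
PLS-fusion counterparts (latents by the 75% cumulative-variance rule).
Each cell reports train and validation R^2, MSE and MAE; the best order
per model is the one maximizing validation R^2 (ties toward lower order).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from . import fusion_models
from .chemometrics import fit_plsr, select_components_cv
from .errors import DegenerateTargetError, StateError, ValidationError
from .fractional_diff import DEFAULT_ORDERS, transform_set
from .fusion_models import GRID_PRESETS, RegressorSpec, fit_fusion
from .spectra_io import (
    COMPARISON_COLUMNS,
    SpectraSet,
    read_comparison_frame,
    write_comparison_frame,
)

#: canonical model names and, for ML models, their regressor kinds
MODEL_KINDS = {
    "rf": "random_forest",
    "xgb": "gradient_boosted_trees",
    "mlp": "feedforward_network",
    "plsr-rf": "random_forest",
    "plsr-xgb": "gradient_boosted_trees",
    "plsr-mlp": "feedforward_network",
}
ALL_MODELS = ("plsr", "rf", "xgb", "mlp", "plsr-rf", "plsr-xgb", "plsr-mlp")


@dataclass
class Metrics:
    r2: float
    mse: float
    mae: float


def split_train_validation(
    n: int, validation_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index sets.

    Validation size is ``ceil(n * fraction)``; assignment is a seeded
    uniform permutation, so the split is deterministic given the seed.
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ValidationError("validation_fraction must be in (0, 1)")
    if n < 5:
        raise ValidationError("need at least 5 samples to split")
    n_val = math.ceil(n * validation_fraction)
    if n_val >= n:
        raise ValidationError("validation fraction leaves no training data")
    perm = np.random.default_rng(seed).permutation(n)
    val = np.sort(perm[:n_val])
    train = np.sort(perm[n_val:])
    return train, val


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """R^2 (against the evaluated subset's own mean), MSE and MAE."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValidationError("need equal-length vectors with >= 2 entries")
    if np.ptp(y_true) == 0.0:
        raise DegenerateTargetError("constant y_true: R^2 undefined")
    return Metrics(
        r2=float(r2_score(y_true, y_pred)),
        mse=float(mean_squared_error(y_true, y_pred)),
        mae=float(mean_absolute_error(y_true, y_pred)),
    )


@dataclass
class ExperimentConfig:
    validation_fraction: float = 0.2
    plsr_variance_threshold: float = 0.75
    plsr_component_cap: int = 30
    standalone_plsr_max_components: int = 20
    cv_folds: int = 10
    grids: str | Mapping[str, dict] = "default"
    seed: int = 0

    def grid_for(self, kind: str) -> dict:
        table = GRID_PRESETS[self.grids] if isinstance(self.grids, str) else self.grids
        return {k: list(v) for k, v in table[kind].items()}


@dataclass
class ComparisonTable:
    """Tidy per-(model, order, split) metric table."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COMPARISON_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"comparison table missing columns: {missing}")
        self.frame = self.frame[COMPARISON_COLUMNS].reset_index(drop=True)

    def write(self, path: str | Path) -> None:
        write_comparison_frame(self.frame, path)

    @classmethod
    def read(cls, path: str | Path) -> "ComparisonTable":
        return cls(read_comparison_frame(path))

    def validation_rows(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == "validation"]


def _metric_rows(model, order, split, metrics, n_components, params, seed, err=""):
    return {
        "model": model,
        "order": float(order),
        "split": split,
        "r2": metrics.r2 if metrics else np.nan,
        "mse": metrics.mse if metrics else np.nan,
        "mae": metrics.mae if metrics else np.nan,
        "n_components": n_components if n_components is not None else "",
        "hyperparams": json.dumps(params, sort_keys=True) if params else "",
        "seed": seed,
        "error": err,
    }


def _fit_cell(model_name, train_set, cfg):
    """Fit one (model, order) cell on training rows only.

    Returns (predict_fn, n_components, hyperparams).
    """
    Xtr, ytr = train_set.reflectance, train_set.potassium
    if model_name == "plsr":
        m = select_components_cv(
            Xtr, ytr,
            max_components=cfg.standalone_plsr_max_components,
            folds=cfg.cv_folds, seed=cfg.seed,
        )
        model = fit_plsr(Xtr, ytr, m)
        return model.predict, model.n_components, {"n_components": m}
    kind = MODEL_KINDS[model_name]
    spec = RegressorSpec(
        kind=kind, grid=cfg.grid_for(kind), cv_folds=cfg.cv_folds, seed=cfg.seed
    )
    fm = fit_fusion(
        train_set, kind,
        use_plsr=model_name.startswith("plsr-"),
        threshold=cfg.plsr_variance_threshold,
        spec=spec, cap=cfg.plsr_component_cap,
    )
    ncomp = fm.extractor.n_components if fm.extractor is not None else None
    return fm.predict_matrix, ncomp, fm.chosen_hyperparams


def run_experiment(
    data: SpectraSet,
    models: Sequence[str] = ALL_MODELS,
    orders: Iterable[float] | None = None,
    config: ExperimentConfig | None = None,
) -> ComparisonTable:
    """Run the full sweep-and-compare experiment on a raw spectra set.

    The train/validation split is drawn once and reused for every order
    and model; each order's transform is computed once on the full set
    (the row-wise derivative touches no cross-sample information), and
    every model is fitted on the transformed training rows only.
    Individual cell failures are recorded in the ``error`` column and the
    run continues. Fully reproducible given ``config.seed``.
    """
    if data.order != 0.0:
        raise StateError("run_experiment expects raw (order 0) spectra")
    cfg = config or ExperimentConfig()
    orders = tuple(float(v) for v in (orders if orders is not None else DEFAULT_ORDERS))
    unknown = [m for m in models if m not in ALL_MODELS]
    if unknown:
        raise ValidationError(f"unknown models: {unknown}")
    tr_idx, va_idx = split_train_validation(
        data.n_samples, cfg.validation_fraction, cfg.seed
    )
    rows = []
    for order in orders:
        tset = transform_set(data, order)
        train_set = tset.subset(tr_idx)
        val_set = tset.subset(va_idx)
        for name in models:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    predict_fn, ncomp, params = _fit_cell(name, train_set, cfg)
                    m_tr = regression_metrics(
                        train_set.potassium, predict_fn(train_set.reflectance)
                    )
                    m_va = regression_metrics(
                        val_set.potassium, predict_fn(val_set.reflectance)
                    )
            except Exception as exc:  # record and continue
                err = f"{type(exc).__name__}: {exc}"
                for split in ("train", "validation"):
                    rows.append(
                        _metric_rows(name, order, split, None, None, None,
                                     cfg.seed, err)
                    )
                continue
            rows.append(
                _metric_rows(name, order, "train", m_tr, ncomp, params, cfg.seed)
            )
            rows.append(
                _metric_rows(name, order, "validation", m_va, ncomp, params, cfg.seed)
            )
    return ComparisonTable(pd.DataFrame(rows))


@dataclass
class BestResult:
    order: float
    r2: float
    mse: float
    mae: float


def select_best(table: ComparisonTable) -> dict[str, BestResult]:
    """Best differentiation order per model by validation R^2.

    Ties break toward the lower order; error-marked cells are excluded.
    Models with no scoreable cell map to ``None``.
    """
    if table.frame.empty:
        raise ValidationError("empty comparison table")
    out: dict[str, BestResult | None] = {}
    val = table.validation_rows()
    for model in val["model"].unique():
        sub = val[(val["model"] == model) & val["r2"].notna()]
        sub = sub[sub["error"].fillna("") == ""] if "error" in sub else sub
        if sub.empty:
            out[model] = None
            continue
        sub = sub.sort_values(["order"], kind="stable")
        best = sub.loc[sub["r2"].idxmax()]  # idxmax takes first (lowest order) on ties
        out[model] = BestResult(
            order=float(best["order"]), r2=float(best["r2"]),
            mse=float(best["mse"]), mae=float(best["mae"]),
        )
    return out


def pivot_by_order(table: ComparisonTable,
                   orders: Sequence[float] = (0.0, 1.0, 2.0, 3.0)) -> pd.DataFrame:
    """Models x orders summary of validation R^2 (plus each model's best)."""
    val = table.validation_rows()
    best = select_best(table)
    recs = []
    for model in val["model"].unique():
        row = {"model": model}
        for o in orders:
            hit = val[(val["model"] == model) & (val["order"] == o)]
            row[f"r2@{o:g}"] = float(hit["r2"].iloc[0]) if len(hit) else np.nan
        b = best.get(model)
        row["best_order"] = b.order if b else np.nan
        row["best_r2"] = b.r2 if b else np.nan
        recs.append(row)
    return pd.DataFrame(recs)
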