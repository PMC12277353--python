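"""Band-wise correlation analysis and partial least squares regression.

Two pieces of machinery live here:

* the correlation surface: per-band Pearson correlation between
  (fractionally differentiated) reflectance and leaf potassium, tabulated
  across differentiation orders — the screening tool that locates
  potassium-sensitive wavelength regions and the derivative order at which
  they express most strongly;

* a single-response NIPALS partial least squares regression (PLS1). Each
  latent variable is a linear combination of the bands whose weight vector
  is proportional to the residual cross-covariance X'y; the predictor
  matrix and response are deflated after each component. Extraction can be
  stopped by a cumulative predictor-variance threshold (the rule used when
  PLS scores feed a downstream regressor) or by cross-validated component
  selection (the rule for standalone PLSR).

X is column-centered but not variance-scaled by default: differentiated
spectra carry meaningful relative magnitudes across bands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.model_selection import KFold

from .errors import AlignmentError, DegenerateTargetError, RankError, ValidationError
from .spectra_io import SpectraSet


# ---------------------------------------------------------------------------
# band-wise correlation
# ---------------------------------------------------------------------------

def bandwise_correlation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with y.

    Zero-variance columns are flagged as NaN (undefined) rather than 0.
    Requires at least 3 samples and a non-constant response.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValidationError("X must be (n, k) and y length n")
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 samples for a correlation")
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc * yc))
    if sy == 0.0:
        raise DegenerateTargetError("response is constant; correlation undefined")
    constant = np.ptp(X, axis=0) == 0.0
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.sum(Xc * Xc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[constant | (sx == 0.0)] = np.nan
    return r


@dataclass
class CorrelationSurface:
    """|Pearson r| between differentiated spectra and potassium, per
    (differentiation order, wavelength)."""

    orders: np.ndarray          # (n_orders,)
    wavelengths: np.ndarray     # (n_bands,)
    abs_r: np.ndarray           # (n_orders, n_bands), NaN where undefined
    per_order_max: np.ndarray   # (n_orders,)

    @property
    def best_order(self) -> float:
        """Order with the largest per-order maximum |r| (ties -> lower)."""
        return float(self.orders[int(np.nanargmax(self.per_order_max))])

    def to_frame(self):
        import pandas as pd

        o, w = np.meshgrid(self.orders, self.wavelengths, indexing="ij")
        return pd.DataFrame(
            {"order": o.ravel(), "wavelength": w.ravel(), "abs_r": self.abs_r.ravel()}
        )


def correlation_surface(
    sweep: Mapping[float, SpectraSet], y: np.ndarray | None = None
) -> CorrelationSurface:
    """Correlation surface over an order sweep.

    All sets must share the wavelength axis and sample order; the response
    defaults to the potassium values carried by the sets. Undefined
    (zero-variance) bands are excluded from the per-order maxima.
    """
    if not sweep:
        raise ValidationError("empty sweep")
    sets = list(sweep.values())
    ref = sets[0]
    for s in sets[1:]:
        if not ref.same_grid(s):
            raise AlignmentError("sweep members disagree on wavelength grid")
        if s.sample_ids != ref.sample_ids:
            raise AlignmentError("sweep members disagree on sample order")
        if not np.array_equal(s.potassium, ref.potassium):
            raise AlignmentError("sweep members disagree on potassium values")
    y = ref.potassium if y is None else np.asarray(y, dtype=float)
    orders = np.array([float(v) for v in sweep], dtype=float)
    abs_r = np.vstack(
        [np.abs(bandwise_correlation(s.reflectance, y)) for s in sets]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        per_order_max = np.nanmax(abs_r, axis=1)
    return CorrelationSurface(orders, ref.wavelengths.copy(), abs_r, per_order_max)


# ---------------------------------------------------------------------------
# PLS regression (NIPALS, single response)
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """Fitted PLS1 model.

    ``x_weights`` (k x m) are the unit-norm weight vectors w of each
    latent variable f = X w; ``x_loadings``/``y_loadings`` come from the
    deflation regressions; ``cum_x_variance[j]`` is the fraction of the
    centered predictor variance explained by the first j+1 components.
    ``x_rotation`` maps centered spectra directly to scores,
    T = (X - x_mean) @ x_rotation, so projection of the training data
    reproduces the stored ``x_scores``.
    """

    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    x_rotation: np.ndarray
    x_scores: np.ndarray
    cum_x_variance: np.ndarray
    threshold_reached: bool = True
    requested_components: int | None = None

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients in original band space:
        yhat = y_mean + (X - x_mean) @ coefficients."""
        return self.x_rotation @ self.y_loadings

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project spectra onto the latent variables (scores)."""
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.x_rotation

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean + self.transform(X) @ self.y_loadings

    def truncated(self, m: int) -> "PLSRModel":
        """The same model restricted to its first ``m`` components."""
        if not (1 <= m <= self.n_components):
            raise RankError(f"cannot truncate to {m} of {self.n_components}")
        W = self.x_weights[:, :m]
        P = self.x_loadings[:, :m]
        rot = W @ np.linalg.inv(P.T @ W)
        return PLSRModel(
            n_components=m,
            x_weights=W,
            x_loadings=P,
            y_loadings=self.y_loadings[:m],
            x_mean=self.x_mean,
            y_mean=self.y_mean,
            x_rotation=rot,
            x_scores=self.x_scores[:, :m],
            cum_x_variance=self.cum_x_variance[:m],
            threshold_reached=self.threshold_reached,
            requested_components=self.requested_components,
        )

    # -- serialisation -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = {
            "n_components": self.n_components,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "cum_x_variance": self.cum_x_variance.tolist(),
            "threshold_reached": self.threshold_reached,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        W = np.asarray(d["x_weights"], dtype=float)
        P = np.asarray(d["x_loadings"], dtype=float)
        rot = W @ np.linalg.inv(P.T @ W)
        return cls(
            n_components=d["n_components"],
            x_weights=W,
            x_loadings=P,
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            x_rotation=rot,
            x_scores=np.empty((0, d["n_components"])),
            cum_x_variance=np.asarray(d["cum_x_variance"], dtype=float),
            threshold_reached=d["threshold_reached"],
        )


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRModel:
    """Fit PLS1 by NIPALS with sequential deflation.

    Component j's weight vector is the normalized residual cross-covariance
    X_res' y_res; X and y are deflated by the component's rank-one
    approximation. Extraction stops early (with fewer components than
    requested, recorded on the model) if the residual cross-covariance
    vanishes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise ValidationError("X and y disagree on sample count")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    max_rank = min(n - 1, k)
    if not (1 <= n_components <= max_rank):
        raise RankError(
            f"n_components={n_components} outside [1, min(n-1, k)={max_rank}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    ss_total = float(np.sum(Xc * Xc))
    if ss_total == 0.0:
        raise ValidationError("predictor matrix is constant")

    W = np.zeros((k, n_components))
    P = np.zeros((k, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    cum = np.zeros(n_components)
    eps = np.finfo(float).eps
    fitted = 0
    for j in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= np.sqrt(eps) * max(1.0, np.linalg.norm(yc)):
            break  # residual cross-covariance exhausted
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= eps * ss_total:
            break
        p = Xc.T @ t / tt
        qj = float(yc @ t / tt)
        Xc -= np.outer(t, p)
        yc = yc - qj * t
        W[:, j], P[:, j], q[j], T[:, j] = w, p, qj, t
        cum[j] = 1.0 - float(np.sum(Xc * Xc)) / ss_total
        fitted += 1
    if fitted == 0:
        raise DegenerateTargetError("no component extractable (X'y is zero)")
    W, P, q, T, cum = W[:, :fitted], P[:, :fitted], q[:fitted], T[:, :fitted], cum[:fitted]
    rot = W @ np.linalg.inv(P.T @ W)
    return PLSRModel(
        n_components=fitted,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_mean=x_mean,
        y_mean=y_mean,
        x_rotation=rot,
        x_scores=T,
        cum_x_variance=cum,
        requested_components=n_components,
    )


def select_components_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Cross-validated choice of the PLS component count.

    Searches 1..max_components with seeded shuffled K-fold CV, maximizing
    mean out-of-fold R^2; ties break toward fewer components. Because PLS
    components are nested, each fold is fitted once at the largest feasible
    count and scored at every truncation. If a fold cannot support the full
    range the searched range shrinks with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if max_components < 1 or folds < 2:
        raise ValidationError("max_components >= 1 and folds >= 2 required")
    if n < folds:
        raise ValidationError(f"n={n} smaller than {folds} folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    feasible = max_components
    fold_r2 = []
    for tr, va in kf.split(X):
        cap = min(max_components, len(tr) - 1, X.shape[1])
        if cap < feasible:
            feasible = cap
        model = fit_plsr(X[tr], y[tr], cap)
        if model.n_components < feasible:
            feasible = model.n_components
        yv = y[va]
        ss = float(np.sum((yv - yv.mean()) ** 2))
        scores = np.full(max_components, -np.inf)
        for m in range(1, model.n_components + 1):
            pred = model.truncated(m).predict(X[va])
            scores[m - 1] = 1.0 - float(np.sum((yv - pred) ** 2)) / ss
        fold_r2.append(scores)
    if feasible < max_components:
        warnings.warn(
            f"searched component range shrunk to 1..{feasible} "
            "(limited by fold size or early stopping)",
            stacklevel=2,
        )
    mean_r2 = np.vstack(fold_r2)[:, :feasible].mean(axis=0)
    return int(np.argmax(mean_r2)) + 1  # argmax takes first (fewest) on ties


def extract_latents_by_variance(
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.75,
    cap: int = 30,
) -> tuple[np.ndarray, PLSRModel]:
    """Extract PLS components until the cumulative explained predictor
    variance reaches ``threshold`` (default 75%).

    At least one component is always extracted; extraction stops at ``cap``
    components if the threshold is unreachable, with
    ``model.threshold_reached`` set False. Returns the training scores and
    the fitted model (whose ``transform`` projects new spectra with the
    training centering and weights).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must be in (0, 1]")
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    limit = min(cap, min(n - 1, k))
    model = fit_plsr(X, y, limit)
    reached = np.nonzero(model.cum_x_variance >= threshold)[0]
    if reached.size:
        m = int(reached[0]) + 1
        model = model.truncated(m) if m < model.n_components else model
        model.threshold_reached = True
    else:
        model.threshold_reached = False
        warnings.warn(
            f"cumulative X-variance {model.cum_x_variance[-1]:.3f} below "
            f"threshold {threshold} at cap {limit}",
            stacklevel=2,
        )
    return model.x_scores, model
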