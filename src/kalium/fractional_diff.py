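"""Grünwald-Letnikov fractional differentiation of uniformly sampled spectra.

The discrete G-L derivative of order ``v`` of a signal sampled at unit step
is the expanding-window weighted difference

    (D^v x)[i] = sum_{m=0}^{i} w_m x[i - m],
    w_m = (-1)^m Gamma(v+1) / (m! Gamma(v - m + 1)),

i.e. a convolution with the generalized binomial coefficients of
``(1 - z)^v``. At integer ``v`` the weights truncate to the classical
difference stencils ([1, -1], [1, -2, 1], ...). Weights are evaluated by
the multiplicative recursion ``w_m = w_{m-1} (m - 1 - v) / m``, which is
exact and avoids the Gamma-function poles that the ratio form hits when
``v`` is an integer and ``m > v``.

The step size is fixed at one band index (1 nm on the working grid), so
derivative values are in per-band units. The window expands from the first
retained band: no history truncation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.signal import fftconvolve

from .errors import StateError, ValidationError
from .spectra_io import SpectraSet

#: the order sweep used throughout: 0.0 to 3.0 in steps of 0.1 (31 values)
DEFAULT_ORDERS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 3.01, 0.1), 1))


@dataclass(frozen=True)
class GLWeights:
    """Generalized binomial weight sequence of the discrete G-L operator."""

    order: float
    weights: np.ndarray
    h: float = 1.0

    def __len__(self) -> int:
        return len(self.weights)


def gl_weights(v: float, length: int) -> GLWeights:
    """First ``length`` G-L weights at order ``v``.

    ``w_0 = 1`` always; for integer ``v`` all weights beyond index ``v``
    are exactly zero (binomial truncation).
    """
    if v < 0:
        raise ValidationError(f"differentiation order must be >= 0, got {v}")
    if length < 1:
        raise ValidationError("need at least one weight")
    w = np.empty(length)
    w[0] = 1.0
    for m in range(1, length):
        w[m] = w[m - 1] * (m - 1 - v) / m
    return GLWeights(order=float(v), weights=w)


def fractional_derivative(x: np.ndarray, v: float) -> np.ndarray:
    """Apply the order-``v`` G-L derivative to a 1-D signal.

    Output has the same length as the input; position ``i`` uses the full
    available history ``x[0..i]``. The operator is linear and composes:
    applying order ``a`` then ``b`` equals applying ``a + b``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite values")
    if v == 0.0:
        return x.copy()
    w = gl_weights(v, x.size).weights
    return np.convolve(x, w)[: x.size]


def _transform_matrix(X: np.ndarray, v: float) -> np.ndarray:
    if v == 0.0:
        return X.copy()
    n, k = X.shape
    w = gl_weights(v, k).weights
    if k >= 256:
        return fftconvolve(X, w[None, :], mode="full", axes=1)[:, :k]
    out = np.empty_like(X)
    for i in range(n):
        out[i] = np.convolve(X[i], w)[:k]
    return out


def transform_set(s: SpectraSet, v: float, trim: int = 0) -> SpectraSet:
    """Row-wise fractional derivative of a raw spectra set.

    Refuses already-differentiated input (``s.order != 0``) to prevent
    accidental double differentiation; compose orders by passing their sum
    instead. ``trim`` drops the first ``trim`` bands of the result, where
    the expanding window has the least history (default keeps all bands).
    """
    if s.order != 0.0:
        raise StateError(
            f"input already differentiated at order {s.order}; "
            "transform raw (order 0) spectra instead"
        )
    if v < 0:
        raise ValidationError(f"differentiation order must be >= 0, got {v}")
    out = _transform_matrix(s.reflectance, v)
    wl = s.wavelengths
    if trim:
        out = out[:, trim:]
        wl = wl[trim:]
    return replace(s, wavelengths=wl, reflectance=out, order=float(v))


def sweep_orders(
    s: SpectraSet, orders: Iterable[float] | None = None, trim: int = 0
) -> Mapping[float, SpectraSet]:
    """Transform a raw set at every requested order (default 0.0..3.0 by 0.1).

    Returns an insertion-ordered mapping order -> transformed set.
    """
    orders = tuple(orders) if orders is not None else DEFAULT_ORDERS
    if not orders:
        raise ValidationError("order list must be non-empty")
    for v in orders:
        if v < 0:
            raise ValidationError(f"differentiation order must be >= 0, got {v}")
    return {float(v): transform_set(s, float(v), trim=trim) for v in orders}
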