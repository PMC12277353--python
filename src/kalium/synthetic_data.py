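"""Synthetic leaf spectra with a controllable potassium signal.

The study dataset this package is designed for is confidential, so every
pipeline stage is exercised against simulated data that reproduces the
statistical structure the analysis assumes:

* leaf potassium content (units of 10 g/kg) follows a right-skewed,
  truncated lognormal distribution with mean ~0.81 and coefficient of
  variation ~1.30 on the support [0.06, 5.87];
* reflectance consists of a smooth vegetation-like continuum, fixed water
  absorption bands near 1450 and 1950 nm, and Gaussian absorption features
  whose depths increase with potassium, placed inside the 700-1100 nm and
  1400-1800 nm regions where foliar potassium expresses spectrally;
* optional per-sample smooth baseline variability (brightness, tilt,
  curvature) uncorrelated with potassium, emulating leaf-structure and
  illumination nuisance; additive i.i.d. Gaussian measurement noise.

The generator is deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import optimize, special

from .errors import ConfigurationError
from .spectra_io import SpectraSet

_GRID = np.arange(400.0, 2501.0, 1.0)


@dataclass(frozen=True)
class GaussianFeature:
    """A Gaussian absorption feature.

    Total depth at potassium content ``k`` is ``base_depth +
    k_sensitivity * k`` (reflectance units); the profile is
    ``exp(-(wl - center)^2 / (2 width^2))``.
    """

    center_nm: float
    width_nm: float
    base_depth: float
    k_sensitivity: float = 0.0


@dataclass(frozen=True)
class NuisanceFeature:
    """An absorption feature whose depth varies across samples
    independently of potassium (other leaf constituents: water, dry
    matter, pigments). Per-sample depth is ``base_depth + N(0, depth_sd)``
    clipped at zero."""

    center_nm: float
    width_nm: float
    base_depth: float
    depth_sd: float


@dataclass(frozen=True)
class BaselineConfig:
    """Per-sample smooth nuisance variability of the continuum.

    ``scale_sd`` multiplies the whole continuum (brightness), ``tilt_sd``
    and ``curve_sd`` are amplitudes of linear and quadratic Legendre terms
    over the spectral range. All are standard deviations of zero-mean
    Gaussian coefficients; zeros disable the nuisance entirely.
    """

    scale_sd: float = 0.0
    tilt_sd: float = 0.0
    curve_sd: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 301
    k_mean: float = 0.81
    k_cv: float = 1.30
    k_bounds: tuple[float, float] = (0.06, 5.87)
    features: tuple[GaussianFeature, ...] = (
        GaussianFeature(760.0, 30.0, 0.02, 0.030),
        GaussianFeature(980.0, 40.0, 0.02, 0.025),
        GaussianFeature(1650.0, 50.0, 0.02, 0.030),
    )
    water_bands: tuple[GaussianFeature, ...] = (
        GaussianFeature(1450.0, 35.0, 0.14),
        GaussianFeature(1950.0, 50.0, 0.26),
    )
    #: Beer-Lambert-like saturation scale of the potassium response:
    #: feature depths grow with ``sat * (1 - exp(-k / sat))`` instead of
    #: ``k``. None keeps the response linear in k.
    k_saturation: float | None = None
    #: per-sample coefficient of variation of the water-band depths
    #: (leaf water content variability); 0 fixes the depths
    water_depth_cv: float = 0.0
    nuisance_features: tuple[NuisanceFeature, ...] = ()
    baseline: BaselineConfig = BaselineConfig()
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.k_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("k_bounds must satisfy 0 < lo < hi")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.water_depth_cv < 0:
            raise ConfigurationError("water_depth_cv must be >= 0")
        if self.k_saturation is not None and self.k_saturation <= 0:
            raise ConfigurationError("k_saturation must be > 0 when set")
        for f in self.features + self.water_bands + self.nuisance_features:
            if not (_GRID[0] <= f.center_nm <= _GRID[-1]):
                raise ConfigurationError(
                    f"feature center {f.center_nm} nm outside 400-2500 nm"
                )
            if f.width_nm <= 0:
                raise ConfigurationError("feature widths must be > 0")
        # noiseless reflectance must stay in [0, 1] across the potassium range
        for k in self.k_bounds:
            spec = _noiseless_spectrum(float(k), self)
            if spec.min() < 0.0 or spec.max() > 1.0:
                raise ConfigurationError(
                    "feature depths drive noiseless reflectance outside [0, 1] "
                    f"at potassium {k}"
                )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["features"] = tuple(GaussianFeature(**f) for f in d.get("features", ()))
        d["water_bands"] = tuple(
            GaussianFeature(**f) for f in d.get("water_bands", ())
        )
        d["nuisance_features"] = tuple(
            NuisanceFeature(**f) for f in d.get("nuisance_features", ())
        )
        if "baseline" in d:
            d["baseline"] = BaselineConfig(**d["baseline"])
        if "k_bounds" in d:
            d["k_bounds"] = tuple(d["k_bounds"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_config(**overrides) -> SyntheticConfig:
    """The default study-scale configuration (n=301, clean continuum)."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def derivative_sensitive_config(**overrides) -> SyntheticConfig:
    """Preset emulating field conditions under which differentiation and
    PLS fusion demonstrably help.

    Three ingredients shape it. A strong smooth per-sample baseline
    nuisance (brightness/tilt/curvature) dilutes band-wise correlation in
    the raw spectra; fractional differentiation suppresses it, so the
    correlation profile strengthens at fractional orders. Broad
    other-constituent absorption features overlap the potassium features
    with independently varying depths, capping the correlation any single
    band can reach while leaving the potassium signal linearly separable
    from full-spectrum shape — the regime in which latent-variable
    extraction beats band-wise regressors. A Beer-Lambert-like saturation
    of the potassium response makes the spectra-to-content map mildly
    nonlinear, giving the ML stage on top of the latents a role.
    """
    cfg = SyntheticConfig(
        features=(
            GaussianFeature(780.0, 50.0, 0.02, 0.050),
            GaussianFeature(980.0, 60.0, 0.02, 0.045),
            GaussianFeature(1650.0, 70.0, 0.02, 0.050),
        ),
        k_saturation=3.0,
        water_depth_cv=0.2,
        nuisance_features=(
            NuisanceFeature(800.0, 60.0, 0.03, 0.08),
            NuisanceFeature(958.0, 70.0, 0.03, 0.08),
            NuisanceFeature(1672.0, 80.0, 0.03, 0.08),
            NuisanceFeature(1210.0, 60.0, 0.02, 0.03),
        ),
        baseline=BaselineConfig(scale_sd=0.10, tilt_sd=0.05, curve_sd=0.04),
        noise_sd=0.0008,
    )
    return replace(cfg, **overrides) if overrides else cfg


PRESETS: dict[str, Callable[..., SyntheticConfig]] = {
    "default": default_config,
    "derivative-sensitive": derivative_sensitive_config,
}


# ---------------------------------------------------------------------------
# potassium distribution
# ---------------------------------------------------------------------------

def _truncated_lognormal_moments(mu: float, sigma: float,
                                 lo: float, hi: float) -> tuple[float, float]:
    """Mean and variance of a lognormal(mu, sigma) truncated to [lo, hi]."""
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    z = special.ndtr(b) - special.ndtr(a)
    if z <= 0:
        return np.nan, np.nan

    def raw(p: float) -> float:
        return (
            np.exp(p * mu + 0.5 * p * p * sigma * sigma)
            * (special.ndtr(b - p * sigma) - special.ndtr(a - p * sigma))
            / z
        )

    m1 = raw(1.0)
    m2 = raw(2.0)
    return m1, m2 - m1 * m1


_CALIBRATION_CACHE: dict[tuple, tuple[float, float]] = {}


def calibrate_lognormal(mean: float, cv: float,
                        bounds: tuple[float, float]) -> tuple[float, float]:
    """Solve for lognormal (mu, sigma) whose truncation matches mean and CV.

    Moment-matching uses the closed-form truncated-lognormal moments; the
    untruncated solution seeds the root search. Raises
    :class:`ConfigurationError` when the requested moments are infeasible
    on the given support.
    """
    key = (round(mean, 12), round(cv, 12), tuple(np.round(bounds, 12)))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    lo, hi = bounds
    target_sd = cv * mean
    sigma0 = np.sqrt(np.log1p(cv * cv))
    mu0 = np.log(mean) - 0.5 * sigma0 * sigma0

    def residual(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        m, v = _truncated_lognormal_moments(mu, sigma, lo, hi)
        if not np.isfinite(m):
            return [1e6, 1e6]
        return [m - mean, np.sqrt(max(v, 0.0)) - target_sd]

    sol = optimize.root(residual, [mu0, np.log(sigma0)], method="hybr")
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    m, v = _truncated_lognormal_moments(mu, sigma, lo, hi)
    if not sol.success or abs(m - mean) > 1e-6 * mean or (
        abs(np.sqrt(v) - target_sd) > 1e-6 * target_sd
    ):
        raise ConfigurationError(
            f"cannot match mean={mean}, CV={cv} on support [{lo}, {hi}]"
        )
    _CALIBRATION_CACHE[key] = (float(mu), float(sigma))
    return _CALIBRATION_CACHE[key]


def sample_potassium(cfg: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``cfg.n_samples`` potassium values (units of 10 g/kg).

    Rejection sampling from the calibrated lognormal keeps only draws
    inside ``cfg.k_bounds``; the result is deterministic given the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mu, sigma = calibrate_lognormal(cfg.k_mean, cfg.k_cv, cfg.k_bounds)
    lo, hi = cfg.k_bounds
    out = np.empty(cfg.n_samples)
    filled = 0
    while filled < cfg.n_samples:
        draw = rng.lognormal(mu, sigma, size=max(2 * cfg.n_samples, 64))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, cfg.n_samples - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# reflectance model
# ---------------------------------------------------------------------------

def _continuum(wl: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like baseline: low visible reflectance, a small
    green peak, a red-edge rise to the NIR plateau, gentle SWIR decline."""
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    green = 0.05 * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)
    swir_decline = 1.0 - 0.22 / (1.0 + np.exp(-(wl - 1700.0) / 250.0))
    return (0.06 + 0.46 * red_edge) * swir_decline + green


def _gaussian(wl: np.ndarray, f: GaussianFeature) -> np.ndarray:
    return np.exp(-0.5 * ((wl - f.center_nm) / f.width_nm) ** 2)


def _noiseless_spectrum(
    k: float,
    cfg: SyntheticConfig,
    baseline_coefs: np.ndarray | None = None,
    water_scale: float = 1.0,
    nuisance_depths: np.ndarray | None = None,
) -> np.ndarray:
    wl = _GRID
    cont = _continuum(wl)
    if baseline_coefs is not None:
        u = (wl - wl[0]) / (wl[-1] - wl[0]) * 2.0 - 1.0  # [-1, 1]
        scale, tilt, curve = baseline_coefs
        cont = cont * (1.0 + scale) + tilt * u + curve * 0.5 * (3 * u * u - 1)
    spec = cont.copy()
    keff = k
    if cfg.k_saturation is not None:
        sat = cfg.k_saturation
        keff = sat * (1.0 - np.exp(-k / sat))
    for f in cfg.features:
        spec -= (f.base_depth + f.k_sensitivity * keff) * _gaussian(wl, f)
    for f in cfg.water_bands:
        spec -= water_scale * f.base_depth * _gaussian(wl, f)
    if nuisance_depths is None:
        nuisance_depths = np.array([f.base_depth for f in cfg.nuisance_features])
    for depth, f in zip(nuisance_depths, cfg.nuisance_features):
        spec -= depth * _gaussian(wl, f)
    return spec


def generate_spectrum(k: float, cfg: SyntheticConfig,
                      noise_draw: np.ndarray | None = None) -> np.ndarray:
    """Reflectance vector on the 1-nm 400-2500 nm grid for one sample.

    ``noise_draw`` is the per-band standard-normal noise (scaled by
    ``cfg.noise_sd``); omit it for a noiseless spectrum.
    """
    lo, hi = cfg.k_bounds
    if not (lo <= k <= hi):
        raise ConfigurationError(f"potassium {k} outside bounds {cfg.k_bounds}")
    spec = _noiseless_spectrum(float(k), cfg)
    if noise_draw is not None and cfg.noise_sd > 0:
        spec = spec + cfg.noise_sd * np.asarray(noise_draw)
    return spec


def generate_dataset(cfg: SyntheticConfig) -> SpectraSet:
    """Full synthetic :class:`SpectraSet` at order 0.0, 400-2500 nm.

    Byte-identical across runs with the same config (including seed). The
    baseline nuisance, when enabled, is drawn independently of potassium.
    Reflectance is clipped to [0, 1] after noise, mirroring the physical
    bounds of a calibrated reflectance measurement.
    """
    rng = np.random.default_rng(cfg.seed)
    k = sample_potassium(cfg, rng)
    n, nb = cfg.n_samples, _GRID.size
    bl = cfg.baseline
    coefs = np.zeros((n, 3))
    if bl.scale_sd or bl.tilt_sd or bl.curve_sd:
        coefs = rng.normal(0.0, 1.0, size=(n, 3)) * np.array(
            [bl.scale_sd, bl.tilt_sd, bl.curve_sd]
        )
    water_scale = np.ones(n)
    if cfg.water_depth_cv > 0:
        water_scale = np.clip(
            rng.normal(1.0, cfg.water_depth_cv, size=n), 0.0, None
        )
    nf = cfg.nuisance_features
    depths = np.zeros((n, len(nf)))
    if nf:
        base = np.array([f.base_depth for f in nf])
        sd = np.array([f.depth_sd for f in nf])
        depths = np.clip(base + rng.normal(0.0, 1.0, size=(n, len(nf))) * sd,
                         0.0, None)
    noise = rng.normal(0.0, 1.0, size=(n, nb)) if cfg.noise_sd > 0 else None
    refl = np.empty((n, nb))
    for i in range(n):
        refl[i] = _noiseless_spectrum(
            k[i], cfg, coefs[i], water_scale[i], depths[i]
        )
    if noise is not None:
        refl = refl + cfg.noise_sd * noise
    np.clip(refl, 0.0, 1.0, out=refl)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return SpectraSet(ids, _GRID.copy(), refl, k, order=0.0)


def sensitive_supports(cfg: SyntheticConfig, n_widths: float = 3.0) -> np.ndarray:
    """Boolean mask over the 1-nm grid of the injected potassium-sensitive
    regions (each feature's center +/- ``n_widths`` widths)."""
    mask = np.zeros(_GRID.size, dtype=bool)
    for f in cfg.features:
        if f.k_sensitivity != 0.0:
            mask |= np.abs(_GRID - f.center_nm) <= n_widths * f.width_nm
    return mask
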