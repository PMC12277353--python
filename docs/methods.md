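# Methods

This note records the models, conventions and design choices behind
`kalium`, in the order the pipeline applies them.

## Spectra model and I/O conventions

A `SpectraSet` is a samples × bands matrix on a strictly uniform 1-nm
wavelength grid with aligned per-sample potassium values (units of
10 g/kg, strictly positive). The working range is fixed to 400–2500 nm;
shorter wavelengths recorded by field instruments are discarded on
ingestion because they are dominated by instrument noise. Input tables on
coarser or irregular grids (typical spectroradiometers sample at 3 nm in
the VNIR and 8 nm in the SWIR) are linearly interpolated onto the 1-nm
grid — the least-assumption resampling — with values at shared grid points
preserved bitwise. Raw (order-0) reflectance must lie in [0, 1];
differentiated spectra are exempt. CSV is the only interchange format;
proprietary binary instrument formats are out of scope.

## Grünwald–Letnikov fractional differentiation

The discrete operator is a convolution with the generalized binomial
weights of (1−z)^v, applied with an expanding window from the first
retained band: output position i uses the full history x[0..i]. Choices:

* **Step size h = 1 band index** (1 nm). The derivative is therefore in
  per-band units; a wavelength-aware h would rescale all orders by a
  constant and change nothing in correlation or model ranking.
* **Weights by multiplicative recursion** `w_m = w_{m−1}(m−1−v)/m`, not by
  Gamma ratios: the recursion is exact to machine precision and avoids
  Γ poles at negative integers when v is an integer and m > v (where the
  true weights are exactly zero). The Gamma-ratio form is kept in the test
  suite as an independent oracle for fractional v.
* **No boundary trim, no pre-smoothing** by default. Early bands have
  short history; an optional `trim` argument drops them, but the default
  keeps the full 400–2500 nm axis. The operator is linear and composes
  exactly: D^a D^b = D^{a+b} (generating-function identity), which the
  suite verifies at 1e−9 on 500-point signals.
* Orders are restricted to [0, 3]; negative orders (fractional
  integration) are rejected. The canonical sweep is 0.0–3.0 in 0.1 steps
  (31 orders).
* Matrices with ≥ 256 bands are convolved via FFT (identical to direct
  convolution within ~1e−13); v = 0 short-circuits to an exact copy.

## Band-wise correlation surface

Pearson r per (order, band) against potassium, reported as |r|.
Zero-variance bands (possible after clipping or in degenerate synthetic
configs) are flagged NaN — undefined, not zero — and excluded from
per-order maxima. Ties in the best-order selection break toward the lower
order. No multiplicity control is applied: the surface is a screening
device, not an inference procedure.

## PLS regression

Single-response NIPALS with sequential deflation: each component's weight
vector is the normalized residual cross-covariance X'y; scores t = Xw;
X and y are deflated by the rank-one regression on t. Conventions:

* X is column-centered but **not variance-scaled**: differentiated spectra
  carry meaningful relative magnitudes across bands, and scaling would
  inflate noise-only bands. Scaling can be added upstream if wanted.
* Extraction stops early (recorded on the model) if the residual
  cross-covariance norm falls below √ε of the residual response norm.
* Predictions use the rotation R = W(P'W)^{-1}, so projecting training
  spectra reproduces the stored scores to 1e−10, and the full-rank limit
  equals OLS (verified at 1e−8 against a least-squares oracle).
* **Cumulative explained variance** for the 75% stopping rule is the
  fraction of the *centered predictor* (X) variance absorbed by the
  deflation — the convention of PLS software — rather than y-variance:
  latent extraction serves dimensionality reduction of the spectra here.
  The rule always extracts at least one component and caps at 30 (a guard
  against runaway extraction when differentiated noise dominates X; the
  cap and a `threshold_reached` flag are recorded).
* Standalone PLSR selects its component count in 1..20 by seeded shuffled
  10-fold CV maximizing mean out-of-fold R². PLS components are nested,
  so each fold is fitted once at the largest feasible count and scored at
  every truncation; ties break toward fewer components.

## Fusion models

PLS scores (75% rule) feed one of three base regressors; standalone
baselines use the full spectra. The base regressors are delegated to
scikit-learn (RandomForestRegressor, MLPRegressor) and xgboost
(XGBRegressor) behind a thin adapter — they are standard published
algorithms and re-implementation would add no fidelity. Adapter policy:

* All fits are single-threaded with explicit seeds; XGBoost uses
  `tree_method="exact"`, which at a few hundred rows is both the fastest
  and a fully deterministic choice.
* The feed-forward network receives z-scored inputs through an internal
  pipeline (Adam on raw differentiated spectra, whose scale is ~1e−3,
  converges poorly otherwise); ReLU activation, Adam solver, max 2000
  iterations, early stopping off for determinism. Non-convergence is a
  warning, not an error. Tree ensembles are scale-invariant and take the
  features as-is.
* Grid search is exhaustive over the spec'd grid with seeded shuffled
  10-fold CV, scored by R²; ties resolve to the first cell in enumeration
  order. The tuned configuration is refit on all training rows.
* The default forest grid unions the two tree-count conventions in common
  use ({50..200 by 50} and {100, 200, 300}) and includes the per-split
  feature rules sqrt, log2 and a fixed 10 (integers are clamped to the
  actual feature count, which matters when the input is a handful of
  latent scores). A `reduced` preset (1–2 values per axis) exists for
  sweeps that repeat the search across many (model, order) cells.

## Experiment orchestration

One train/validation split (validation = ceil(n/5), seeded permutation)
is drawn before any transform and reused for every order and model:
re-splitting per order would confound order effects with split noise. The
fractional derivative is row-wise, so transforming the full matrix before
row-subsetting leaks nothing across samples — the suite verifies this by
poisoning validation rows and checking all training artifacts are
byte-identical. Validation R² is computed against the validation subset's
own mean. Per-cell failures are recorded in an `error` column and excluded
from best-order selection; best order per model maximizes validation R²
with ties toward the lower order.

## Synthetic data

The generator emulates the statistical structure of a field campaign on
karst vegetation; all randomness flows from one seed and datasets are
byte-identical across runs.

**Potassium.** A lognormal truncated to [0.06, 5.87] (10 g/kg), with
(μ, σ) solved by moment matching (closed-form truncated-lognormal moments,
root-finding seeded at the untruncated solution) so the *truncated*
distribution has mean 0.81 and CV 1.30. Rejection sampling keeps the seed
contract simple. A lognormal is the simplest positive right-skewed family
consistent with the heavily skewed field distributions of foliar
potassium.

**Reflectance.** A smooth vegetation-like continuum (low visible, green
bump, red-edge rise to an NIR plateau, gentle SWIR decline), minus fixed
water absorption bands at 1450/1950 nm, minus Gaussian potassium features
whose depths grow with potassium, placed at 780, 980 and 1650 nm — inside
the 700–1100 and 1400–1800 nm regions where foliar potassium expresses —
plus i.i.d. Gaussian noise. Noiseless spectra are validated to stay in
[0, 1] across the potassium range at construction; noisy spectra are
clipped to the physical bounds.

**Default preset** (`default_config`): clean continuum, noise
sd 0.003 — every band near a feature center correlates almost perfectly
with potassium. This is the transparent configuration for unit tests.

**Derivative-sensitive preset** (`derivative_sensitive_config`): the
configuration under which the full pipeline shows the effects it exists
for, via three mechanisms chosen to mirror field reality:

1. *Smooth per-sample baseline nuisance* (brightness ±10%, tilt,
   curvature; Legendre terms) dilutes raw-spectrum correlations;
   differentiation suppresses it, so max |r| strengthens at fractional
   orders (0.33 → 0.58 at order 0.5 with the defaults) before
   differentiated measurement noise (sd 0.0008) takes over at high
   orders.
2. *Overlapping nuisance constituents*: broad absorption features at
   800/958/1672/1210 nm whose depths vary independently of potassium
   (plus ±20% per-sample water-band depth). No single band then isolates
   potassium — the maximum band |r| sits near 0.5, the weak-univariate
   regime reported for real foliar potassium — while the signal remains
   linearly separable from full-spectrum shape, which is exactly the
   regime where latent-variable extraction beats band-wise regressors and
   standalone ensembles overfit.
3. *Beer–Lambert-style saturation*: feature depths grow with
   `sat(1 − e^{−k/sat})`, sat = 3.0 (10 g/kg), making the spectra→content
   map mildly nonlinear so the ML stage on top of the latents has a role
   beyond linear regression.

An earlier design that merely *narrowed* the potassium features made
differentiation help but left single bands almost perfectly informative,
and standalone tree ensembles then matched the fusions; the
overlapping-constituent design above replaced it.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: physically based radiative transfer (leaf
structure, pigments), species/plot hierarchies and spatial
autocorrelation, wavelength-correlated instrument noise, detector seams,
and atmospheric water-vapor artifacts. Absolute metric values on the
synthetic presets are not predictions of performance on any real
campaign; only the qualitative orderings (fractional order > integer
orders, fusion > standalone) are the tested claims.

## Problem sizes in the test suite

The acceptance-style end-to-end tests run the full seven-model comparison
at orders {0.0, 0.5, …, 3.0} with the `reduced` tuning grids and n = 301
samples (~7 minutes single-threaded); the reproducibility check repeats
the seven models at a two-order subset, which exercises the identical
determinism contract at a fraction of the cost. The complete 31-order
sweep with full grids is supported (`kalium run --orders 0:3:0.1 --grids
default`) and left to users with hours rather than minutes.

## Known limitations

* PLS1 only (single response); no multi-response PLS2.
* The 75% rule's X-variance convention is one reading of
  "cumulative explained variance"; a y-variance variant would stop far
  earlier on noisy high-order spectra. The component cap (30) is an
  artifact guard with no field meaning.
* G-L boundary values at the first few bands use very short history;
  analyses sensitive to the 400–420 nm region should consider `trim`.
* Grid-search determinism relies on single-threaded fits; parallel tree
  building may reorder floating-point sums in other environments.
* The generator's noise level, nuisance amplitudes and saturation scale
  are artifact choices (no per-band variance is published for the target
  instrument class); they are documented defaults, not fitted quantities.
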