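# kalium

Fractional-derivative chemometrics for estimating leaf potassium content
from hyperspectral reflectance.

Leaf potassium is a key indicator of plant physiological status, but wet
chemistry is slow and destructive. Field spectroradiometers measure leaf
reflectance at thousands of narrow wavelengths (here 400–2500 nm on a 1-nm
grid), and potassium expresses weakly in that signal — through leaf
structure and water relations in the 700–1100 nm and 1400–1800 nm regions —
buried under smooth baseline variation and overlapping absorption by other
constituents. `kalium` implements the analysis chain that makes this
inversion work at field-campaign sample sizes (a few hundred leaves),
together with a calibrated synthetic-data generator so the whole pipeline is
testable without any proprietary spectra.

## Method

**Grünwald–Letnikov (G-L) fractional differentiation.** For a signal
sampled at unit step, the order-v derivative is the expanding-window
difference

```
(D^v x)[i] = Σ_{m=0..i} w_m x[i−m],   w_m = (−1)^m Γ(v+1) / (m! Γ(v−m+1))
```

computed here with the exact multiplicative recursion
`w_m = w_{m−1}(m−1−v)/m`. Integer v reproduces the classical difference
stencils; fractional v interpolates between them, suppressing smooth
baseline structure while preserving (and sharpening) absorption features.
Spectra are swept over v = 0.0–3.0 in 0.1 steps.

**Band-wise correlation screening.** |Pearson r| between each
differentiated band and potassium, tabulated per (order, wavelength),
locates the sensitive regions and the order at which they express most
strongly.

**PLS latent extraction.** A NIPALS PLS1 model extracts latent variables
`f_m = Σ_k w_mk z_k` whose weights follow the residual cross-covariance
X'y; extraction stops once the components explain 75% of the cumulative
predictor variance. Standalone PLSR instead selects 1–20 components by
10-fold cross-validation.

**PLSR–ML fusion.** The latent scores feed a tuned base regressor — random
forest, gradient-boosted trees (XGBoost) or a feed-forward network —
giving the fusion models PLSR-RF, PLSR-XGBoost and PLSR-MLP.
Hyperparameters are tuned by exhaustive grid search with seeded 10-fold
CV maximizing R². Standalone baselines train the same regressors on the
full 2101-band spectra.

**Evaluation.** One fixed 4/5–1/5 train/validation split is drawn before
any transform and reused across the whole (order × model) sweep; every
cell reports train and validation R², MSE and MAE, and each model's best
order is the one maximizing validation R².

## Worked example

```python
import numpy as np
import kalium as K
from kalium import synthetic_data as sd

cfg = sd.derivative_sensitive_config()       # 301 samples, 400-2500 nm
s = sd.generate_dataset(cfg)

orders = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
surf = K.correlation_surface(K.sweep_orders(s, orders))
print({o: round(float(m), 3) for o, m in zip(orders, surf.per_order_max)})

table = K.run_experiment(s, K.ALL_MODELS, orders,
                         K.ExperimentConfig(grids="reduced", seed=1))
for model, best in K.select_best(table).items():
    print(f"{model:9s} best order {best.order:3.1f}  val R2={best.r2:.3f}")
```

prints

```
{0.0: 0.331, 0.5: 0.584, 1.0: 0.327, 1.5: 0.208, 2.0: 0.198, 2.5: 0.197, 3.0: 0.188}
plsr      best order 0.5  val R2=0.941
rf        best order 0.5  val R2=0.707
xgb       best order 0.5  val R2=0.693
mlp       best order 0.5  val R2=0.426
plsr-rf   best order 0.5  val R2=0.830
plsr-xgb  best order 0.5  val R2=0.815
plsr-mlp  best order 0.5  val R2=0.961
```

Reading the output: the maximum band-potassium |r| rises from 0.33 on raw
reflectance to 0.58 at fractional order 0.5 — differentiation strips the
smooth per-sample baseline nuisance and strengthens the potassium signal —
then collapses at high orders as differentiated measurement noise takes
over. Every PLS-fusion model beats its standalone counterpart on held-out
data (0.83 vs 0.71, 0.82 vs 0.69, 0.96 vs 0.43): the standalone regressors
overfit 2101 collinear bands at n=240 training samples, while the latent
extraction compresses the spectra to a handful of informative directions
first.

The same pipeline is scriptable from the shell:

```
kalium simulate --n 301 --seed 1 --preset derivative-sensitive --out spectra.csv
kalium run --orders 0:3:0.5 --grids reduced --seed 1 spectra.csv comparison.csv
kalium report comparison.csv pivot.csv
```

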