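# eigenformer

Forecasting continuous renal biomarkers (creatinine, eGFR, BUN, ...)
from daily-aggregated longitudinal clinical records with a transformer
whose architecture is **configured by the data itself**, for
biostatisticians and clinical-ML researchers who want a small,
transparent, fully reproducible pipeline rather than a black box.

## The method

Given long-format lab events per patient, the pipeline:

1. **Cohort construction** — aggregates measurements to a daily grid
   (mean or last value per day), imputes gaps causally in three stages
   (short internal gaps ≤ 7 days by linear interpolation, longer and
   trailing gaps by last-observation-carried-forward, patients with
   > 30 % residual missingness in essential features dropped),
   z-scores features with statistics frozen on the training split, and
   cuts `(lookback L, horizon H)` regression windows with a strict
   no-look-ahead guarantee.
2. **Eigen-guided design** — computes the Pearson correlation matrix
   `C = Vdiag(λ)Vᵀ` of the training features and sets the number of
   attention heads to

   `h = min{ k : EVR_k ≥ α }`,  `EVR_k = Σ_{i≤k} λ_i / Σ_i λ_i`

   (default α = 0.95), so model width tracks the intrinsic
   dimensionality of the feature correlations.
3. **Eigenvector initialization** — head *i*'s query/key/value
   projections are tied and aligned with eigenvector `v_i` scaled by
   `λ_i^(−γ)` (γ = 0.5 whitening by default), so with positional
   encoding off the pre-softmax score of head *i* between steps *t*
   and *s* is exactly `√d_k · λ_i^(−2γ) · ⟨x_t,v_i⟩⟨x_s,v_i⟩` — each
   head starts out attending along one principal component.
4. **Depth search** — trains b = 1, 2, … blocks and stops when the
   validation-loss improvement `ΔL_val(b) = L_val(b−1) − L_val(b)`
   falls below τ = 1e-4; the selected depth `b*` is the shallowest
   depth within τ of the best.
5. **Training protocol** — Adam (lr 1e-3, weight decay 1e-4), cosine
   annealing, batch 64, dropout 0.2, MSE loss, five seeds
   (42, 100, 500, 1000, 2000) with per-seed 80/10/10 patient-level
   reshuffling; metrics reported as mean ± sample std on the z-score
   scale and in clinical units.
6. **Uncertainty and fairness** — MC-dropout (50 stochastic passes)
   Gaussian prediction intervals with an expected-vs-observed coverage
   table, and a demographic audit (age bands, sex, ethnicity) whose
   scalar summary is the worst-to-best subgroup MSE ratio.

The network itself is implemented on numpy with a compact
reverse-mode autodiff engine; models at this scale (d_model ≈ 40,
L = 7) train in seconds per epoch on one CPU.

Credentialed EHR extracts are not required: `eigenformer.synth`
generates cohorts from a latent AR(1) factor model whose population
correlation eigenspectrum is known in closed form, with controllable
missingness, demographics and planted regimes (fairness disparity,
depth-2 optimality) so every stage is testable end to end.

## Worked example

```python
from eigenformer import EigenGuidedTransformer, make_fixture

cohort = make_fixture("default", seed=1)       # 1000 synthetic patients
model = EigenGuidedTransformer.from_tables(cohort.events, cohort.demographics,
                                           target="creatinine")
res = model.fit(seed=42, depth="search", epochs=20)
print(res.summary())
```

```
Eigen-Guided Transformer Results
======================================================
Target feature:               creatinine
Lookback / horizon (days):    7 / 1
Features (d):                 8
Patients (train/val/test):    800/100/100
Sequences (train/val/test):   5583/742/736
------------------------------------------------------
Variance threshold alpha:     0.95
Attention heads h:            5  (EVR at h: 0.961)
Blocks b*:                    1  (stopped at 2)
d_model / d_k / d_ff:         40 / 8 / 80
Parameters:                   13,481
Forward FLOPs (M):            0.19
------------------------------------------------------
Test MSE (normalized):        0.3847
Test MAE (normalized):        0.4977
Test MSE (clinical units^2):  0.3158
Test MAE (clinical units):    0.4510
Target sigma (clinical):      0.9060
Best epoch / val loss:        11 / 0.3810
======================================================
```

The head count (5 of 8 possible) is the smallest component count
covering 95 % of training-feature variance.  On this cohort the target
is a linear factor readout, so one block already reaches the noise
floor and the τ rule stops immediately (`b* = 1`); on the
planted-depth cohort, whose signed two-lag target a single attention
profile cannot represent, the same search recovers `b* = 2` (see
`docs/methods.md`).  The test MSE approaches the generator's
irreducible forecast variance (≈ 0.35 normalized).
`res.calibration()`, `res.fairness()` and `res.attention()` return the
coverage table, the subgroup table with its disparity ratio, and
head-averaged temporal attention maps.

A CLI mirrors the library (`eigenformer synth | prepare | design |
fit | protocol`).

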