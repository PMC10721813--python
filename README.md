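# hybridts

Hybrid linear + nonlinear forecasting for annual agricultural yield
series, built around the additive decomposition

```
y_t = L_t + N_t,        e_t = y_t - L̂_t,        ŷ_t = L̂_t + N̂_t
```

A linear ARIMA/ARIMAX stage captures the trend, autocorrelation and the
effect of an exogenous covariate (here: area under irrigation, in
percent); its one-step residuals are screened for non-linearity with the
BDS test and handed to one of six nonlinear learners — TDNN, NLSVR, WNN,
CNN, RNN or LSTM — whose recursive multi-step forecast of the residual
series is added back to the linear forecast.  The package is aimed at
analysts comparing classical, machine-learning and hybrid forecasters on
short (≈70-point) trending annual series with a chronological holdout.

## What's inside

| module | role |
| --- | --- |
| `series_io` | year-indexed dataset type, CSV I/O, differencing, holdout split |
| `diagnostics` | descriptives, Pearson correlation, ADF unit-root test, BDS non-linearity test (from correlation integrals) |
| `linear_arimax` | ARIMA/ARIMAX exact-ML fitting (φ(B)∇ᵈy_t = μ + βx_t + θ(B)ε_t), order selection by AIC/BIC/holdout error, forecasting |
| `nonlinear_learners` | lag embedding, the six learners with exact trainable-parameter accounting, grid search |
| `hybrid_pipeline` | the additive hybrid and the canonical 14-model study on a shared split |
| `evaluation` | RMSE / MAPE (Eq.-style: RMSE = √(Σ(y−ŷ)²/n), MAPE in %), accuracy tables, improvement summaries |
| `synthetic_data` | seeded generator of yield-like series with known latent linear/nonlinear decomposition |
| `cli` | `hybridts` command: describe, adf, bds, fit, fit-hybrid, compare, evaluate, forecast, simulate, reproduce-abstract |

The MA polynomial is reported in the subtraction convention
θ(B) = 1 − Σθ_jB^j; the five network learners are small NumPy networks
trained with Adam (seeded, bitwise reproducible), and NLSVR is an
RBF-kernel ε-insensitive support vector regression.

## Worked example

```python
import hybridts as ht

# a wheat-like synthetic series: 70 years, strong trend, irrigation-like
# exogenous percentage, a nonlinear component in the increments
synth = ht.generate(ht.default_crop_profiles()["wheat-like"])
ds = synth.dataset
split = ht.split_holdout(ds, 7)          # last 7 years held out

print(ht.select_differencing(split.train))   # -> 1
r, p = ht.pearson_correlation(ds.y, ds.x)
print(round(r, 3))                           # -> 0.937

lin = ht.LinearModelSpec(order=ht.ArimaOrder(0, 1, 1), exogenous=True)
spec = ht.HybridSpec(linear=lin,
                     residual_learner=ht.NLSVRSpec(lags=3),
                     bds_gate="advisory")
fit = ht.fit_hybrid(ds, split, spec, ht.TrainingConfig(seed=1))
yhat = ht.forecast_hybrid(fit, 7, future_exog=split.test.x)
print(round(ht.rmse(split.test.y, yhat), 2)) # -> 321.63
```

The printed numbers mean: the level series needs one difference to
become stationary; yield and irrigation share correlate at r ≈ 0.94; and
the hybrid's holdout RMSE is in the units of the response (kg/hectare
for the emulated series).  A full 14-model comparison on the same split:

```
hybridts simulate --profile wheat-like --seed 3 --out sim.csv
hybridts compare --input sim.csv --response yield --exog irrigation_pct \
         --seed 1 --csv accuracy.csv
hybridts evaluate --accuracy-csv accuracy.csv --reference ARIMAX-LSTM
```

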