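# thermoyield

Thermal-time crop condition indices and leakage-safe yield-anomaly
forecasting for administrative regions.

`thermoyield` is aimed at agricultural-monitoring analysts who combine daily
satellite vegetation indicators (NDVI, land-surface temperature) with
meteorological reanalysis to forecast regional crop yields from very short
yield records (a handful of years per region). It implements the full chain
as a tested library plus a thin CLI, and ships a synthetic-data generator
with a known generative model so that every stage — including the
cross-validated forecasting skill — can be verified against ground truth.

## The method

**Thermal time.** Daily weather is converted to growing degree days with
crop-specific base temperature `T_b` (5 °C for winter wheat and winter
rapeseed, 10 °C for maize) and a 30 °C cap:

    GDD_d = Σ_{i≤d} max(0, (min(T_x,i, 30) + max(T_n,i, T_b)) / 2 − T_b)

Satellite observations are re-indexed from calendar dates to cumulative GDD,
so the same coordinate refers to the same crop development stage in every
year, and are read off a milestone grid of 150, 300, …, 1200 °C·day (eight
levels).

**Condition indices.** At every milestone, NDVI and LST are scaled against
their multi-year min–max envelopes into Kogan's indices on a 0–100 scale:

    VCI = 100 (NDVI − NDVI_min) / (NDVI_max − NDVI_min)
    TCI = 100 (LST_max − LST) / (LST_max − LST_min)

**Spatial aggregation.** Gridded products are averaged to administrative
units after screening pixels with arable-land fraction below 30 %, weighting
each surviving pixel by arable fraction × unit-coverage fraction.

**Crop-mask post-processing.** Where two satellite orbits disagree on a
field's crop, the label is resolved from the per-orbit classification
probability `p` and the regional presence prior `q` (higher `p` *and* `q`
wins; otherwise the higher-`p` crop is kept only if its `p` advantage
exceeds its `q` deficit). Fields whose mid-May–June NDVI stays below 0.4 in
a majority of images are reclassified as unsown.

**Forecasting loop.** One row per (unit, year), 105 predictors (13 variables
× 8 GDD levels + seasonal max NDVI). Yields are modelled as anomalies from
each unit's mean via gradient boosting after min-max scaling, removal of
predictor pairs with |r| > 0.75 and recursive importance-based feature
elimination — with **every** step recomputed inside each leave-one-year-out
fold, so no fold ever sees its own answer. Skill is reported as R² (squared
Pearson correlation), MAE, RMSE and MAPE.

## Worked example

```python
import thermoyield as ty

config = ty.SyntheticConfig(seed=42)   # 30 units, years 2018-2022
result = ty.run_synthetic_study(config, snr=3.0)

print("held-out skill over", len(result.cv.predictions), "unit-years")
for name, value in result.cv.metrics.items():
    print(f"  {name:8s} {value:8.3f}")
print("true drivers recovered in "
      f"{100 * result.true_feature_selection_rate:.0f}% of folds")

anomalies = ty.yield_anomaly_table(result.yields, 2022, "five_year_mean")
print(anomalies.head(3).round(2).to_string(index=False))
```

prints

```
held-out skill over 150 unit-years
  mae         0.176
  rmse        0.229
  r2          1.000
  r2_sse      1.000
  mape        0.335
true drivers recovered in 100% of folds
unit_id  value_current  value_reference  percent_change
unit000          75.50            75.82           -0.42
unit001          47.00            46.24            1.63
unit002          90.41            89.60            0.91
```

Yields here were generated as `baseline + 0.8·TCI_gdd600 + 0.5·sm_7_28_gdd300
+ noise` (signal-to-noise ≈ 3, units dt/ha). The cross-validated loop
recovers the signal almost perfectly — MAE 0.18 dt/ha against a noise floor
of ≈ 0.09 dt/ha — and names the two true driver predictors in every fold.
The anomaly table uses the convention that −20 % means the year reached 80 %
of the five-year reference yield.

The same pipeline is available from the shell:

```bash
thermoyield synth --config cfg.yaml --out data/      # write synthetic inputs
thermoyield run   --config cfg.yaml --out results/   # predictions + metrics
thermoyield report --what yield-change --out results/
```

## Layout

- `src/thermoyield/thermal_time.py` — GDD accumulation, milestones, resampling
- `src/thermoyield/condition_indices.py` — envelopes, VCI/TCI
- `src/thermoyield/spatial_aggregation.py` — arable-weighted zonal means
- `src/thermoyield/crop_mask_fusion.py` — orbit overlap resolution, unsown rule
- `src/thermoyield/yield_model.py` — predictor matrix, selection, LOOCV
- `src/thermoyield/reporting.py` — GDD differences, percent yield change
- `src/thermoyield/synthetic_data.py` — the generative model behind all tests
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
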