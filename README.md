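# smokepm

Hourly surface PM2.5 estimation during a wildfire episode, by fusing
regulatory monitors with calibrated low-cost sensors, geostationary
satellite aerosol products and high-resolution meteorology in a weighted
random forest — with minority oversampling to fight underestimation of the
rare, health-relevant high concentrations.

## Who this is for

Exposure modelers and air-quality researchers who need hourly PM2.5
surfaces during smoke episodes, where regulatory networks are too sparse
(and report too intermittently) to resolve a moving plume, and low-cost
sensor networks are dense but biased. The package provides the full
pipeline as a library plus a seeded synthetic study domain, so every stage
is testable end to end against known truth without any data downloads.

## The method

1. **Calibration.** Low-cost sensors within 500 m of a regulatory monitor
   form hourly collocated pairs. Geographically weighted regression fits,
   at each collocation site s, weighted least squares

   `PM_AQS = β₀(s) + β₁(s)·PM_sensor + β₂(s)·T + β₃(s)·RH + β₄(s)·uptime + β₅(s)·optime`

   with Gaussian spatial kernel weights; coefficients transfer to all
   sensors by kernel-weighted averaging.
2. **Fusion.** Sub-hourly AOD is averaged (valid retrievals) and detection
   masks OR-ed per cell-hour; meteorology points join the grid by an
   injective nearest-neighbor match; ground values deduplicate to one per
   cell-hour (regulatory supersedes low-cost; weights 1.0 vs 0.15).
3. **Features.** Each cell-hour's predictor vector adds a "convolutional
   layer": the inverse-distance-weighted average of the five nearest
   same-hour measurements (the cell's own measurement excluded in
   training).
4. **Model.** A random forest (500 trees, m_try = ⌈√p⌉, node size 5, depth
   20) whose bootstrap samples each observation with probability
   proportional to its weight. The SMOTE variant additionally interpolates
   two synthetic rows per minority observation (target ≥ 100 μg/m³)
   between minority nearest neighbors — training folds only.
5. **Validation.** Out-of-bag metrics, 10-fold temporal blocked CV, and
   spatial leave-ten-monitors-out CV with Hilbert-curve round-robin groups;
   R² is the squared Pearson correlation of measured vs predicted, and the
   high-range slope (measured ≥ 100 μg/m³) diagnoses smoke-peak
   underestimation.

## Worked example

```python
import smokepm as sp

# synthetic wildfire episode: 40x40 grid of 3x5 km cells, 240 hours,
# 30 regulatory monitors + 240 clustered low-cost sensors
data = sp.run_pipeline(sp.DomainConfig(), seed=0)

model = sp.SmokePM25Model(data.features, variant="aqs_pa",
                          forest=sp.ForestConfig(n_trees=40, seed=0))
results = model.fit()
print(results.summary())

plan = sp.make_spatial_folds(model.table, group_size=10)
cv = sp.cross_validate(model, plan)
print(cv.summary())

surf = sp.predict_hour(results, data.fused, data.ground,
                       data.domain.grid, data.domain.config, hour=30)
sp.export_surface(surf, data.domain.grid, "surface_h30.csv", format="csv")
```

This prints (seed 0):

```
Weighted Random Forest PM2.5 Results
============================================
variant:            aqs_pa
training rows:      22425 (0 synthetic)
trees / m_try:      40 / 5
min node / depth:   5 / 20
--------------------------------------------
OOB R2:             0.982
OOB RMSE:           3.74 ug/m3
slope / intercept:  0.963 / 0.56
high-range slope:   0.877 (n=430)

spatial_leave_ten_out CV, variant=aqs_pa: R2=0.975 RMSE=4.54 ug/m3
slope=0.936 intercept=0.91 high-range slope=0.795 (n=453)
```

Read: on held-out monitors the fused model explains ~97% of the variance
with ~4.5 μg/m³ RMSE, but the cross-validated high-range slope of 0.80 says concentrations
above 100 μg/m³ are still underestimated by ~20% — the gap the SMOTE
variant (`variant="aqs_pa_smote"`) narrows.

A command-line interface mirrors the library:
`smokepm simulate --config cfg.yaml --seed 0 --out dir/`,
`smokepm train --features dir/features.csv --variant aqs_pa`,
`smokepm cv --features dir/features.csv --scheme spatial --variant aqs_pa_smote`.

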