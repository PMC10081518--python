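# Methods

`smokepm` implements an hourly surface-PM2.5 estimation pipeline for a
wildfire episode, together with a synthetic study domain that reproduces the
statistical structure such an episode presents to the method. This note
records the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic experiments do and do not demonstrate.

## The estimation problem

Ground truth for surface PM2.5 during a major fire is sparse: regulatory
monitors (AQS-type) are unbiased but few and report intermittently (about
six hourly values per station per day), while low-cost optical sensors
(PurpleAir-type) are dense but clustered in populated areas and biased. The
pipeline fuses both networks with satellite aerosol retrievals (AOD and
detection masks), assimilated meteorology and static land-use covariates on
a 3 × 5 km modeling grid, and fits a weighted random forest to predict PM2.5
at every cell-hour where all predictors are present.

## Pipeline stages

**Sensor calibration (GWR).** Sensors within 500 m of a regulatory monitor
form hourly collocated pairs. At each collocation site the regulatory value
is regressed on (1, sensor PM2.5, temperature, relative humidity, uptime,
operating time) by weighted least squares with Gaussian spatial kernel
weights, giving coefficient surfaces that vary smoothly in space. Choices
the method itself leaves open, decided here: Gaussian kernel; bandwidth by
leave-one-station-out CV RMSE over a logarithmic ladder (5–500 km, 8 rungs)
when `bandwidth='auto'`; coefficients transferred to non-collocated sensors
as kernel-weighted averages of anchor coefficient vectors; calibrated values
floored at 0 μg/m³ (physical non-negativity); a locally rank-deficient
design widens that anchor's kernel by doubling (at most five times) before
failing. With a single anchor and infinite bandwidth the fit reduces exactly
to OLS, which the tests exploit.

**Grid fusion.** Sub-hourly satellite records are aggregated per cell-hour:
AOD as the mean of valid retrievals, binary masks by the any-rule (they are
detections); zero valid records yield nulls. Meteorology points are joined
to cells injectively: candidate (point, cell) pairs are scanned in
increasing great-circle distance (ties by point id, then cell id) and taken
greedily while both members are free, so no two points share a cell; cells
left over inherit their nearest assigned cell's point and are flagged.
Ground observations are deduplicated per cell-hour: any regulatory value
present ⇒ regulatory values averaged, weight 1.0; otherwise sensor values
averaged, weight 0.15. After gridding, all same-cell stations necessarily
act as one monitor; each cell carries a representative station id (lexically
first contributor on the winning network) so spatial cross-validation moves
a cell's rows as a unit.

**Convolutional layer.** Each cell-hour receives the inverse-distance
weighted average of the nearest five same-hour ground measurements,
distances taken between cell centers. For a training row the cell's own
measurement is excluded — including it would hand the model its own label.
For prediction rows all same-hour measurements are eligible (the cell has
none of its own). Fewer than five neighbors ⇒ all available; none ⇒ the row
is incomplete; an exact zero distance returns that value.

**Weighted random forest.** Regression trees are grown on bootstrap samples
drawn with selection probability proportional to the observation weight
(0.15 for sensor-derived rows, 1.0 for regulatory rows), which realizes the
down-weighting through the bagging mechanism rather than the split
criterion. Defaults: 500 trees, m_try = ⌈√p⌉ predictors per split, minimum
node size 5, maximum depth 20. Split search and tree growth delegate to
scikit-learn's `DecisionTreeRegressor`; the bootstrap, the out-of-bag
accounting (a row's OOB prediction averages only trees whose bag excluded
it) and OOB permutation importance are implemented here because the
weighted bootstrap is part of the method's contract.

**SMOTE for the continuous target.** Rows at or above 100 μg/m³ (inclusive)
are the minority. For each minority row, two synthetic rows (default) are
drawn by interpolating toward one of its five nearest minority neighbors
with a Uniform(0,1) gap; the target is interpolated along with the
continuous predictors, binary masks are copied from the seed row, and the
seed's weight, network and coordinates are inherited (a synthetic
sensor-derived point should not gain regulatory-level trust). Neighbor
search runs in z-scored continuous-predictor space over the minority subset
only (classical SMOTE; units are otherwise incommensurable), with spatial
coordinates and hour excluded from the metric — they are bookkeeping, not
predictors. The count law |out| = |in| + 2·|minority| is exact. Per-row RNG
streams are keyed on (cell, hour), so permuting the input permutes only the
output order.

**Cross-validation.** Temporal: rows sorted by (hour, station) are cut into
10 contiguous blocks whose sizes differ by at most one. Spatial: monitors
ranked along a Hilbert curve over lon/lat are dealt round-robin into groups
of ten, so adjacent monitors land in different groups and every group spans
the domain (the stated goal is spatial heterogeneity within a group; the
curve-plus-round-robin construction is this package's choice). All of a
monitor's rows travel with its group. SMOTE, when configured, is applied
inside each fold's training part only; metrics are always computed on
pooled held-out original rows — synthetic rows are never scored. For the
full (non-CV) SMOTE fit, OOB metrics are computed over all training rows
including synthetic ones; this choice is documented because OOB and CV
metrics are therefore not directly comparable for that variant.

**Evaluation.** R² is the squared Pearson correlation of measured vs
predicted (matching the scatter-plot-with-regression-line presentation);
RMSE in μg/m³; slope/intercept from OLS of predicted on measured; the
high-range slope repeats the OLS on the subset measured ≥ 100 μg/m³ and is
the diagnostic for underestimation of smoke-impacted concentrations.

## The synthetic domain

The generator is seeded and fully deterministic: every output is a pure
function of (config, seed).

* **Grid** — 40 × 40 cells of 3 × 5 km (desk-scale stand-in for the real
  40,578-cell state grid), lon/lat cell centers, great-circle distances.
* **Truth field** — background PM2.5 as exponentiated space-time-smoothed
  Gaussian noise, moment-matched to mean 9 / sd 6 μg/m³ (positive and
  right-skewed by construction), plus a Gaussian plume (amplitude 400
  μg/m³, σ = 11 km) whose amplitude follows an ignition-ramp/diurnal/decay
  intensity profile and whose center sweeps the domain under a prevailing
  easterly with an Ornstein–Uhlenbeck meander; the advecting wind is
  derived from the track so x_{t+1} = x_t + u·Δt holds exactly. Smoothing
  is periodic so the field's variance is stationary (no inflated edges).
* **Networks** — 30 regulatory monitors placed by farthest-point sampling
  (quasi-uniform), reporting each hour with probability 0.25 (≈ 6/24),
  value = truth + N(0, 1) clipped at 0; 240 sensors in 8 spatial clusters
  (σ = 4 km), 12 of them within 50–400 m of a regulatory monitor to supply
  collocations, reporting with probability 0.97, value = truth + 0.9 +
  0.02·RH + N(0, 2) clipped at 0. With mean sensor-site RH near 50% the
  raw network bias averages ≈ +1.9 μg/m³. Sensors carry diurnal
  temperature/RH trajectories, uptime (hours since a Poisson-process
  reboot) and operating time (install age plus elapsed days). The
  regulatory noise level is a parameter (1 μg/m³ default), not an asserted
  fact.
* **Satellite** — three sub-hourly slots per hour (desk-scale stand-in for
  5-minute retrievals); AOD = 0.01·truth + N(0, 0.05) clipped at 0, with
  retrieval failure probability rising from a 0.15 floor toward ~1 as the
  column thickens (informative missingness inside the plume, mirroring
  retrieval failure under heavy aerosol loading); smoke mask fires where
  the plume component exceeds 5 μg/m³ with 92% per-slot detection; masks
  carry their own 10% validity dropout.
* **Meteorology** — one point per cell jittered off-center (so the
  injective join is non-trivial): 2-m temperature with diurnal cycle and
  lapse against elevation, hydrostatic pressure, winds equal to the
  plume-advecting wind plus smooth perturbation, diurnal boundary-layer
  height, RH anti-correlated with temperature.
* **Static covariates** — smooth elevation, road-distance and four
  land-use-fraction fields (softmax-normalized).

Plume amplitude and width were fixed once so that the share of ground
observations at/above 100 μg/m³ averages ≈ 2% and stays within 1–4% for
every seed — the imbalance regime the augmentation step exists for.

**What the generator does not emulate:** fire emission physics or
chemistry, real retrieval QA-flag semantics, terrain-channelled winds,
sensor dropouts correlated with smoke, population-weighted sensor
placement, and the real grid's coastline geometry. Passing tests therefore
demonstrate that the pipeline's logic is correct and that its qualitative
structure (sensor fusion helps; SMOTE reduces high-range underestimation)
is recovered when the data genuinely contain it — not that the real-data
performance numbers would be reproduced.

## Problem sizes used by tests and the reproduction script

Unit and property tests run on a reduced 20 × 20 × 48 h domain. The
variant-comparison experiment (and `scripts/acceptance.py`) runs the full
default 40 × 40 × 240 h domain over five seeds with 40-tree forests under
spatial leave-ten-monitors-out CV: the variant ordering is a property of
the data composition, not of ensemble size, and 40 trees already give
stable pooled CV metrics (the 500-tree default remains for production
fits). Bandwidth for the pipeline's calibration stage defaults to a fixed
50 km rather than the CV ladder, which is exercised separately.

## Known limitations

* The greedy distance-ordered injective match is not guaranteed to minimize
  total distance (the contract is injectivity plus nearest-first
  preference); tests bound its cost against the exhaustive optimum on small
  instances.
* GWR anchors exist only at collocation sites; with few collocated sensors
  the coefficient surface is close to globally constant.
* OOB metrics for the SMOTE variant include synthetic rows (see above).
* Predictions are floored at 0 μg/m³; no uncertainty quantification is
  attached to the surfaces.
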