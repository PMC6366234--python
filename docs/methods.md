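# Methods

This note documents the methods implemented in `upliftscape`: how the
synthetic study is generated, how uplift presences and absences are derived
from biologging data, and how the suitability, intensity, and energy models
are fitted. It is the package's own methodological account; module and
function names refer to the public API.

## 1. Synthetic landscape and tracking data (`synthetic`)

Real analyses of this kind run on continental raster stacks and multi-year
tracking archives that cannot be redistributed. The package therefore ships
a seeded generator producing both the environment and the data, with the
ground truth retained so that every downstream claim can be verified.

**Landscape.** `generate_landscape(seed, shape)` builds a co-registered
100 m raster stack: a digital elevation model composed of smoothed Gaussian
random fields plus ridge structures, NDVI and land-use layers correlated
with elevation, an urban-footprint layer, and thermal/orographic potential
layers. From the DEM the generator derives the same terrain layers the
analysis will later recompute (slope, aspect, roughness, topographic
position, unevenness). The *planted truth* is a logistic uplift probability
field

p_uplift = σ(β₀ + 2.0·z(roughness) + 1.4·z(dem) − 1.6·z(ndvi)),

so that roughness, elevation, and NDVI are by construction the informative
static predictors, and an uplift intensity field (expected climb rate on
uplift-positive cells) that depends on thermal potential and sinusoidally on
aspect.

**Flight simulator.** `simulate_tracks` moves each bird through a day as a
renewal process of behavioural bouts — circular soaring (climbing in
thermals, high turning), linear soaring (slope soaring, climbing with low
turning), gliding (descending, straight), flapping (level, straight, high
dynamic body acceleration), and resting. Bout initiation probabilities
depend on the local planted uplift probability, so soaring concentrates
where uplift is available and flapping where it is not. Bout-rate
parameters are calibrated once (`_budget_params`) so that the *realized*
time budget matches the study conditions: about 0.51 of flight time
soaring and about 0.05 of accelerometer bursts flapping. These budgets are
fixed properties of the simulated population, not tuning knobs.

**Sampling schedules.** GPS is recorded as 1 Hz bursts of 5 min every
15 min with configurable Gaussian position/altitude noise; tri-axial
accelerometer bursts of 40 samples per axis at 10.54 Hz are recorded every
10 min. Behaviour labels per GPS fix and per ACC burst are kept in a
separate truth object that the analysis code never reads.

**I/O.** Rasters are stored as ESRI ASCII grids; GPS and ACC tables as
Movebank-dialect CSV (`io.read_gps_csv`, `io.read_acc_csv`, and writers).

## 2. Terrain predictors (`terrain`)

Slope and aspect are computed with Horn's 3×3 third-order finite-difference
method; any window containing a missing cell yields a missing derivative
(no silent fill). Roughness is the largest absolute elevation difference to
the eight neighbours, topographic position index is the centre minus the
neighbour mean, and terrain unevenness is the standard deviation of slope in
a 3×3 window. `check_multicollinearity` screens predictor pairs at sampled
locations and reports pairs with |Spearman ρ| above a threshold (0.7 by
default) so one of each pair can be dropped before modelling.

## 3. Behavioural segmentation of GPS bursts (`segmentation`)

Each GPS burst is divided into consecutive non-overlapping 15 s segments
(incomplete trailing windows dropped; bursts shorter than 120 s are
ineligible). Per segment, the mean vertical speed (forward differences of
altitude) and mean absolute turning angle (heading change, wrapped to
[0°, 180°]) are computed.

`embc_classify` implements expectation–maximization binary clustering: for
each variable independently, a two-component 1-D Gaussian mixture is fitted
by EM (deterministic median-split initialization) and a *delimiter* — the
equal-posterior point between the component means — splits the variable
into low/high. The low/high quadrant then labels the segment: high turning
→ circular soaring; otherwise positive-climb regime → linear soaring;
otherwise gliding. Two guards prevent degenerate splits: if the high-turning
component mean falls below 90° the data contain no circling regime, and a
vertical-speed regime with non-positive mean can never produce soaring
labels.

Labels are then smoothed: a segment whose label differs from all four
neighbours (two before, two after, within the same burst) is reassigned to
the window mode; ties keep the original label. Finally,
`extract_soaring_events` turns runs of soaring segments longer than 30 s
into events, merging runs separated by gaps shorter than 60 s; the event
location is the mean position of the member fixes. Events are the *uplift
presences*.

## 4. Accelerometer processing (`acc`)

ODBA per burst is the sum over the three axes of the mean absolute
deviation from the per-axis burst mean (the static component). Bursts are
clustered into three activity tiers by k-means on standardized ODBA;
the most-active tier corresponds to flapping flight. Bursts are geolocated
by temporal midpoint interpolation between the bracketing GPS fixes,
rejected when the bracketing gap exceeds 30 s or falls outside a bird's GPS
span, and assigned height above ground from the DEM. `select_flapping`
keeps most-active bursts strictly higher than 100 m above ground: flapping
at altitude means the bird found no atmospheric support there. These are
the *uplift absences*.

## 5. Uplift suitability (`suitability`)

`assemble_observations` extracts the static predictors at presence and
absence locations (frameworks: `static`, thermal/orographic `potential`, or
`combined`). `fit_rf_cv` fits an ensemble of random forests (default 500
trees, √p features per split) over 10 random 90/10 train/test splits,
recording train/test AUC, and sensitivity, specificity, and true skill
statistic (TSS = sensitivity + specificity − 1) at the max-TSS threshold
chosen on the training scores (ties resolved toward the larger threshold).
Variable importance is permutation-based mean accuracy decrease (MSE
increase), averaged across runs, with node-purity increase reported
alongside.

`predict_map` averages the ensemble's probability predictions over the
raster stack, masks cells where any predictor lies outside the ranges seen
in training (no extrapolation), and binarizes at the mean max-TSS
threshold. Model skill is validated in the tests against the planted field:
held-out AUC, recovery of the three planted predictors among the top
importances, a shuffled-label null at AUC ≈ 0.5, and agreement of the
suitable-area fraction with the planted prevalence under uniform sampling.

## 6. Uplift intensity (`intensity`)

Within soaring events, per-fix vertical speeds are averaged onto the 100 m
grid; non-positive cell means are dropped, and cells above the 99.97th
percentile are removed as outliers. A Gaussian GAM
(`fit_gam`) models mean climb rate with a cyclic cubic smooth for aspect
(period 360°, so the fitted curve is continuous across north), B-spline
smooths for the remaining continuous predictors, and parametric terms for
land-use classes and optional thermal/orographic potentials. Smoothing
weights are selected by coordinate-wise generalized cross-validation;
`compare_gams` ranks candidate frameworks by AIC. `intensity_map` predicts
expected climb rate on cells the suitability map classifies as suitable and
leaves unsuitable or unclassified cells missing.

## 7. Energy landscape (`energy`)

`build_daily_records` reduces the data to one record per bird-day: the mean
ODBA of flight bursts (the energy proxy) and the mean predicted uplift
suitability at the locations of those bursts, excluding bursts on
unclassified cells and days with too few usable bursts.
`fit_energy_model` fits a linear mixed-effects model (maximum likelihood)
of daily mean ODBA on daily mean suitability with a random intercept per
individual, and the same model without the slope as a null; ΔAIC = AIC −
AIC_null quantifies the evidence. A negative fitted slope is the
energy-landscape result: birds expend more energy on days spent over
terrain with little predicted uplift.

## 8. Pipeline and reproducibility

`run_pipeline(seed, ...)` chains all stages from a single seed and returns
every intermediate object plus runtime; with an output directory it writes
the rasters, tables, and a `summary.json` including a landscape checksum.
All stochastic components (landscape, simulator, k-means, forest splits)
take explicit seeds derived from the pipeline seed, so any run is exactly
reproducible.

## Limitations

The simulator is a deliberately simplified renewal model: it omits wind
drift, diurnal thermal cycles, and route-level decision making, and the
planted uplift field is static while real uplift varies within days. The
synthetic absences are scarcer than presences (flapping at altitude is
rare), which limits attainable model skill at small sampling efforts;
longer tracking windows recover it. Geolocation of accelerometer bursts by
midpoint interpolation is only as accurate as the GPS duty cycle allows.
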