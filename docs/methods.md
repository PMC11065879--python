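# Methods

This note documents the models, numerical choices and assumptions
behind `phenomigrate`, and what the synthetic test bed does and does
not establish about real satellite data.

## Temporal regularization

Optical observations arrive irregularly (a 5-day revisit thinned by
clouds). All curve analysis happens on a fixed day-of-year grid
covering the growing season, DOY 90–318, in 10-day bins with centres at
DOY 95, 105, …, 315 (23 bins). Each bin takes the **median** of its
valid observations — robust to residual cloud outliers and exact for
constant signals.

Remaining empty bins are filled with the quadratic Newton
divided-difference interpolant through the three nearest observed bins.
This is exact on polynomials of degree ≤ 2, which is the testable
content of the published formula it implements (whose printed
divided-difference notation with repeated nodes is internally
inconsistent; we adopt the quadratic-interpolant reading). One
deliberate deviation: for bins **outside** the observed time span the
quadratic becomes an extrapolation whose error grows without bound in
the presence of noise (we observed negative reflectance at grid edges),
so boundary bins default to nearest-value extension
(`fill_gaps(..., edge="quadratic")` restores full extrapolation).

Smoothing is Savitzky–Golay with a 7-bin window and quadratic
polynomial (no parameters are prescribed by the protocol; 7 × 10-day
bins ≈ a 70-day window preserves a 100–150-day season peak while
suppressing bin-level noise). Edges are handled by evaluating the
boundary polynomial fit (scipy's `interp` mode). Bands are smoothed
first and indices computed from the smoothed bands (configurable); the
alternative order is available by regularizing an `IndexSeries`
directly.

## Indices

The nine optical indices follow their published formulations, with two
conventions worth noting:

* **OSAVI** is implemented as printed in the source protocol,
  `1.16 (ρ_NIR − ρ_red) / (ρ_NIR + ρ_SWIR1 + 0.16)`. The SWIR1 term in
  the denominator deviates from the standard OSAVI (which uses ρ_red);
  the `osavi_standard` flag switches to the standard form. The default
  follows the printed form so that CCI values are comparable with the
  protocol's.
* **SAR channel combinations** (ratio, sum, RVI) are computed in linear
  power after converting from decibels, since a dB-domain "sum" has no
  physical meaning; `db_domain=True` preserves a dB-domain variant for
  sensitivity checks. VH and VV pass through in dB.

Any denominator below 1e-9 in magnitude yields a missing value, never
±inf; isolated missing bins in derived index curves are refilled by the
same divided-difference interpolation.

## Phenology

POS is the bin centre of the global EVI maximum (earliest on ties).
SOS/EOS use the amplitude-median rule: the level
`min + 0.5 (max − min)` over the grid window, with SOS the last upward
crossing before POS and EOS the first downward crossing after it,
linearly interpolated between bin centres and clamped to the grid edge
when no crossing exists. The amplitude base is the **global** minimum
over the window (the precise variant is unspecified in the protocol;
the global minimum is deterministic and robust for single-season
curves). A flat curve (amplitude < 1e-6) has no extractable season and
raises an error. Double-cropping (two peaks) is out of scope.

Seasonal integrals use the trapezoidal rule on the piecewise-linear
gridded curve with interpolated fractional endpoints — exact for
piecewise-linear curves and linear in the integrand, which the tests
exploit.

## The migration model

The screening assumes the reference soybean integral vectors follow a
3-D multivariate Gaussian per group. Parameters are the sample mean and
sample covariance (ddof = 1); if the covariance condition number
exceeds 1e8 a ridge of `1e-6 · tr(Σ)/3` is added (small survey sets
with correlated integrals can be near-degenerate). At least 30
reference points are required to fit a 3-D Gaussian; below that the fit
aborts with guidance rather than silently degrading.

The density threshold p₅₀ is estimated by Monte Carlo with
n_mc = 100 000 seeded draws: the median sampled density, equivalently
the density at the median Mahalanobis radius r₅₀. For a 3-D Gaussian
the closed form is r₅₀ = √(χ²₃ median) ≈ 1.5382 and
p₅₀ = (2π)^(−3/2) |Σ|^(−1/2) e^(−1.183); the Monte-Carlo route is kept
as the documented method and the closed form serves as the test oracle.
Distances are computed through a Cholesky factorization of Σ (no
explicit inverse).

Thresholds: soybean admission at the 90th percentile of the robust
(above-p₅₀) references' distances; non-soybean rejection at the 95th
percentile of **all** reference distances, applied symmetrically to
both groups (the low-group non-soybean threshold is stated incompletely
in the source protocol; symmetry with the high group is the natural
completion). Thresholds are always computed per group model and never
shared across regions or years. The decision rules are conjunctions:
soybean requires CCI < 0 and both distances under the soybean
thresholds; non-soybean requires both distances over the non-soybean
thresholds regardless of CCI (as specified — a convex-curve outlier far
from the soybean cloud is a valid non-soybean sample). The screen is
precision-oriented by construction: with thresholds at the 90th
percentile of the central half, only ≈ 20 % of true soybean candidates
are admitted, which is intended — migrated labels seed a classifier, so
label purity matters far more than label count.

When several survey collections are available, selection priority is:
same region (temporal migration, nearest year), then same year from the
climatically nearest region (spatial), then nearest year and zone
(spatiotemporal); ties break on smaller year gap, then lexicographic
region id.

## Features and classification

The feature inventory is fixed at 119: six statistics (min, max, std,
15/50/90th percentiles, linear-interpolation definition) for five index
curves and five band curves (60); SOS/EOS/LOS (3); amplitude and phase
of the first two harmonics of EVI (4); green-up and senescence EVI
integrals, split at POS (2); seven statistics (adding the mean) for
five SAR parameters (35); and the first three temporal
principal-component scores per SAR parameter (15). The harmonic model
`a + b·t + Σ C_m cos(2πmωt) + D_m sin(2πmωt)`, ω = 1/365, is fitted by
ordinary least squares to the raw valid observations. Temporal PCA
centres time columns and fixes eigenvector signs by making the
largest-magnitude loading positive, so scores are reproducible.

Feature selection keeps the top half by the impurity importance of a
seeded random forest. Training follows the fixed protocol: stratified
50/50 split per region, forests at 50–500 trees (step 50) with seed
999, chosen count = first local maximum of held-out accuracy above 100
trees (boundary 500 compares leftward only; a still-rising curve
returns 500 with a warning). The tree-count criterion is measured on
the held-out half (the protocol does not name the data used; the
held-out choice avoids selecting on training fit).

The majority filter votes over the 3×3 neighbourhood including the
centre; ties keep the centre (symmetric and idempotent-friendly),
nodata cells neither vote nor change. The exported product encodes
soybean as 1 and everything else as nodata.

Accuracy metrics use the standard remote-sensing convention
(producer's accuracy = recall, user's accuracy = precision);
`paper_convention=True` computes the variant with the two error terms
swapped, and every report labels which convention produced it. Area
agreement uses the squared Pearson correlation for R², so a constant
bias yields R² = 1 with the bias visible in RMSE/MAE.

## Synthetic scene generator

Each crop archetype drives all nine bands between a shared bare-soil
state and a crop-specific peak-canopy state with a normalized
double-logistic curve (green-up and senescence inflections, per-crop
rates); optional per-band shape exponents delay individual bands. SAR
backscatter is an affine function of canopy development plus noise.
Observations are 5-day cadence, each dropped with probability 0.3
(clouds), bands carry i.i.d. Gaussian noise of σ = 0.01 reflectance —
about the residual error of atmospherically corrected surface
reflectance. Defaults: a 200-points-per-crop scene of soybean, corn,
rice and peanut with 80 ground-survey soybean references.

Peak-state values were chosen once so the generator meets its
documented contract at zero noise: concave TCARI/OSAVI (CCI < 0) for
soybean/corn/rice, convex for peanut/cotton/potato/other, and soybean's
seasonal integrals above corn/rice in the high-value group and below
them in the low-value group. The double-logistic driver was picked
because its continuous curve gives closed-form/numeric oracle values
for the mid-amplitude phenology dates.

What passing tests show — and what they do not: the generator
reproduces the *statistical structure the method assumes* (Gaussian
integral clusters, monotone index trajectories, a single season). Real
fields add mixed pixels, intercropping, double cropping, regionally
varying soil backgrounds, correlated (not i.i.d.) atmospheric residuals
and SAR speckle; none of these are emulated, so synthetic accuracies
bound the method's behaviour under its own assumptions rather than
predict operational accuracy. Scene sizes (hundreds of points per crop,
a 60 px demonstration raster) were chosen as the smallest scales at
which the population statistics stabilize.

## Degenerate inputs and tie-breaks

* Flat EVI → "no seasonal signal" error; missing crossings clamp to the
  grid edge; tied maxima take the earliest bin.
* Zero-length seasons integrate to 0.
* Index denominators below 1e-9 → missing value.
* PCA on a rank-deficient matrix returns the available components with
  a warning.
* Candidates whose phenology cannot be extracted are dropped and
  counted in the run report, never silently imputed.
* All randomness (scene, Monte Carlo, splits, forests) flows through
  explicit seeds recorded in the run manifest; reruns are
  byte-identical.

## Known limitations

* Single-season phenology only; double-cropping systems need a
  different season segmentation.
* The migration thresholds assume the reference year/region's integral
  distribution transfers to the target; strong phenological shifts
  (e.g. drought years) violate this and would need re-calibration.
* The raster path predicts per-pixel from a feature stack; tiled
  country-scale mosaicking and GPU inference are out of scope.
* Rasters are exchanged as ESRI ASCII grids and points as GeoJSON;
  coordinates are nominal (local metres mapped to a lon/lat window) in
  synthetic scenes.
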