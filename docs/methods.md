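# Methods

This note documents the statistical model, the estimators and their
numerical treatment, the synthetic-data generator, and the design choices
made where the methodology left genuine latitude.

## 1. The Random Encounter Model

Density is estimated as

    D = (Y/H) · π / (v · r · (2 + θ)),

with Y independent encounters, H camera-days, v day range (km/day), r and θ
the radius (km) and full angular width (rad) of the sector-shaped detection
zone.  Under ideal-gas assumptions — animals uniformly distributed, moving
independently with uniform headings — the expected encounter rate of a
sector is exactly D·v·r(2+θ)/π, because the mean profile width a convex
region presents to an isotropic flux of straight paths is perimeter/π
(Cauchy), and the sector's perimeter is r(2+θ).  The formula is therefore
exact for straight transits at constant speed; tortuous movement and
clumped animals perturb it only weakly, which the simulator quantifies.

Units: rate is per camera-day, v in km/day, r in km, θ in rad, D in
individuals/km².  Dimensional coherence is asserted in the test suite by a
scaling check (expressing v and r in metres rescales D by exactly 10⁻⁶).

## 2. From photo frames to Y and H

Cameras fire 3-frame bursts retriggered at 1 s, so one pass yields a run of
closely spaced frames.  Frames at one station (and species) with successive
gaps ≤ `burst_gap_s` (default 120 s — comfortably merges one pass, splits
separate passes) form a *sequence*.  Sequences are then screened by the
30-minute independence rule, applied greedily per station and species to
start times: a sequence is retained iff it starts ≥ `window_min` (default
30) minutes after the start of the last *retained* sequence.  The boundary
counts as independent (a gap of exactly 30 min is kept); anchoring to the
last retained start makes the rule deterministic and order-independent
given sorted input, unlike any-pair sliding rules.  Y counts retained
sequences; H sums per-deployment operational time in fractional days.

A note on reported rates: a published study may print an overall rate that
is not exactly Y/H as printed (e.g. 66 encounters over 428 trap nights
alongside a rate of 0.143 rather than 66/428 = 0.154, suggesting effort or
counts were adjusted upstream of the printed numbers).  `remcam` always
reports Y, H and Y/H together, and the parameter-override path accepts a
reported rate directly so printed results can be reproduced as printed.

## 3. Day range: speed × activity

**Speed.**  Each usable sequence gives sᵢ = dᵢ/tᵢ, with dᵢ the
marker-calibrated path length across the field of view and tᵢ the time
between first and last frame.  Zero-duration (single-frame) triggers are
dropped with a warning; sequences where the animal reacted to the camera
stay in the encounter count but are excluded from the speed pool.  The
default average is the unweighted arithmetic mean (a harmonic-mean option
exists: it answers "speed at a random point in space" rather than "speed of
a random transit", and is deliberately off by default).

**Activity level.**  Detection times of independent encounters (one per
encounter, not per frame, to avoid burst pseudo-replication) are mapped to
the 24-h circle and smoothed with a von Mises kernel density f̂; the
activity level is p = 1/(2π·max f̂), i.e. the fraction of the day that
would be active if all animals were active at the diel peak.  Clock time is
used directly (no solar anchoring).  The kernel concentration follows the
circular rule of thumb ν = [3n κ̂² I₂(2κ̂)/(4√π I₁(κ̂)²)]^{2/5} with κ̂ the
von Mises ML concentration of the sample (multiplier 1.0, configurable).
The peak is located by ternary search between grid points, so p is
invariant to rotations of the time origin.

**Peak bias.**  max f̂ is a maximum over a noisy function and therefore
biased upward, biasing p downward — by as much as −7% relative for a
flat-topped (hard on/off) schedule at n ≈ 2000.  `fit_activity` corrects
this by default with an extreme-value argument: over a plateau the
estimate fluctuates with pointwise sd σ = √(f̂·R(K)/n) (R(K) the kernel
roughness I₀(2ν)/(2π I₀(ν)²)), and the observed maximum overshoots by
about σ·E[max of m standard normals], with m the plateau length (iterated
to a fixed point) divided by the noise correlation length 2√(π/ν).  For
sharply peaked densities m → 1 and the correction vanishes.  When a
bootstrap runs, the residual bias seen in the bootstrap world
(2p̂ − mean p̂*) is removed as well, and the CI is the basic bootstrap
interval.  Validated against top-hat (10/24 and 12/24 of the day), uniform
and von Mises truths: residual bias ≲ 1% on flat shapes, ≲ +4% on peaked
shapes at small n, uniform clips to p = 1.  Without correction
(`bias_correct=False`) the raw field-standard estimator is used.

**Composition.**  v = mean speed × p × 86.4 (m/s → km/day).  Its SE treats
the two factors as independent (no covariance is estimable from separate
speed and time-of-day data): (se_v/v)² = (se_s/s̄)² + (se_p/p)².

## 4. Detection zone

First-trigger positions (radial distance, signed bearing) of positioned
encounters give r = mean distance (m → km) and θ = 2·mean|bearing| — the
common field protocol, and the package default (`zone_method="mean"`).

That protocol is, however, geometrically biased when the recorded position
is the point where the animal *entered* the zone: for isotropic straight
paths, entries distribute uniformly over the sector boundary (two radial
edges of length R, arc R·Θ), so

    E[distance] = R(1+Θ)/(2+Θ)   ≈ 0.59 R at Θ = 0.426,
    E[|bearing|] = Θ(4+Θ)/(4(2+Θ)),

and the plain mean underestimates R, inflating D by ≈ (2+Θ)/(1+Θ) ≈ 1.7.
`zone_method="entry-corrected"` inverts these two moment equations in
closed form (the second is a quadratic in Θ) and recovers (R, Θ)
consistently; the recovery tests use it, and the simulator's entry
geometry is itself verified against the closed forms.  On real surveys the
choice depends on what the markers record: calibrated sighting distances
justify the plain mean; entry positions justify the correction.

## 5. Uncertainty

All component SEs are nonparametric bootstraps (default B = 10,000,
seeded): stations with replacement for the encounter rate (the
design-based resampling unit — rate* = ΣY*/ΣH*), observations for speed,
activity times and zone positions.  The total SE uses the delta method for
a product/quotient of independent components:

    (se_D/D)² = (se_rate/rate)² + (se_v/v)² + (se_r/r)² + (se_θ/(2+θ))²,

reported together with the per-component squared-CV decomposition.
First-order propagation agrees with direct Monte-Carlo within 10% for
component CVs around 0.1; at CVs ≳ 0.2 the reciprocal terms acquire
second-order variance (≈ 6·CV² relative) and the delta method
underestimates — the acceptance suite checks the valid regime.  Published
component SEs of the scale typical for REM surveys (rate CV ≈ 0.22, v CV ≈
0.20) imply a total CV near 0.30; a printed total SE much smaller than
that cannot be reconstructed from printed component SEs by any
delta-method combination, so `remcam` always reports its own propagation.

## 6. The synthetic-data generator

`SimTruth`/`simulate` implement the ideal-gas world the REM assumes, with
full ground truth for recovery tests.

* **Defaults are the study conditions**: 23 stations ≥ 1 km apart
  (hard-core sequential placement, mirroring a gridded survey design),
  428 camera-days total, density 1.875 ind/km² on a toroidal 6.4 × 7.25 km
  arena (so round(D·A) = 87 animals, realized density exactly 1.875),
  detection radius 0.0045 km, angle 0.426 rad, day range 21.39 km/day
  split as a hard 19:00–05:00 activity window (fraction 10/24) at
  0.59417 m/s, 5% of encounters flagged as reacting to the camera.
* **Movement**: correlated random walk, wrapped-normal turning with sd
  κ^{-1/2} (default κ = 200, near-straight at 1-s steps), constant speed
  while active, stationary otherwise; toroidal wrap avoids edge-induced
  density bias.
* **Detection is continuous in time**: a step registers when its path
  segment intersects a camera's sector (exact segment/arc and segment/edge
  tests).  This matters: the mean chord of a 0.426-rad sector is ≈ 0.28 R,
  shorter than one movement step, so sampling point-in-zone at 1 Hz would
  miss ~40% of transits and break the closed-form rate.  The coarseness
  guard (speed·dt > r/2 → error) remains as a validation error.
* **Records**: one frame per in-zone second (bursts merged downstream);
  the first-trigger position is the exact entry point of the path into the
  sector; the marker distance is the path length between first and last
  frame.  Performance: a fused numba pass integrates movement and stores
  block-start states; fine trajectories are regenerated only for
  animal-blocks within reach of a camera (~2–3 s per study-scale survey).

**What the generator does not emulate**: home ranges or habitat selection,
terrain, imperfect detection inside the zone (the REM's r, θ are effective
zone parameters by definition), smooth diel activity ramps (the hard
window gives an exactly known activity fraction; the peak-bias correction
was validated on smooth shapes separately), and multi-animal social
structure.  Camera spacing matters: packing cameras much closer than 1 km
makes one animal's nightly track hit several cameras, autocorrelating
detection times and inflating the fitted activity peak — an effect of
survey design, not of the estimator — which is why the default honours the
1-km spacing.  Passing tests on this generator demonstrate internal
consistency of the estimator chain under its own assumptions, not
robustness to the field phenomena listed above.

**Recovery performance** (the quantities the test suite computes): across
150 simulated surveys at the default conditions, the mean encounter rate
matches D·v·r(2+θ)/π within ~1%, the entry-corrected zone recovers (r, θ)
within ~1%, the pooled activity fit recovers the planted fraction within
the stated ±0.07, and the full pipeline's mean density is within 5% of
truth.  Activity is fitted on detection times pooled across surveys
(≈ 6000 times) and the zone on pooled entry positions: both are
population-level quantities shared by design across replicates, and a
single survey's ~60 encounters are too few for a stable circular-KDE fit —
the per-survey quantities are the rate and the speed pool.

## 7. Spatial layer

* **Hotspots**: quartic kernel K(u) = 3/(πh²)(1−u²)², maximal at the
  point, zero at the search radius h, unit mass — so the raster conserves
  total point weight (within 1% when h fits inside the extent).  Default
  bandwidth 2 × mean nearest-neighbour station distance (no bandwidth is
  canonical for sparse station sets; this scales with the design).
  Output is plain-text ESRI ASCII grid.  Classes are equal intervals over
  the positive range, class 0 reserved for empty cells.
* **Exploratory regression**: all non-empty subsets of up to 6 candidate
  covariates are fitted by OLS; each model reports adjusted R², coefficient
  p-values, per-predictor VIF (auxiliary-regression form), Jarque–Bera
  residual-normality p, and Moran's I of residuals with inverse-distance,
  row-standardized weights under the normal approximation (the classical
  global test; the specific autocorrelation test behind GIS toolboxes is
  not published, and Moran's I is the standard choice).  A model passes
  when adj R² ≥ 0.3, all coefficient p ≤ 0.05, max VIF ≤ 7.5, and JB and
  Moran p ≥ 0.1.
* **Variable importance** is the percentage of models *containing* a
  variable in which it is significant.  With 6 candidates each variable
  appears in exactly 2⁵ = 32 of the 63 subsets, which is why published
  importances from such screens are multiples of 1/32 (e.g. 23/32 =
  71.88%, 1/32 = 3.12%).  A "screened" denominator (models whose
  coefficients are all significant) is available as an option.  Note that
  a variable's importance is inherently lumpy: a chance 5%-level
  significance propagates to all 32 subsets containing it, so single-table
  importances of pure-noise covariates are occasionally large; averages
  over tables are the stable quantity, and the tests treat them that way.

## 8. Numerical and degenerate-input conventions

* Timestamps are ISO-8601; H may be fractional days.  Records outside
  their station's deployment interval fail validation (or are dropped with
  a report, on request).
* Y = 0 yields D = 0 with a warning rather than an error; H ≤ 0, empty
  speed pools, or missing positions raise typed errors naming the stage.
* Bootstraps, the simulator and the CLI are seeded end-to-end; reports
  embed the package version, seed and a configuration hash, and identical
  configuration + seed reproduce outputs bit-for-bit.
* Activity fits clip p to 1 (flat samples can put the fitted peak below
  the uniform level 1/2π numerically) and require ≥ 10 detection times.
* The simulator refuses time steps that cannot resolve a zone transit and
  camera layouts that cannot satisfy the spacing constraint.

## 9. Known limitations

* The REM assumptions themselves (uniform density, independent movement,
  closed population during the survey) are taken as given; no correction
  for attraction/avoidance beyond the reaction-exclusion flag on speeds.
* The delta method ignores covariances between components and degrades at
  component CVs ≳ 0.2 (Section 5).
* The plain-mean zone estimator is biased under entry-position recording
  (Section 4); the package defaults to the field protocol and leaves the
  correction as an explicit choice.
* The activity estimator retains a small negative bias (≈ 1–3%) for
  flat-topped schedules even after correction, and the correction can
  overshoot by a few percent for sharply peaked patterns at n ≲ 500.
* Raster covariate extraction from real GIS layers is out of scope; the
  regression consumes a prepared per-station covariate table.
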