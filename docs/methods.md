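# Methods

## The measurement model

An upward-looking camera under a street-tree canopy sees dark foliage
against bright sky, so the blue channel of an RGB frame is strongly
bimodal. Binarizing at the histogram valley between the foliage and sky
peaks yields a canopy/sky mask from which cover-photography statistics are
derived. The frame is partitioned into a 5×5 grid; sub-images with more
than 75% sky are *large gaps*, interpreted as between-crown openings
rather than within-crown porosity. Foliage projective cover `ff`, crown
cover `fc` and crown porosity `Φ = 1 − ff/fc` then feed the Beer–Lambert
inversion `LAI = −fc ln Φ / k` with light-extinction coefficient
`k = 0.5` (appropriate for tall broadleaf trees; configurable). The
zenith clumping index `Ω(0) = (1−Φ) ln(1−ff)/(ff ln Φ)` equals 1 exactly
when crowns fill the frame and foliage is randomly dispersed (then
`Φ = 1 − ff` and the logarithms cancel) and falls below 1 for clumped
canopies; `LAIe = LAI · Ω(0)`.

The thermal camera exports per-pixel radiometric temperature (°C) as CSV.
Clear-sky apparent temperature is far below 0 °C at thermal-infrared
wavelengths, so leaf material is every pixel strictly above a 0 °C cutoff
(configurable for cold climates). `T_canopy` is the mean of masked pixels
(median available). The tree water stress index normalizes `T_canopy`
between a fully transpiring (`T_wet`) and a non-transpiring (`T_dry`)
reference; `Ig = (T_dry − T_canopy)/(T_canopy − T_wet)` is proportional to
leaf conductance and satisfies `Ig = (1 − TWSI)/TWSI` wherever TWSI is
unclamped — an identity the tests verify to 1e−9.

## Reference temperatures: two routes

*Percentile* (default): `T_wet`/`T_dry` as the 5th/95th percentiles of the
canopy pixel-temperature distribution (linear interpolation between order
statistics). The published procedure this stands in for is a
statistical-distribution discrimination whose exact recipe is not public;
the 5/95 choice is a documented, reproducible default, and both
percentiles are exposed as configuration.

*Energy balance*: with micromet inputs (air temperature, relative
humidity, shortwave irradiance used as net isothermal radiation `R_ni`),

    T_dry = T_air + r_HR·R_ni/(ρ·c_p)
    T_wet = T_air + [r_HR·r_aw·γ·R_ni/(ρ·c_p) − r_HR·δe]/(γ·r_aw + s·r_HR)

Saturation vapour pressure follows the Tetens form
`es(t) = 610.78·exp(17.27 t/(t+237.3))` Pa with analytic slope `s`; the
vapour pressure deficit is `δe = es(T_air)(1 − rh)`. Air density comes
from the ideal gas law at standard pressure, `c_p = 1005 J kg⁻¹ K⁻¹`,
`γ = 66 Pa K⁻¹`. The resistances `r_aw = 50` and `r_HR = 30 s m⁻¹` are
survey-level inputs (typical broadleaf values) because no wind
measurements exist to model them. Both references collapse to `T_air` as
`R_ni → 0` and `δe → 0`; `T_dry` is monotone increasing in `R_ni` and
`T_wet` monotone decreasing in `δe` — tested properties.

## Sign and polarity conventions

Temperature depression is `TD = T_canopy − T_air` (positive = canopy
warmer than air; consistent with hot-day survey tables that pair a
28.2 °C canopy with TD = 3.2 on a 31 °C-max day). Canopy is the *dark*
histogram peak (blue ≤ threshold); an inversion flag covers overcast
scenes. TWSI is clamped to [0, 1] with a flag rather than erroring,
because field frames routinely stray outside the references.

## Geo-matching

The GPS tracker and the cameras log independently, so each frame's
position is linearly interpolated in time between bracketing track points
(1 Hz track). A frame is assigned to its nearest anchor by haversine
distance (Earth radius 6371 km) iff within 25 m — about half a typical
street-tree spacing, preventing cross-street mis-assignment; exact ties
break to the lexicographically lower tree id, making assignment a pure
function. Matching is per-frame; per-tree observations are means (or
medians) over contributing frames, with degenerate frames excluded and
trees with zero valid frames omitted with a logged warning.

## Synthetic scenes and what they do (not) show

The generator is the test bed: survey imagery of this kind is proprietary,
so every stage is validated against scenes with closed-form truth.

*Visible frames* use a Boolean disc model: foliage discs of radius 2% of
image width (small against the 5×5 blocks, so Poisson scenes are
near-random at block scale) placed by a homogeneous Poisson process with
intensity `λ` chosen so the gap fraction `exp(−λπr²)` equals the
Beer–Lambert target `exp(−k·LAI)`. Centres are sampled on a
margin-extended window, keeping the gap fraction stationary at the image
edge. The clustered variant is a Matérn-style process (Poisson parents,
Poisson(25) Gaussian-scattered offspring, scatter sd = 2 disc radii, same
total intensity), which produces genuine between-crown gaps and drives the
recovered `Ω(0)` below 1. Blue intensities are N(60,10) for foliage and
N(220,10) for sky — cleanly bimodal. *Thermal frames* paint the same mask
with N(28,1) °C leaves over a uniform −40 °C sky, so segmentation truth is
exact by construction. *Surveys* place anchors evenly along a straight
northbound route, offset 8 m east (the nature strip), with a 7 m s⁻¹
vehicle, 1 Hz GPS, frame pairs at each anchor passage, and a 0.5 Hz
micromet log; per-tree true LAI is uniform on [1, 4] and canopy
temperature mean uniform on [24, 32] °C — a realistic street-tree spread
for a warm survey day.

What passing these tests shows: the estimator chain inverts its own
generating model correctly, the indices satisfy their algebraic and limit
properties, and the plumbing is deterministic. What it does not show:
robustness to real-world nuisances absent from the generator — motion
blur, overcast or partially cloudy skies, sun glint, buildings and wires
in frame, mixed species, emissivity errors, GPS multipath. The valley
binarization in particular assumes a bimodal blue histogram; the Otsu
fallback fires on unimodal scenes but has no ground truth here.

## Numerical choices

- Valley detection: moving-average smoothing (width 5 bins), plateau-aware
  local maxima (a flat run strictly above both neighbours is one peak at
  its midpoint, rounded down), the two highest peaks retained, threshold
  at the minimum strictly between them, ties resolved to the midpoint of
  the tied run rounding down. Deterministic by construction.
- 5×5 partition of non-divisible dimensions: integer division with
  remainder pixels merged into the last row/column of blocks, so the
  partition is exhaustive.
- "Over 75% sky" is a strict inequality (a block at exactly 75% is not a
  large gap); configurable.
- Degenerate frames — all sky, all canopy, `fc = 0`, too few thermal
  pixels (< 5% of frame), `T_dry ≤ T_wet` — are flagged and excluded from
  aggregation, never raised, so one bad frame cannot abort a survey.
- Thermal CSV round-trips exactly: values are written with shortest
  round-tripping float repr.
- Output determinism: observation CSVs use fixed float formatting and
  GeoJSON uses sorted keys, so identical inputs give identical bytes.

## Validation problem sizes

The recovery study uses 1000×1000 px scenes, 8 per LAI level over
levels {1, 2, 3, 4} (32 scenes), recovering each level's mean LAI within
10% relative error and mean `Ω(0)` within 0.1 of 1; the clumping contrast
uses 20 matched Poisson/clustered pairs under a one-sided sign test; the
index-identity grid uses 10⁴ random temperature triples; segmentation
exactness uses 20 seeded 120×180 frames; matching is cross-checked against
a brute-force all-pairs oracle on 50 random instances up to 200 frames ×
50 anchors; the end-to-end contract runs a 20-tree survey twice and
compares bytes.

## Known limitations

- The large-gap rule misclassifies rare random voids as between-crown gaps
  at low LAI; at these scene sizes the induced LAI bias is well under the
  10% test tolerance but it is not zero.
- `Ig` is only *proportional* to stomatal conductance; no absolute
  calibration is attempted.
- Radiometric temperatures are taken as exported (the camera applies
  emissivity upstream); no atmospheric correction.
- The straight synthetic route does not exercise curved tracks or repeated
  passes in opposite directions, though the matcher itself is
  direction-agnostic.
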