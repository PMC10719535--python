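# Methods

`alleyshade` couples four small physical models — a solar ephemeris, a
clear-sky irradiance model on terrain, a linear tree-growth model with a
spherical crown, and analytic ray–sphere shadow casting — into a
deterministic time-stepping simulation of alley-cropping shade. This note
records the models, their assumptions, the parameter defaults and the design
choices taken where the problem was genuinely open.

## Solar position and schedule

Sun azimuth/altitude come from a truncated-series ephemeris of the kind used
by the NOAA solar calculator (geometric mean longitude/anomaly, equation of
centre, apparent longitude, obliquity with nutation correction, equation of
time, hour angle), followed by the standard piecewise atmospheric-refraction
correction. Accuracy is ~0.1° over 1950–2050, two orders of magnitude below
the angular size of a crown seen from across a field. The frame convention
for the whole package: azimuth 0° = geographic north, clockwise; the sun
direction vector lives in a local east-north-up frame,
`(cos α sin φ, cos α cos φ, sin α)`.

Schedules are generated on the site's *local clock* (fixed UTC offset, no
daylight-saving), every `interval_minutes` from 00:00 of the start date over
whole calendar years, leap days included. Only moments with
refraction-corrected altitude strictly above 0° are kept. At the default
site (52.9° N, 12.8° E, UTC+1) one year at 20-minute cadence yields 13,372
daylight moments.

A subtlety worth recording: a local-clock grid has a fixed phase offset from
solar noon (~8 min at this site's longitude under UTC+1). At hourly cadence
that offset aliases into a systematic east/west bias of order 10% in
near-row shading statistics, because one flank is always sampled nearer
noon; at the default 20-minute cadence the annual equation-of-time variation
(±15 min) smears the phase across the whole cycle and the residual bias is
below 1%. Symmetry-sensitive analyses should therefore use the 20-minute
interval even when the spatial grid is coarsened.

## Terrain

DEMs are square-celled rasters (ESRI ASCII, bit-exact round-trip; or
single-band GeoTIFF via `tifffile` GeoTIFF tags), row 0 northernmost, with
the origin at the lower-left corner. The surface mesh places one vertex per
cell centre and splits each 2×2 vertex block along a fixed SW–NE diagonal —
the split is not prescribed by any standard, so a fixed choice keeps ray
tests reproducible. Slope and aspect use Horn's 3×3 method (the common GIS
default), with linear-extrapolation padding so edge cells behave as
one-sided differences and planar surfaces are recovered exactly everywhere;
aspect is the downslope direction, undefined (NaN) on flat cells.

## Clear-sky radiation

Per-cell instantaneous potential incoming solar radiation (PISR) uses the
classic lumped-transmittance formulation: direct
`S₀ τ^m cos θᵢ` with relative air mass `m = 1/sin α` capped at 38 near the
horizon, and diffuse `S₀ (0.271 − 0.294 τ^m) sin α` on the horizontal,
scaled by an isotropic sky-view factor (1 by default) and clamped at zero
(negative values are possible for τ near 1). Defaults: solar constant
S₀ = 1367 W m⁻², bulk transmittance τ = 0.70 — a conventional clear-sky
value for temperate mid-latitudes. Integration over a uniform schedule is
the left-rectangle rule; halving the step from 20 to 40 minutes moves the
annual flat-terrain integral by well under 1%. The resulting annual
flat-terrain total at 52.9° N (~1480 kWh m⁻² a⁻¹) is a *potential*
(cloud-free) value and intentionally exceeds measured all-sky irradiation;
only ratios of shaded to unshaded PISR are interpreted quantitatively.

Terrain self-shadowing (a hill hiding the sun from a cell) is available but
off by default: the intended use case is gently sloped fields where horizon
occlusion is negligible. When enabled it marches each cell's sun ray across
the bilinear terrain surface at one-cell steps and suppresses the direct
component where the surface rises above the ray.

## Trees

Growth is deliberately minimal: constant height rate 0.25 m yr⁻¹, constant
DBH rate 0.5 cm yr⁻¹, and a linear crown allometry
`crown_diameter [m] = 0.1393 · DBH[cm] + 2.6937` published for wild service
tree. Age is fractional, counted in mean Gregorian years from the planting
date, so growth is continuous rather than stepped annually. The allometry is
used as printed down to DBH = 0 (a newly planted tree carries the 2.69 m
intercept crown); its calibration range below a few cm DBH is unknown and
results for the first years should be read accordingly.

The crown is a sphere whose top sits at tree height, clamped so that young
trees' crowns rest on the ground (`centre z = ground + max(height − r, r)`),
with ground elevation bilinearly interpolated from the DEM. Top-alignment
is our convention; the source material only states that the crown is a
sphere. The trunk is not modelled as an occluder — at ≤ 0.3 m diameter it is
far below the 1 m raster resolution.

Foliage is a two-state seasonal cycle: crown opacity 0.75 foliated
(May–October), 0.20 leafless (November–April), switching on the calendar
month. The shading multiplier applied to radiation under a crown is the
**transmittance** 1 − opacity: a summer-shadowed cell keeps 25% of its
clear-sky radiation, a winter-shadowed cell 80%. The alternative reading —
multiplying by the opacity value itself — would make leafless crowns cast
darker shade than foliated ones, which contradicts the physical meaning of
the cited opacities; we use the physically consistent interpretation
throughout and flag below where this matters for comparisons with earlier
published summaries.

Row layouts buffer the field polygon inward (default 20 m, the minimum
field-edge distance required for agroforestry eligibility under the current
CAP rules), draw parallel row axes at the chosen orientation spaced
`row_spacing` apart and anchored at the buffered polygon's centroid, clip
them to the buffered polygon, and place trees every `tree_spacing` along
each clipped row starting half a spacing from its (canonically ordered)
end. Orientations 180° apart produce identical layouts.

## Shadow casting

For each daylight moment a ray is cast from every cell centre (lifted 1 cm
above ground to avoid grazing self-hits on sloped faces) toward the sun and
tested against all crown spheres with the analytic quadratic; tangency
counts as a hit and intersections closer than 1 µm are ignored. Cells shaded
by several crowns attenuate once (boolean union), matching a single
is-shadowed test; multiplicative stacking (`transmittanceᵏ`) is available
behind a flag. A per-sphere candidate window — the bounding box of the
crown's projected shadow footprint over the DEM's elevation range, padded by
`r/sin α` — is purely an acceleration device; the test suite asserts exact
mask equality with an all-pairs reference. The analytic sphere differs from
a polygonal crown silhouette by less than one cell at metre resolution.

The simulation loop updates the tree state per moment (fractional age,
calendar month), rebuilds the crown spheres on fixed positions, computes the
PISR map, casts shadows and accumulates shaded (scenario) and unshaded
(tree-free baseline) maps into monthly kWh m⁻² rasters. There is no
randomness anywhere; re-running a config reproduces archives bit-for-bit.
Archives are written one raster per (year, month, layer) with a JSON
manifest carrying the config hash, so long runs checkpoint per year and can
be resumed by re-running with the same config.

## Reduction analytics

Percent reduction per cell is `(1 − scenario/baseline)·100`, computed only
on valid crop area: habitat strips (centrelines buffered by half the row
width) are removed from both layers first, so scenario and baseline cover
identical areas. Shade-intensity tabulation uses six closed-open bins
(<2, 2–5, 5–10, 10–20, 20–30, ≥30%); shares always sum to 100. Distance
classes ([0.5,3), [3,6), [6,9), [9,12), [12,15) m) are assigned by
perpendicular distance to the *nearest* row axis, restricted to the row's
clipped extent, with ties to the lower row index; sides are labelled by the
compass direction of the row-perpendicular. Class means are unweighted over
equal-area cells. Note that a coarse grid can leave a 3 m band without any
cell centre (e.g. no 4 m cell centre falls 3–6 m from a row lying on a cell
boundary); consumers should treat empty classes as missing, not zero.

## Synthetic study conditions

No real field DEM or boundary is shipped; the fixture generator emulates the
kind of site the method targets: a rectangular 6.4 ha field (320 × 200 m) in
northern Brandenburg (52.9° N, 12.8° E, UTC+1), mean elevation ~54 m, a
gentle (1.8%) west-falling slope with a shallow depression near the northern
edge, total relief ≈ 7 m. Two ready-made designs mirror the canonical
alternatives: north-south rows at 32 m spacing (shade-minimizing) and
west-east rows at 36 m spacing (windbreak-oriented), both with 12 m in-row
tree spacing, 1 m strips and the 20 m buffer. The synthetic field reproduces
the *geometry class* of a real site, not its measured topography, soil or
climate: passing tests demonstrate correct shading physics and bookkeeping
on such terrain, not agreement with any particular field's absolute
irradiation, tree counts or row lengths.

Test and example runs use a coarse profile — 4 m cells with 60-minute steps
for magnitude-level results, or the 60th growth year only where the question
concerns mature trees — keeping a full design comparison under a minute
while the full-resolution, multi-decade configuration remains a plain
parameter choice.

## Known limitations and open interpretation

- Growth ignores site quality, competition, management and mortality; the
  linear rates are species-level simplifications.
- The clear-sky parameterization (τ = 0.70, isotropic diffuse) is a
  documented substitute for whatever options earlier GIS-based analyses
  used; absolute kWh m⁻² values are not comparable across tools, ratios are.
- Shadows are hard (no penumbra) and the crown is a homogeneous sphere.
- With the transmittance interpretation of crown opacity, cells immediately
  north of west-east rows can lose more than 30% of a foliated month's PISR
  (we measure up to ~50% at tree age 60 on the synthetic field), whereas
  summaries built on the opacity-as-multiplier reading are bounded at 25%
  in foliated months by construction. The qualitative claim that no cell
  ever exceeds 30% monthly reduction therefore holds for north-south
  designs in this model, but not for the northern flank of west-east
  designs; the discrepancy traces entirely to that interpretation choice,
  which we resolve on physical grounds (foliated crowns must shade more,
  not less, than leafless ones).
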