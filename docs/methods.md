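# Methods

This note documents the models implemented in `terravalue`, the choices
made where the method description leaves room, and what the synthetic data
do and do not establish.

## Evaluation units and zonal statistics

The atomic spatial unit is the evaluation unit: a 4-connected component of
cells sharing one (land use, soil, administrative region) triple, restricted
to farmland cells. Components below a minimum area are merged into their
largest edge-adjacent unit; the default threshold is 0.36 hm² (four 30 m
cells) — the source workflow eliminates slivers without stating a
threshold, so the smallest non-trivial multiple of the cell area was fixed
once. Isolated slivers with no neighbour are kept rather than dropped, so
area accounting stays exact: the sum of unit areas always equals farmland
cell count × cell area (cell_size²/10⁴ hm², no geodesic correction —
grids are assumed projected and co-registered; the package validates
alignment and refuses to resample silently).

Per-unit indicator values are zonal arithmetic means of valid cells. Units
with no valid cells are flagged NaN and propagate to an "ungraded" flag
rather than becoming zeros.

## Membership scoring

Numeric indicators use the calibrated function families
`Y = 1/(1 + a(u − c)²)` (decreasing and peak type) and `Y = a·u + b`
(linear). Two conventions are applied that the calibration tables do not
state:

* inputs are clamped to the fitted bounds `[u_lo, u_hi]` before evaluation
  (the parameters are only fitted inside the bounds);
* raw outputs are clamped to [0, 1] (membership is by definition a degree;
  e.g. the organic-matter line reaches 1.0026 at its own upper bound).

Known oddities of the shipped calibration, implemented as printed and
flagged here rather than "fixed": the pH row is labelled peak-type but has
c = 0, making it monotone decreasing over [5.4, 7.2]; the effective-water
line (a = 0.0015, b = 0) never exceeds ≈ 0.055 over its own bounds, which
looks like a units inconsistency; the total-nitrogen line exceeds 1 below
its upper bound (clamped).

Conceptual indicators map ordered categories onto the score columns 1.0,
0.9, 0.8, …. The printed tables do not pin each row's categories to
columns; the package assigns consecutive columns starting at 1.0 (terrain
1.0→0.4 over 7 classes, texture 1.0→0.3 over 8, five-level rows 1.0→0.6),
exposed via `ConceptualScale` so alternative alignments are testable. For
both distance indicators "Closer" is best (score 1.0), reading distance as
irrigation/cultivation convenience.

## Weights

The principal right-eigenvector of the reciprocal judgment matrix (power
iteration, relative tolerance 1e-10) is the primary method, since pairing
weights with a consistency ratio implies the eigenvector formalism; the row
geometric mean is provided as a cross-check (exact for consistent
matrices). CR uses Saaty's random-index table (extended to n = 16 with the
commonly tabulated 1.60) and the conventional CR < 0.1 gate. The full
16-indicator judgment matrix behind the shipped weight vector is not
published, so the pipeline defaults to the published weights (printed sum
0.9999, preserved verbatim; renormalisation is an explicit opt-in) and
treats matrix-based derivation as the general capability.

## Grading

Natural breaks are computed by the exact Fisher–Jenks dynamic programme
(O(k·n²) over distinct values with frequency compression), not a heuristic,
so results are deterministic and provably optimal in within-class sum of
squared deviations. Breaks are computed on unit-level IFI values, matching
the unit-based definition of the assessment. Interval boundaries are the
minima of the upper classes; classification is half-open [lo, hi) with a
top-inclusive maximum, which reproduces the DP partition exactly. Two
published fixed five-grade interval sets exist and conflict; the set that
accompanies the published grade areas is the canonical named scheme, the
other ships as `hefei_grade_scheme(alternate=True)`.

## Production potential

Thornthwaite Memorial, as given in the README. Numerical conventions: NPP
is floored at 0 for V < 20 mm (the closed form goes negative there); the
unit conversion is the explicit identity 1 g/m² = 0.01 t/hm² (a competing
"divide by 10,000" phrasing is inconsistent with the published potential
range of 15.11–16.69 t/hm² and is treated as an erratum). Grade standard
yields are area-weighted means of unit MPP by default — consistent with
zonal statistics over polygons of unequal size — with an unweighted option.

## Valuation

V_j = MPP_j (p − c) is implemented literally; prices and costs may be given
per cropping season and are averaged arithmetically. The published Hefei
unit values are *not* reproduced by this identity with the published yields
and margin (10.28 × 880 = 9046.4 vs the printed 3291.13; the implied
effective margin is ≈ 320.15 yuan/t, unexplained). The package therefore
also supports deriving unit values from per-grade totals and areas
(`derive_unit_values_from_totals`), and the reference-table verification
asserts only the internally consistent aggregation identities: marginals of
the area table, the sum of per-grade totals, unit values × areas against
the grand total, and the stated share percentages. The stated 7.6 %
first-grade value share is not derivable from the published tables (their
arithmetic gives 5.96 %) and is excluded from verification. The single-year
discount PV = V₁/(1 + r) is provided for sensitivity analysis (r ≈ 3–5 %).

## Synthetic landscapes

Continuous fields are white noise smoothed by a Gaussian kernel (truncated
at 4σ) and affinely rescaled after smoothing so the sample bounds equal the
configured bounds exactly; categorical maps cut a smooth latent field at
equal quantiles, giving contiguous patches. Locational indicators are
derived the way the real workflow derives them: Euclidean distance to
feature cells, classified into five 500 m buffer rings (outermost ring
absorbs everything beyond). One seed drives independent spawned streams per
layer, so bundles are bit-identical per (config, seed).

Defaults are chosen to emulate the study conditions: indicator ranges equal
the calibrated membership bounds; the default 200 m patch scale makes the
triple overlay yield evaluation units of ≈ 5 hm² mean area on the default
100×100 grid, matching the ≈ 5.1 hm² mean unit of the case study; climate
defaults (T 15–17 °C, R 900–1100 mm) are plausible subtropical-monsoon
values and are configuration, never asserted as case-study data.

What the synthetic data do not emulate: real spatial cross-correlation
between indicators (fields are independent), anisotropy, measurement error,
nodata patterns of real acquisitions, and the actual Hefei rasters. Tests
passing on synthetic data therefore establish the correctness of the
arithmetic and the pipeline plumbing, not the empirical results: the
published climatic-potential range (15.11–16.69 t/hm²), MPP range
(5.82–12.52 t/hm²), grade standard yields (10.28/9.94/9.31/8.91/7.95
t/hm²), the grade areas, and the judgment-matrix CR of 0.08 all depend on
the original rasters and expert matrix and are shipped as reference
constants, not recomputed.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances — 20×20 to 100×100 grids, 200 random natural-breaks instances
with n ≤ 12 and k ≤ 4 (where exhaustive enumeration is feasible as an
oracle), 10⁵ random membership evaluations — chosen so that every check is
exact or near-exact while the whole suite completes in seconds.

## Known limitations

* No reprojection engine: all layers must share one grid; resampling is
  out of scope.
* GeoTIFF is not supported; rasters travel as ESRI ASCII grids (exact
  round-trip, but no embedded CRS — the CRS tag is carried in memory only).
* The AHP implementation is single-level (criteria → indicators flattened),
  matching the flat weight table it ships.
* Only the single-year discount is implemented; no capitalisation over
  horizons.
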