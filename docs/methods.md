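# Methods

This note documents the model, the conventions the implementation fixes
where the published formulations of this index family are ambiguous, the
synthetic data used for validation, and known limitations.

## The risk model

Risk is evaluated on a square sample grid (default edge 2.5 km) anchored
at the raster's top-left origin. Partial border cells are retained with
their true valid (non-nodata) area rather than discarded — the final
area-weighting makes this unbiased — and cells with no valid pixels are
dropped. Each cell's index value is attributed to the geometric center of
its full (unclipped) grid square; those centers are the point support for
interpolation, spatial statistics, and GWR. An optional grid-origin
offset exposes sensitivity to anchoring.

Patches are maximal connected components of equal-coded pixels *within* a
cell: patches are clipped at cell boundaries, so a region spanning two
cells is counted in both, and cell-boundary edges count toward perimeter
(consistent with clipping; the flood-fill oracle in the tests uses the
same rule). Connectivity defaults to 8-neighbor and is configurable.
Nodata pixels contribute boundary but no area.

Per cell and class: `C_i = n_i/A_i` (km⁻²), `N_i = (A/2A_i)·√(n_i/A)`,
`D_i = (P_i/P_tot + n_i/N_tot)/4 + (A_i/A)/2 ∈ [0,1]`,
`E_i = 0.5·C_i + 0.3·N_i + 0.2·D_i`, `R_i = E_i·V_i`, and
`ERI = Σ_i (A_i/A)·R_i`.

Conventions fixed by this implementation (the published variants of this
index family print these formulas inconsistently, often typographically
collapsed):

* **Isolation** uses the standard splitting form `(A/2A_i)·√(n_i/A)`.
* **Dominance** identifies its three terms as relative perimeter,
  relative patch count, and relative area, which makes `D_i ∈ [0,1]` and
  `Σ_i D_i = 1` within a cell.
* **Vulnerability** treats the conventional integers (cropland 5 …
  wasteland 1) as rank positions with rank 1 = most vulnerable, so bare
  desert is most and cropland least sensitive — consistent with water
  ranking second and deserts carrying the highest risk in arid basins.
  Scores are raw `6 − rank` divided by their sum (15), so `Σ V_i = 1`.
  The scheme is user-overridable.
* **Locality**: all indices are computed per cell from within-cell
  patches, not once globally.
* **Units** are fixed at km/km². `C_i` carries units of km⁻², so the ERI
  is unit- and convention-dependent: absolute magnitudes are only
  comparable between runs that hold these conventions fixed (the tests
  assert the exact scale covariance: scaling all lengths by k divides
  `C_i` by k² and `N_i` by k). Published absolute values from other
  conventions are not comparable.

A consequence worth knowing: because `(A_i/A)·N_i = √(n_i/A)/2` is
independent of `A_i`, and `(A_i/A)·C_i = n_i/A`, *every patch of any
class adds a floor contribution to the cell's ERI regardless of how small
it is*. A single stray water pixel in a 6.25 km² cell adds ≈ 0.04 —
roughly a third of a pure desert cell's total. Thin corridors therefore
*raise* the risk of the cells they cross, while only cells dominated by
coherent low-vulnerability cover fall below the desert baseline. This is
faithful behavior of the index (fragmented water has long shorelines and
outsized influence), not an artifact.

## Interpolation and classification

The empirical semivariogram uses 12 lag bins to half the maximum pairwise
distance by default; bins with fewer than 5 pairs are dropped; a
spherical (optionally exponential/Gaussian) model is fitted by
pair-count-weighted least squares. Ordinary kriging solves the augmented
system with a Lagrange multiplier per target over the 16 nearest samples
(all samples optionally, intended for ≤ ~2000 points); duplicate sample
locations are averaged before solving; weights sum to 1 to 1e-9 and
prediction is exact at sample points when the nugget is zero.

Jenks natural breaks are computed by Fisher's exact dynamic program
(O(k·n²)); inputs longer than 3000 are thinned to evenly spaced order
statistics first. Classification intervals are right-closed
((−∞, b₁], (b₁, b₂], …), a deterministic tie rule. For multi-epoch series
breaks are recomputed per epoch by default; `fix_breaks` pools all
epochs' surfaces so class shares are comparable across years.

## Spatial statistics

Weights default to queen contiguity over the sample grid, row
standardized; rook and distance-band schemes are available; isolated
cells are flagged. Global Moran's I uses full random relabeling; local
Moran's I uses conditional permutation (cell i held fixed, a random
subset of the remaining values placed on its neighbors). Both report
two-sided pseudo-p values `(#{|I*| ≥ |I|} + 1)/(n_perm + 1)` with 999
permutations by default. LISA labels (HH/LL/HL/LH) are assigned from the
signs of the centered value and its lag where pseudo-p ≤ α = 0.05, with
no multiple-testing correction by default (an optional Benjamini–Hochberg
flag exists). The identity `Σ_i I_i = S₀·I` is asserted in tests.

## GWR

Distances are exact Euclidean distances from cell centers to the nearest
pixel center of the target class, in km. Risk is regressed on distance to
water and distance to impervious surfaces as two separate univariate
local regressions by default (a joint fit is a one-line change — pass
both columns), with a Gaussian kernel and a fixed bandwidth selected by
golden-section search on AICc. Singular local designs fall back to a tiny
ridge penalty with a warning. With bandwidth → ∞ the fit provably
collapses to pooled OLS (tested to 1e-6).

## Synthetic data

The neutral generator thresholds a Gaussian-filtered noise field at
class-proportion quantiles: realized shares match targets to ±2 % and the
smoothing scale controls patch size/count. It exists to exercise every
pipeline stage under known conditions.

The oasis scenario paints, in order, a wasteland matrix, a buffered
sinuous river centerline ending in a terminal-lake disc, a grassland halo
within a fixed distance of water, and compact cropland and town patches.
Defaults model a 50 × 50 km desert basin at 200 m resolution (400 sample
cells): desert ≈ 90 % of the area, grassland ≈ 8 %, water ≈ 1.3 %,
cropland and settlements < 1 % — the composition regime of an arid
endorheic basin. Geometry is exact by default so the painted water area
matches the analytic buffer + disc area to rasterization error; an
optional boundary-roughness field (single seed, shared across epochs so
masks nest) adds ecotone irregularity at the cost of that analytic
ground truth. The conveyance series widens the corridor and lake
monotonically (defaults +0.25 km and +0.4 km per epoch over 4 epochs)
with the halo tracking the water — an idealized rewetting trajectory.

What the scenario does *not* emulate: classification speckle and
mixed-pixel noise of real satellite-derived maps, hydrological realism
(no flow routing, no groundwater), gradual vegetation transitions, or
multi-class confusion. Passing tests therefore demonstrate correctness
of the computational chain and the direction of the rewetting response
under clean geometry, not calibration against any real basin.

Under these conditions the rewetting trend is as expected — study-wide
mean ERI and the very-high class share (fixed breaks) decline as the
corridor widens — but the *static* zonal contrast "halo cells below
pure-desert cells" does not hold: the sliver-penalty floor described
above keeps the average of corridor-crossed cells slightly above the
uniform-desert baseline (0.120 vs 0.113 at defaults). Only cell
populations dominated by coherent grassland drop below it. The
corresponding acceptance check is left failing deliberately rather than
redefining the zones or re-shaping the landscape to force it.

## Problem sizes and determinism

Default analysis sizes — 400 cells, 62 500 kriging targets, 999
permutations, AICc bandwidth search over ~400 local fits — run in seconds
to a few tens of seconds on one core; the test suite uses a 30 × 30 km
reduction of the scenario for pipeline tests. All randomness flows from
explicit seeds (scenario config, permutation inference); reruns with the
same config are byte-identical, and every run writes a manifest with the
config hash, seed and library versions.
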