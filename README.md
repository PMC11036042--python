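# lerisk — grid-based landscape ecological risk assessment

`lerisk` assesses the ecological risk of arid-land landscapes from
categorical land-cover rasters. It is aimed at landscape ecologists and
GIS analysts studying desertified river basins — in particular endorheic
systems where engineered ecological water conveyance (EWC) rewets a dried
river corridor and terminal lake — who want a reproducible, scriptable
version of the standard "landscape index → risk grid → interpolation →
cluster/driver analysis" workflow.

## The method

The study area is partitioned into square sample cells (default 2.5 km).
Within each cell and for each land-cover class *i* (cropland, impervious,
grassland, water, wasteland), patches are delineated as connected
components and three structural indices are computed from patch count
`n_i`, class area `A_i` (km²), class perimeter `P_i` (km), and the cell's
valid area `A`:

```
fragmentation  C_i = n_i / A_i
isolation      N_i = (A / 2A_i) · √(n_i / A)
dominance      D_i = (P_i/P_tot + n_i/N_tot)/4 + (A_i/A)/2
```

These combine into a disturbance index `E_i = a·C_i + b·N_i + c·D_i` with
weights `(a, b, c) = (0.5, 0.3, 0.2)`, and, together with a normalized
vulnerability score `V_i` (rank-based: wasteland most vulnerable, then
water, grassland, impervious, cropland; `V_i = (6 − rank)/15`), into the
per-cell **Ecological Risk Index**

```
ERI = Σ_i (A_i / A) · E_i · V_i
```

evaluated at the cell center. Cell-center ERI points are then

* interpolated to a continuous surface by **ordinary kriging** with a
  fitted semivariogram,
* classified into five risk levels (very low … very high) by **Jenks
  natural breaks**, with class-area percentages tabulated,
* tested for spatial clustering with **global and local Moran's I**
  (permutation inference, HH/LL/HL/LH labels), and
* regressed on per-cell **distance to water** and **distance to
  impervious surfaces** with **geographically weighted regression** (GWR,
  AICc-selected bandwidth) to map proximity drivers of risk.

A synthetic-landscape module generates both neutral (filtered-noise)
land-cover rasters and a stylized desert–river–oasis scenario with a
widening-corridor time series, so the whole pipeline is testable without
satellite data.

## Worked example

```python
import lerisk as lr

raster, truth = lr.oasis_scenario()          # 50 x 50 km, 200 m pixels
result = lr.assess_epoch(raster)

print(f"cells: {result.grid.n_cells}")
print(f"mean ERI: {result.risk.cells['eri'].mean():.4f}")
print(f"global Moran's I: {result.moran.I:.3f} (p={result.moran.p_sim:.3f})")
print(result.risk_surface.percentages.round(2))
```

prints

```
cells: 400
mean ERI: 0.1140
global Moran's I: 0.000 (p=0.991)
very low      0.87
low           5.27
moderate     81.59
high          7.87
very high     4.40
Name: percent_area, dtype: float64
```

The mean ERI of 0.114 sits just above the closed-form value of a pure
single-patch desert cell (`V_wasteland · 0.34 = 0.1133`), because cells
crossed by the thin water corridor carry extra fragmentation and
isolation; 81.6 % of the surface falls in the moderate class that contains
the uniform desert matrix, the low tail is the coherent oasis interior,
and the high tail is the corridor-fragmented cells. Global Moran's I is
indistinguishable from zero here: risk variation is confined to the narrow
corridor band, which contributes too few of the 400 cells to produce
grid-wide autocorrelation. The same objects expose the
full component chain (`result.risk.per_class`), the LISA table
(`result.lisa.table`) and the GWR fits (`result.gwr_fits["water"]`).

The same workflow is available from the shell:

```bash
lerisk generate --out lc.asc --seed 1
lerisk assess --raster lc.asc --outdir out/
lerisk series --rasters lc_0.asc --rasters lc_1.asc --fix-breaks --outdir out/
```

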