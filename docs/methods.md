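# Methods

## Model structure and assumptions

The model is a deterministic, expert-weighted habitat/pressure/vulnerability
index stack on a regular metric grid (10 × 10 km cells by default). It makes
no statistical fit: all constants are exogenous — expert land-use scores and
published physiological breakpoints — and the package's job is to apply them
reproducibly. Consequences worth keeping in mind:

- Scores are *relative favourability indices*, not calibrated probabilities
  or abundances. Only orderings and spatial patterns are meaningful.
- The presence score is multiplicative (`Y4 = Y1·Y2·Y3`): any hostile factor
  (cold month, dry month, unsuitable land use, no water accumulation) zeroes
  the cell for that month. This is an ecological AND, deliberately
  conservative.
- Vulnerability (`Y10`) is threat-independent: densely populated cells score
  high even where no vector could live; risk only appears in the products
  `Y11–Y13`.
- The same district ITN density `D` raises resistance pressure (`Y6`) and
  lowers vulnerability (`Y9`). This duality is intended and is asserted by a
  cross-module test (the ITN sweep: `Y6`, `Y12` rise while `Y9`, `Y11` fall).

## Parameters

All constants live in `ModelParams` (YAML-overridable); none is hard-coded
in the math.

| parameter | default | units | meaning |
|---|---|---|---|
| `temp_breaks` | (15, 28, 33, 36) | °C | larval development: onset, optimum plateau, lethal max |
| `rain_breaks` | (40, 400, 800) | mm/month | breeding-habitat creation vs washout |
| `itn_zero`, `itn_full` | 0.05, 0.5 | nets/person | no-effect and saturation ITN densities (shared by Y6 and Y9) |
| `y9_floor` | 0.25 | – | residual vulnerability at full net coverage (not everyone uses a net) |
| `pop_scale`, `poverty_scale` | 5000, 1000 | persons | arctan scales of Y8a / Y8b |
| `y7_weights` | (0.9, 0.1) | – | agricultural vs ITN insecticide pressure |
| `y8_weights` | (1, 3) | – | density vs poverty weighting in Y8 |
| `month_aggregate` | mean | – | month reduction for the headline Y4 (max also available) |
| `twi_combiner` | multiply | – | how the wetness index modulates Y3a and Y5a |

The arctan population responses saturate *below* 1 (≈ 0.705 at P = 10,000);
the printed formulas are taken as normative rather than their prose gloss
("tends to 1").

The expert weight table (60 land-use classes, three species suitability
weights 0–10 and an insecticide-intensity score 1–4 each) ships as a
versioned CSV (`anophrisk/data/landuse_weights.csv`) so it can be audited or
replaced for other regions. Unknown land-use codes default to a=0 / b=1 with
a logged warning (configurable to a hard error).

## Terrain: topographic wetness index

`Y3` and `Y5` use the TOPMODEL wetness index ln(a / tan β):

- exact priority-flood pit filling (no epsilon gradient — plateaus are kept
  and resolved by the router, so a filled pit floor sits exactly at its
  spill level);
- D8 single-direction routing to the steepest strictly-lower neighbour;
  ties resolve to the lowest direction code in the fixed scan order E, SE,
  S, SW, W, NW, N, NE; plateau cells drain toward the nearest spill point by
  breadth-first distance within the plateau; boundary cells without a lower
  in-grid neighbour drain off-grid. These rules make routing fully
  deterministic and the flow graph provably acyclic (accumulation runs in
  topological order and errors on any cycle);
- `a` = flow accumulation per unit contour length (contour length = one
  pixel width); `tan β` = the downslope gradient toward the D8 receiver,
  floored at 0.001 so flats stay finite (standard TOPMODEL practice);
- the index is computed at DEM resolution, averaged per analysis cell, then
  min-max normalised to [0, 1] *across the cells of the analysis region*
  (a constant field maps to 0.5). Min-max normalisation is this package's
  choice; the combiner is pluggable (`multiply`, the default, zeroes scores
  where no water accumulates; `modulate` = 0.5 + 0.5·t never removes more
  than half).

D8 (rather than multiple-flow-direction) routing was chosen because it is
the simplest defensible reading of "water received from upstream" and is
checkable against an exhaustive path-walking oracle, which the test suite
does on every random 8 × 8 DEM it generates.

## Grid engine

- Cell inclusion: any positive-area intersection with the region polygon
  (not a centroid rule), with the grid origin snapped to cell-size
  multiples, so cell ids are reproducible and boundary cells are kept.
- Land-use proportions use the classified area of the cell as denominator,
  so Σ spᵢ = 1 also in partially covered boundary cells; a raster path
  (pixel counting) and an exact polygon-overlay path are both provided and
  cross-checked in tests.
- Village points integrate into half-open cells (a point on a shared edge
  counts exactly once; total population is conserved exactly).
- ITN counts exist only per district: each cell inherits its district's
  per-capita density, districts being assigned by dominant overlap area and
  district population being the sum of its cells' village populations.
  Zero-population districts yield D = 0 with a logged warning.
- District summaries are intersection-area-weighted means of cell values;
  district incidence = confirmed cases / integrated district population.
- Point-based village integration is the default; a polygon-weighted
  variant was considered and left out (the source data are point lists).

## Synthetic study regions

The generator produces structural stand-ins, not imitations of any real
geography: its purpose is that every downstream branch is exercised and
every claimed invariant is testable offline.

- **Defaults**: 120 × 120 km extent at 1 km resolution (144 analysis
  cells), 9 districts (Voronoi partition — realistic district area for the
  region size), 150 villages in clusters (Clark–Evans index < 1),
  populations log-uniform on [100, 8000], poverty fractions uniform on
  [0.05, 0.8], district per-capita ITN densities spread evenly over
  [0, 0.6] nets/person.
- **Land use** is a smoothed Gaussian field cut at its own quantiles, so
  target area fractions are hit nearly exactly while patches stay
  contiguous; the default mix (forest, paddy, scrub, mixed agriculture,
  wetland, water, coffee, urban, high-insecticide orchard) covers every
  insecticide score 1–4 and the full suitability range.
- **Climate**: 12 monthly ranges sweeping a full seasonal cycle across
  *every* regime of the temperature and rainfall responses (months below
  15 °C, on the 28–33 °C plateau, above 36 °C; below 40 mm, near 400 mm,
  above 800 mm). Fields are smooth by construction (additional smoothing
  passes enforce a ≤ 5 %-of-range pixel-to-pixel jump bound).
- **DEM**: multi-octave smoothed noise on a gentle westward regional tilt
  (guaranteeing a boundary outlet), or a deterministic inclined plane for
  routing oracles.
- **Incidence**: district malaria cases are Poisson draws whose rate
  follows the district's true environmental hazard in the synthetic world
  (land-use suitability weighted by terrain wetness, spread over
  0.002–0.032 cases/person-year). The presence–incidence correlation is
  therefore positive by construction but noisy: with ~9 districts, a
  handful of which may lack villages (incidence undefined), the Pearson r
  varies widely across seeds. The pipeline reports whatever it computes.
- Every generator draws from an independent, CRC-keyed random stream of the
  scenario seed, so outputs are bit-identical across runs and across
  regeneration order.

What passing tests on these scenarios does **not** show: realism of any
particular score level for a real country, behaviour under reprojection or
misaligned rasters (all synthetic layers share one metric CRS and grid
alignment), or the effect of land-use classification error. Real-data runs
go through `external_data.load_study_inputs` (documented plain-text layer
layout) and exercise exactly the same code path.

## Numerical choices

- Piecewise responses implement left-closed intervals exactly as printed;
  continuity at every breakpoint (verified to 1e-9) makes the boundary
  choice value-irrelevant. The Y9 slope is parameterised as
  (itn_full − itn_zero)/(1 − y9_floor), which reproduces the printed 0.6
  divisor and keeps the floor exactly continuous at saturation.
- Missing data propagate as NaN: a month without climate yields a missing
  monthly Y4, aggregates use available months; cells with no classified
  land use get missing Y1/Y5a; risks with any missing component are
  missing.
- Zonal means weight pixels by assignment of their centers to cells, exact
  for grid-aligned square pixels; the polygon overlay path is exact
  geometry.
- The Pearson correlation requires ≥ 3 districts with both values and
  reports NaN (never a crash) for degenerate variance.
- Display surfaces use inverse-distance weighting (power 2, 12 nearest cell
  centers, exact at cell centers) on a 1 km raster clipped to the region;
  they are presentation-only and never feed statistics.

## Problem sizes

Default test and acceptance runs use the 120 × 120 km scenario (144 cells,
14,400 DEM pixels) and 40–60 km variants for sweeps; flow-routing oracles
run on 8 × 8–10 × 10 DEMs where exhaustive enumeration is exact. These
sizes exercise every code path; the pipeline scales linearly in pixels and
cells for larger regions.

## Known limitations

- Expert weights are exogenous; nothing here validates them against
  entomological collections.
- No insecticide-class resolution, no indoor residual spraying term, no
  mosquito population dynamics — the outputs are environmental risk
  indices.
- The wetness-index normalisation domain is the analysis region, so scores
  are not comparable across differently-bounded runs.
- 10 km cells mix urban cores with peri-urban fringes; vulnerability in
  urban cells should be read with that aggregation scale in mind.
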