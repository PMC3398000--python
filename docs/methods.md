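# Methods

## The model

`wildcorridor` implements focal-species least-cost-path (LCP) corridor
modelling for a tiger dispersing between two protected areas. Movement
difficulty across the landscape is expressed as a composite movement cost
raster

    CM = W_H·H + W_S·S + W_WS·WS + W_TE·TE + W_RD·RD + W_R·R

where the six layers are integer cost ranks produced by reclassifying raw
landscape quantities through published rank tables:

| layer | raw quantity | ranking |
|---|---|---|
| H | habitat class | Bamboo Mixed 1 · Teak Mixed 2 · Mixed Bamboo 2 · Miscellaneous 3 · Teak 4 · Non-Forest 10 |
| WS | distance to perennial water | 0 at <1 km rising 1/km to 7 at ≥7 km; cells **on** water are barriers (10) |
| RD | PCU-weighted road line density (pcu/m) | 0 absent · 2 low (0–4) · 5 medium (4–6) · 10 high (≥6) |
| R | railway presence | 10 present · 0 absent |
| S | population point density (pop/m²) | 0 absent · 3 low (<0.001) · 6 moderate (0.001–0.0015) · 10 high (≥0.0015) |
| TE | Total Edge per hexagon (m) | 0 below 27 000 · 4 to 35 000 · 6 to 59 000 · 8 to 77 000 · 10 above |

The habitat ranking is grounded in field prey abundance: pellet-group
densities per habitat class, ranked per ungulate species and summed to a
cumulative preference order (bamboo-dominated classes most preferred, pure
teak least).

Importance weights come from a five-expert questionnaire scoring seven
movement parameters 0–5. Cover (forest-cover continuity) maps to the edge
weight `W_TE`, food/prey to the habitat weight `W_H`, water to `W_WS`,
habitation to `W_S`, roads to `W_RD`, railway to `W_R`; slope is dropped
(experts scored it near zero and the model has no slope layer). Three run
options bracket the elicited variability:

* **RO1** — all six weights 1 (equal importance).
* **RO2** — expert E2's column verbatim: TE 5, H 4, S 3, WS 2, RD 1, R 0.
  The narrative listing of "3, 2 and 1" for the remaining variables is
  ambiguous; the E2 ratings column resolves it directly.
* **RO3** — habitat, edge and water doubled (2) against a baseline of 1.
  "Did not get any weights" is read as weight 1, not 0, because the option
  contrasts "twice as important" against baseline importance.

No weight normalisation is applied; weights enter the linear combination as
given. Positive rescaling of all weights provably leaves the arg-min route
unchanged, and the test suite checks this end to end.

## Numerical conventions

* **Grids.** Planar metres, no CRS mathematics; row 0 is the northernmost
  row; cells addressed (row, col), 0-based. Default cell size for synthetic
  runs is 100 m; the model is scale-tolerant. All distances are measured
  cell-centre to cell-centre; sub-cell geometry is ignored, matching the
  resolution of the raster LCP.
* **Cost tables.** Numeric categories are half-open intervals [lo, hi) —
  a density exactly on a boundary takes the higher-cost bin — and the last
  interval is closed above, so values beyond observed ranges clamp to the
  top category. Exact zero density is always the separate "Absent" rank 0.
* **Cost distance.** Dijkstra over the 8-connected cell graph; stepping
  between adjacent cells a, b costs `(cm[a]+cm[b])/2 × (1 | √2)` — the
  standard GIS cost-distance convention (4-connectivity available).
  Neighbours are visited in the fixed order N, NE, E, SE, S, SW, W, NW and
  the priority queue is insertion-stable, so accumulation is reproducible.
* **Tracing and ties.** A traced path descends the accumulated-cost
  surface, at each cell choosing the neighbour minimising
  `acc + transition` with a relative tolerance of 1e-9; ties resolve to the
  first neighbour in the fixed order. Because both terms scale linearly,
  the chosen route is invariant under positive scaling of the cost surface
  despite floating-point noise. On exact-cost plateaus (all-zero cost) the
  stored backlink supplies the direction, which is an acyclic tree, so
  tracing always terminates.
* **Density kernels.** Line density clips each segment to the search
  circle in closed form (quadratic roots), so cell values are exact, not
  sampled; point density is an exact neighbour sum. The search radius is a
  parameter (default 1 000 m); the source analysis never stated its kernel
  radius, so absolute road densities are reproducible only up to that
  choice — the categorisation machinery is what is tested. Note the PCU
  ranges of the road table imply traffic volumes in the thousands of
  PCU per segment at a 1 km radius.
* **Total Edge.** Measured on the raster as rook-adjacency class
  transitions × cell edge length — the raster-mode FRAGSTATS equivalent of
  the polygon metric. The landscape boundary contributes no edge (boundary
  proportion 0). Hexagon units are flat-top, width (flat-to-flat) 2 000 m
  by default; cell centres are assigned by axial cube-rounding, which
  partitions the grid exactly, and a pair straddling two hexagons is
  counted once, for the hexagon of the lexicographically smaller cell, so
  per-hexagon TE sums exactly to whole-landscape TE. TE below the first
  published bin edge (100 m) maps to cost 0 for continuity.
* **Euclidean distance.** `scipy.ndimage.distance_transform_edt` (exact
  EDT), verified against a brute-force minimum-over-sources oracle.
* **Weak links.** Forest width at a path cell is operationalised as twice
  the distance to the nearest non-forest cell (the source analysis reports
  widths without a formula). Maximal runs of path cells below the width
  threshold (default 4 km) are flagged; a run whose hexagon edge cost
  reaches 8 is attributed to fragmentation rather than constriction.
* **Corridor buffer.** Union of per-cell discs, radius 6 km (default) in
  continuous forest and 2 km inside weak links, tapering linearly at 1 km
  of radius per km along the path.
* **Water gaps.** Path cells farther than 5 km (default) from perennial
  water form gap spans; waterholes are proposed greedily from each gap's
  midpoint outwards at 2×5 km spacing, which guarantees no path cell
  remains beyond the limit (along-path distance bounds Euclidean distance).
  The source analysis lists proposed sites without an algorithm; the
  greedy rule is this package's choice.

## Pellet-survey analysis

Plots are 10 m × 2 m belt-transect strips (20 m²), five per 0.5 km
transect at 100 m spacing; the reference design is 79 transects = 395
plots. A pellet group is a cluster of more than five pellets from one
defecation; for latrine-forming species (nilgai, chowsingha) all groups at
one spot count once. Mean groups/plot per (habitat, species) carry a
standard error using the sample (n−1) standard deviation (the estimator
was unstated; n−1 is the conventional choice), undefined at n = 1.
Per-hectare conversion is ×500 exactly (10 000/20). Ranking uses
fractional (mean-of-positions) ranks for ties — the source is silent on
ties — and zero densities share the worst rank; an all-zero species
contributes equal ranks everywhere. The cumulative order sorts ascending
rank sums, alphabetical on ties for determinism.

## What the synthetic generator emulates — and what it does not

The real inputs (classified LISS III imagery, Survey of India base layers,
traffic PCU and census attributes, the field pellet survey) are
proprietary, so every input is emulated, seeded, and bit-reproducible:

* habitat mosaic from thresholded smoothed Gaussian random fields
  (autocorrelation scale 1.5 km default), class fractions hit exactly by
  quantile thresholding (default 75% forest across five classes);
* two rectangular parks forced to forest; road polylines with PCU drawn
  from 1 000–12 000; one railway; clustered settlements with populations
  50–1 500; perennial streams and tanks;
* optionally a **planted channel**: a straight corridor of the best
  habitat class between the park peripheries, the best class withheld from
  the matrix, streams hugging both channel edges (water within 1 km of
  every channel cell, no open water on it), and roads/rail/settlements
  cleared from a 2.5 km buffer around channel and parks. Every channel
  cell then scores the best value in all six layers and every off-channel
  matrix cell is strictly worse, making channel recovery a ground-truth
  test of the whole chain;
* optional **necks**: strips across the channel where forest is cut back
  to a stated width, the band inside padded to forest so the measured
  neck width equals the planted width;
* pellet counts drawn negative-binomial (dispersion 2 by default;
  Poisson in the large-dispersion limit) with intensities =
  species base rate × habitat multiplier (2.5, 1.6, 1.0, 0.6, 0.3 down the
  preference order), transects allocated to habitat classes by
  largest-remainder proportionality to class area.

What passing tests on these landscapes shows: the machinery — rasterised
layer construction, reclassification, weighting, accumulation, tracing,
flagging — behaves correctly where the truth is known. What it does not
show: that the cost ranks or weights are ecologically right for any real
landscape, nor the real-geography corridor lengths (the published 145–171
km segment figures depend on proprietary layers at a different extent and
are out of reach at desk scale). The generator makes no attempt to mimic
the actual Kanha–Pench geography.

## Problem sizes

Synthetic runs in the tests and the acceptance script use 18 km × 10 km
landscapes at 100 m cells (180 × 100 grid), three start cells and one
source cell, 50-seed survey recovery experiments, 100 random grids for the
accumulation oracle and 30 masks for the distance oracle. These sizes keep
a full run in seconds while leaving every code path exercised; the
pipeline itself handles larger grids (Dijkstra is the bottleneck,
~O(n log n) in cells).

## Known limitations

* Cost ranks, weights and category boundaries are expert-derived
  constants, not fitted to telemetry; no sensitivity analysis beyond the
  three run options is built in.
* The density kernel radius and hexagon width are unknowns of the source
  analysis; results depending on them are comparable only within one
  parameterisation.
* Corridor width from the distance transform is a raster approximation
  (quantised to the cell size, measured perpendicular only in effect).
* No circuit-theory connectivity, no multi-species optimisation, no land
  acquisition or ecotourism analyses.
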