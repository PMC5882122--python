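# Methods

## Model

The Landscape Integrity Index is an equal-weight combination of three
normalized indicators on a shared 90-m, north-up, square-pixel grid in a
projected CRS (meters), followed by a circular 1-km moving-window mean. All
indicators share one orientation — 0 is degraded, 1 is intact — so the
combination is a plain weighted average.

### Human Influence Index

Each of 16 human land-use layers is modelled independently:

1. the layer's features are rasterized to a binary presence grid (points
   and lines mark every cell their geometry touches; polygons mark cells
   whose center they cover);
2. a Euclidean distance transform gives each cell its center-to-center
   distance `d` (m) to the nearest presence cell (presence cells hold 0;
   a layer with no features gives `d = +inf` everywhere);
3. a distance-decay curve maps `d` to intactness in `[s, 1]`.

Two curve families are used, chosen per layer by the presumed severity of
the land use. The linear family is `s + (1 − s)·min(d, D)/D`. The logistic
family starts from the raw S-curve `f(d) = 1/(1 + exp(−k(d − D/2)))` with
`k = 2·ln((1−ε)/ε)/D`, so that `f(0) = ε` and `f(D) = 1 − ε`, then rescales
affinely to map `[ε, 1−ε]` onto `[s, 1]` and clamps at 1 beyond `D`. The
rescaling makes both families hit the endpoints *exactly* — `s` at the
feature, 1 at the distance of influence — which the tests assert at machine
precision. The tail tolerance `ε` defaults to 0.01 and only shapes the
steepness of the logistic midsection; the curve's midpoint value is always
`(s + 1)/2` at `D/2`. Whether the original analyses clamped their logistic
at `D` or let it approach 1 asymptotically is not documented anywhere we
could find; clamping is our choice, and it is what makes the endpoint law
exact.

Distances of influence are capped at 4 km — the distance beyond which
effects of development on wildlife are rarely measurable — and the config
loader rejects larger values unless explicitly overridden.

The composite HII is the cellwise **minimum** over the 16 layer surfaces:
the most impacting land use governs each cell. Nodata in any layer
propagates to the composite.

### Species richness

Per-species categorical suitability rasters (240-m grid, integer codes)
are binarized against a caller-supplied set of "suitable" codes. The code
levels of real gap-analysis products are not standardized, so the suitable
set is a required configuration input; the shipped convention is "any
nonzero category is suitable". Binaries are summed cellwise and the counts
min–max normalized over the valid cells of the analysis extent (the
observed range, not a theoretical one — richness has no absolute scale).
If richness is uniform, the surface carries no information; a neutral
constant 0.5 is emitted with a warning rather than dividing by zero, so a
degenerate indicator cannot bias the combination in either direction.

### Vegetation departure

The departure raster (30-m grid) measures, 0–100, how far current
vegetation has moved from reference conditions. Its indicator is the fixed
range inverse `(100 − v)/100`. Unlike richness, the [0, 100] range is
absolute, so the theoretical range is used: zero departure must always map
to full integrity regardless of what the extent happens to contain.

### Combination and smoothing

Richness (240 m) and departure (30 m) are resampled to the 90-m grid by
bilinear interpolation of cell centers (nearest-neighbour is used for
categorical data); grids snap to the HII grid's pixel lattice and extents
are harmonized by cropping to the intersection. The three indicators are
averaged with equal weights (weights are configurable and must sum to 1)
and the result smoothed by a moving-window mean: each cell becomes the mean
of valid cells whose centers lie within 1 km of its center.

Two orders are possible — smooth each indicator then average, or average
then smooth. Because both operations are linear they commute exactly
wherever the window footprints coincide (a property the tests assert to
1e-12 on random fields); averaging first needs one focal pass instead of
three, so that is the implementation. The window is circular
(center-distance ≤ radius), the isotropic choice and the common default of
focal-statistics tools; a square window is available behind a flag. The
window truncates at grid edges and skips nodata cells, so border values are
means over the cells actually present.

### Summary statistics

The surface is summarized at random cell centers sampled uniformly without
replacement (stratified by polygon layers where given, e.g. ownership class
or protected/unprotected), deterministically from a seed. Group comparisons
use a one-way ANOVA across ownership classes and Welch's unequal-variance
t-test between protection levels, both via scipy. All-pairs post-hoc
comparison uses a permutation approximation of the Tukey studentized-range
null: the familywise reference distribution is the maximum pairwise range
statistic under random relabelling of the pooled sample (10,000 permutations
by default, seeded). This is self-contained and deterministic, at the cost
of Monte-Carlo noise in p-values near the significance boundary relative to
table-based HSD; groups not significantly different at α share a letter in
the compact letter display (insert-and-absorb construction).

### Conservation planning

**Corridors.** The integrity surface is described as the corridor
resistance layer, yet corridors are meant to follow the land of *highest*
integrity — using LII literally as resistance would route them through
degraded land. The default transform is therefore `resistance =
max(1 − LII, 1e-6)`; the literal transform is available behind a flag. The
floor keeps edge weights strictly positive so accumulated costs are well
defined. Accumulated cost from each priority area is a shortest-path
computation on the 8-connected grid graph with edge weight = mean of the
two cell resistances × center-to-center distance in pixel units (1
orthogonal, √2 diagonal), computed with scikit-image's geometric
minimum-cost-path solver and verified against an explicit-graph Dijkstra
oracle. For a pair of areas, `cost_A + cost_B − min(cost_A + cost_B)` is 0
exactly along the least-cost path and grows with detour cost. The corridor
network takes, per cell, the best (minimum) value across all area pairs and
selects the lowest-valued `round(0.30 × N)` cells of the `N` valid cells
outside priority areas — "highest-value 30%" read as the 30% closest to the
least-cost optimum. Ties at the quantile boundary break deterministically
in row-major order, which also makes selections nested across fractions.
All pairs of priority areas are linked by default; a pair list can be
supplied when only a subset of links is wanted.

**Expansion.** Cells with LII strictly above the threshold (default 0.70,
the upper-30% cutoff of a regional integrity distribution) outside the
priority areas are grouped into 8-connected components; components sharing
at least one edge or corner with a priority-area cell are kept, and areas
are reported in km² (cell count × pixel area). "Adjacent" is read as
8-connectivity.

## Synthetic landscapes

The generator emulates the structural properties the pipeline consumes, at
desk scale: random road/powerline polylines crossing the extent, settlement
and land-cover polygons, tower and mine points (all 16 configured layers
receive a collection, possibly empty); per-species smooth random fields
thresholded into categorical suitability codes on the 240-m grid, with the
true richness counts retained for oracle tests; a Gaussian-smoothed
departure field rescaled to [0, 100] on the 30-m grid, with correlation
length set by `vdep_smoothness`; and non-overlapping priority-area
polygons plus a three-strip ownership partition.

Defaults sketch a rural valley: a 9 km × 9 km extent (100 × 100 cells at
90 m, small enough for the brute-force O(n²) test oracles), a sparse road
network (6 primitive roads, 3 local roads, 1 highway), 3 small settlements,
2 towers, 2 powerlines, 2 mines, about 20% of the land in agriculture or
grazing, 20 species, 5 priority areas. One integer seed drives a splittable
generator — each sub-generator derives its stream from (seed, stream-id) —
so outputs are bit-reproducible and adding a generator never perturbs
existing ones.

What the synthetic landscape does *not* emulate: realistic road topology,
settlement-size distributions, the semantics of real land-cover classes,
or the spatial extent of a real region. The last point matters for
interpretation: a 1-km moving window on a 9-km extent averages a large
share of the grid into every cell, compressing the integrity surface
toward its mean. Desk-scale runs therefore rarely produce cells above the
0.70 expansion threshold, and the expansion result is often empty at
default settings — the adjacency and threshold contracts are exercised on
constructed surfaces in the tests. Passing tests demonstrate the
correctness of the operations and their contracts, not that a particular
real region has any particular integrity distribution.

## Numerical choices and limitations

- Distances are computed center-to-center on the grid, not sub-pixel to
  the original geometry; rasterization resolution bounds the error at half
  a pixel diagonal.
- Bilinear resampling interpolates between the four surrounding source
  cell centers, clamping to the margin beyond the outermost centers;
  target cells outside the source extent, or whose interpolation stencil
  touches nodata, become nodata.
- `focal_mean` agrees with a nested-loop oracle to 1e-10; distance
  transform, composite minimum, richness stacking and cost distance agree
  with their oracles exactly.
- GeoTIFF values are written float32; round-trips are bit-exact for
  float32 values. No CRS reprojection is performed — all inputs must share
  a projected meter CRS. Vector I/O is GeoJSON only.
- Statistics assume independent samples; no spatial-autocorrelation
  correction is applied to the t-test or ANOVA, so p-values on smooth
  surfaces are optimistic.
- The permutation post-hoc needs the group sizes to be moderate (its cost
  is permutations × pairwise statistics) and its letters can flicker for
  pairs with p ≈ α; increase `n_permutations` for tighter decisions.
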