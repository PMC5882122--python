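# landintegrity

A modelling framework for mapping **landscape ecological integrity** and
applying it to regional conservation planning.

Land managers increasingly plan conservation and mitigation at the landscape
scale, using geospatial indicators of how intact an ecosystem is. This
package implements a Landscape Integrity Index (LII) built from three
indicators on a common 90-m grid:

1. **Human Influence Index (HII).** Each of 16 mapped human land uses
   (roads, development, towers, powerlines, mines, agriculture, grazing, …)
   is parameterized by a *site impact score* `s ∈ (0, 1]` (intactness at the
   feature itself; lower = greater impact) and a *distance of influence*
   `D ≤ 4 km`. The Euclidean distance `d` from every cell to the nearest
   feature is mapped through a distance-decay curve — linear,
   `s + (1 − s)·min(d, D)/D`, or a logistic S-curve rescaled to hit exactly
   `s` at `d = 0` and `1` at `d = D`. The composite HII is the **cellwise
   minimum** across the 16 layer surfaces.
2. **Species richness.** Per-species categorical habitat-suitability rasters
   (240 m) are binarized (suitable / not), summed cellwise, and min–max
   normalized to [0, 1].
3. **Inverse vegetation departure.** A 0–100 vegetation-departure raster
   (30 m; how far current vegetation has moved from reference conditions) is
   mapped to `(100 − VDEP)/100`.

All three are resampled to the 90-m grid and combined with equal weights,
then smoothed with a 1-km circular moving-window mean:

    LII = focal_mean( (HII + R_norm + VDEP_inv) / 3 , radius = 1 km )

Two planning applications run on the result:

- **Least-cost corridors** between protected priority areas (GAP status 1–2)
  over the resistance surface `1 − LII`: for each pair, the summed
  accumulated-cost surface is shifted so the optimal path sits at 0, and the
  corridor network is the best 30% of valid land outside the priority areas.
- **Protected-area expansion**: 8-connected components of cells with
  `LII > 0.70` that touch the existing priority-area network.

A seeded synthetic-landscape generator produces complete input sets (vector
land-use layers, habitat stacks with retained richness ground truth,
autocorrelated departure fields, priority areas and ownership polygons) so
the whole pipeline is testable without external data.

## Worked example

Run the full pipeline on the default 9 km × 9 km synthetic landscape
(100 × 100 cells at 90 m, 5 priority areas):

```bash
lii pipeline --seed 42 --out-dir demo/
```

prints

```json
{
  "seed": 42,
  "corridor_fraction_selected": 0.29998924384209963,
  "expansion_total_area_km2": 0.0,
  "n_priority_areas": 5,
  "lii_mean": 0.4711560074061208
}
```

and writes `hii.tif`, `lii.tif`, `corridor_network.tif` and `expansion.tif`.
Reading the numbers: the corridor network covers 30% of the valid land
outside the five priority areas (2,789 of 9,297 cells — the request is met
to within one cell); mean integrity on this landscape is 0.47, i.e. a
moderately modified landscape; and no 8-connected patch above the 0.70
integrity threshold touches a priority area at this seed — the 1-km window
at a 9-km extent smooths the surface toward its mean, so desk-scale
landscapes rarely produce the extreme values a 25,000-km² region does.

The stages are also available individually (`lii synth`, `lii build-hii`,
`lii richness`, `lii vdep`, `lii compute`, `lii stats`, `lii corridors`,
`lii expand`) and as library functions:

```python
import landintegrity as li

spec = li.LandscapeSpec(seed=42)
result = li.run_pipeline(spec)
result.lii.values          # Raster in [0, 1] on the 90-m grid
result.corridors[0].pair   # ('pa0', 'pa1') least-cost corridor surface
```

The per-layer decay parameterization ships as an editable YAML file
(`landintegrity/data/default_layers.yaml`); `lii build-hii --config`
accepts overrides without code changes.

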