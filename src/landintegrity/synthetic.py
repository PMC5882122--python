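"""Seeded synthetic-landscape generator.

Emulates, at desk scale, the complete input set the integrity model
consumes: vector human land-use layers for all 16 configured inputs (road
polylines, utility lines, tower and mine points, settlement and land-cover
polygons), a stack of per-species categorical habitat-suitability rasters on
a 240-m grid with retained richness ground truth, a spatially autocorrelated
vegetation-departure field on a 30-m grid, non-overlapping priority-area
polygons tagged with GAP status, and a three-class land-ownership partition.

The default extent is 9 km x 9 km (100 x 100 cells at 90 m) — small enough
that brute-force test oracles stay tractable while every pipeline stage is
exercised. The defaults sketch a rural valley landscape: a sparse road
network, a few small settlements, and roughly a fifth of the land in
agriculture or grazing.

One integer seed drives everything; each sub-generator derives its own
independent stream from (seed, stream-id), so adding a generator never
perturbs the output of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, box

from .grid import GridSpec, Raster
from .integrity_layers import HabitatModel
from .planning import PriorityArea

# stable stream ids: appending new generators never reshuffles old streams
_STREAMS = {"features": 0, "habitat": 1, "vdep": 2, "priority": 3}

HABITAT_CODES = frozenset({0, 1, 2, 3})


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of one synthetic landscape (all reproducible from seed)."""

    seed: int = 42
    width_m: float = 9000.0
    height_m: float = 9000.0
    pixel_size: float = 90.0
    n_primitive_roads: int = 6
    n_local_roads: int = 3
    n_major_highways: int = 1
    n_settlements: int = 3
    n_towers: int = 2
    n_powerlines: int = 2
    n_mines: int = 2
    agriculture_fraction: float = 0.20
    n_species: int = 20
    n_priority_areas: int = 5
    vdep_smoothness: float = 500.0
    crs_id: str = "synthetic-m"

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.height_m <= 0:
            raise ValueError("degenerate extent")
        if not (0 <= self.agriculture_fraction <= 1):
            raise ValueError("agriculture_fraction must be in [0, 1]")

    def model_grid(self) -> GridSpec:
        """The 90-m analysis grid."""
        return self._grid(self.pixel_size)

    def habitat_grid(self) -> GridSpec:
        return self._grid(240.0)

    def vdep_grid(self) -> GridSpec:
        return self._grid(30.0)

    def _grid(self, px: float) -> GridSpec:
        return GridSpec(
            x_origin=0.0,
            y_origin=self.height_m,
            pixel_size=px,
            n_rows=max(int(math.ceil(self.height_m / px)), 1),
            n_cols=max(int(math.ceil(self.width_m / px)), 1),
            crs_id=self.crs_id,
        )


def _rng(spec: LandscapeSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((spec.seed, _STREAMS[stream]))
    )


# ---------------------------------------------------------------------------
# Human land-use features
# ---------------------------------------------------------------------------

def _random_polyline(rng, w, h, n_vertices=5) -> LineString:
    """A wiggly line crossing the extent between two random boundary points."""
    # pick entry/exit on opposite sides
    if rng.random() < 0.5:  # west-east
        p0 = (0.0, rng.uniform(0, h))
        p1 = (w, rng.uniform(0, h))
    else:  # north-south
        p0 = (rng.uniform(0, w), h)
        p1 = (rng.uniform(0, w), 0.0)
    ts = np.linspace(0, 1, n_vertices)
    jitter = rng.normal(0, 0.05 * min(w, h), size=(n_vertices, 2))
    jitter[0] = jitter[-1] = 0
    pts = np.outer(1 - ts, p0) + np.outer(ts, p1) + jitter
    pts[:, 0] = np.clip(pts[:, 0], 0, w)
    pts[:, 1] = np.clip(pts[:, 1], 0, h)
    return LineString(pts)


def _random_patch(rng, w, h, min_size, max_size) -> shapely.Polygon:
    sx = rng.uniform(min_size, max_size)
    sy = rng.uniform(min_size, max_size)
    cx = rng.uniform(sx / 2, w - sx / 2)
    cy = rng.uniform(sy / 2, h - sy / 2)
    return box(cx - sx / 2, cy - sy / 2, cx + sx / 2, cy + sy / 2)


def generate_features(spec: LandscapeSpec) -> dict[str, list]:
    """Vector collections for every configured human land-use layer.

    Every one of the 16 layer names receives a (possibly empty) list of
    shapely geometries. Reproducible from the spec seed.
    """
    rng = _rng(spec, "features")
    w, h = spec.width_m, spec.height_m
    feats: dict[str, list] = {}

    feats["primitive_roads"] = [
        _random_polyline(rng, w, h) for _ in range(spec.n_primitive_roads)
    ]
    feats["local_roads"] = [
        _random_polyline(rng, w, h) for _ in range(spec.n_local_roads)
    ]
    feats["major_highways"] = [
        _random_polyline(rng, w, h, n_vertices=3) for _ in range(spec.n_major_highways)
    ]

    # settlements: low-density patches, with one denser core when there are
    # several settlements (rural valley: high-density development is rare)
    low, med, high = [], [], []
    for i in range(spec.n_settlements):
        patch = _random_patch(rng, w, h, 300, 900)
        low.append(patch)
        if i == 0 and spec.n_settlements >= 2:
            med.append(_random_patch(rng, w, h, 200, 400))
    feats["low_density_development"] = low
    feats["medium_density_development"] = med
    feats["high_density_development"] = high
    feats["urban_polygons"] = [shapely.buffer(p.centroid, 250) for p in med]
    feats["high_impervious_surfaces"] = [
        shapely.buffer(p.centroid, 120) for p in med
    ]

    feats["communication_towers"] = [
        Point(rng.uniform(0, w), rng.uniform(0, h)) for _ in range(spec.n_towers)
    ]
    feats["powerlines"] = [
        _random_polyline(rng, w, h, n_vertices=3) for _ in range(spec.n_powerlines)
    ]
    feats["mines_wellpads"] = [
        Point(rng.uniform(0, w), rng.uniform(0, h)) for _ in range(spec.n_mines)
    ]

    # managed/modified land cover: patches until the agriculture fraction
    # of the extent is covered, split among cultivated, pasture and low/ag
    target = spec.agriculture_fraction * w * h
    ag_layers = {"cultivated_agriculture": [], "pasture": [],
                 "low_agriculture_invasives": []}
    names = list(ag_layers)
    covered = 0.0
    guard = 0
    while covered < target and guard < 200:
        patch = _random_patch(rng, w, h, 600, 1800)
        ag_layers[names[guard % 3]].append(patch)
        covered += patch.area
        guard += 1
    feats.update(ag_layers)
    feats["grazing_allotments"] = (
        [_random_patch(rng, w, h, 1200, 2400)] if target > 0 else []
    )
    feats["introduced_vegetation"] = (
        [_random_patch(rng, w, h, 300, 600)] if target > 0 else []
    )
    return feats


# ---------------------------------------------------------------------------
# Habitat stack and vegetation departure
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, sigma_px) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma_px > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    return noise


def generate_habitat_stack(
    spec: LandscapeSpec,
) -> tuple[list[HabitatModel], Raster]:
    """Per-species categorical suitability rasters on the 240-m grid.

    Each species gets a smooth random field thresholded into codes
    {0 no habitat, 1 low, 2 moderate, 3 high suitability}. Returns the stack
    and the retained ground-truth richness (count of species with any
    nonzero suitability per cell) for oracle tests.
    """
    if spec.n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _rng(spec, "habitat")
    grid = spec.habitat_grid()
    truth = np.zeros(grid.shape, dtype=np.float64)
    models = []
    for i in range(spec.n_species):
        f = _smooth_field(rng, grid.shape, sigma_px=2.0)
        qs = np.quantile(f, [0.5, 0.75, 0.9])
        codes = np.digitize(f, qs).astype(np.float64)  # 0..3, ~50% suitable
        truth += codes > 0
        models.append(
            HabitatModel(
                species_id=f"sp{i:03d}",
                suitability=Raster(grid, codes, nodata=-1.0),
                code_set=HABITAT_CODES,
            )
        )
    return models, Raster(grid, truth, nodata=-1.0)


def generate_vdep(spec: LandscapeSpec) -> Raster:
    """Spatially autocorrelated vegetation-departure field in [0, 100] on
    the 30-m grid; correlation length set by ``vdep_smoothness`` (m)."""
    rng = _rng(spec, "vdep")
    grid = spec.vdep_grid()
    sigma_px = spec.vdep_smoothness / grid.pixel_size
    f = _smooth_field(rng, grid.shape, sigma_px)
    lo, hi = f.min(), f.max()
    vals = (f - lo) / (hi - lo) * 100.0 if hi > lo else np.full(grid.shape, 50.0)
    return Raster(grid, vals, nodata=-1.0)


# ---------------------------------------------------------------------------
# Priority areas and ownership
# ---------------------------------------------------------------------------

def generate_priority_areas(
    spec: LandscapeSpec,
) -> tuple[list[PriorityArea], list[dict]]:
    """Non-overlapping priority-area polygons (GAP 1/2) plus a three-class
    ownership partition of the extent (Federal / Private / State strips)."""
    rng = _rng(spec, "priority")
    w, h = spec.width_m, spec.height_m
    areas: list[PriorityArea] = []
    placed: list[shapely.Polygon] = []
    guard = 0
    while len(areas) < spec.n_priority_areas and guard < 1000:
        guard += 1
        patch = _random_patch(rng, w, h, 500, 1400)
        if any(patch.intersects(p) for p in placed):
            continue
        placed.append(patch)
        areas.append(
            PriorityArea(
                id=f"pa{len(areas)}",
                geometry=patch,
                gap_status=int(rng.integers(1, 3)),
            )
        )
    if len(areas) < spec.n_priority_areas:
        raise RuntimeError("could not place non-overlapping priority areas")

    # ownership: two vertical cuts partition the extent into three strips
    cuts = np.sort(rng.uniform(0.2, 0.8, size=2)) * w
    ownership = [
        {"geometry": box(0, 0, cuts[0], h), "properties": {"label": "Federal"}},
        {"geometry": box(cuts[0], 0, cuts[1], h), "properties": {"label": "Private"}},
        {"geometry": box(cuts[1], 0, w, h), "properties": {"label": "State"}},
    ]
    return areas, ownership
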