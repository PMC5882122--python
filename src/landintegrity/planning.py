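"""Conservation-planning applications of the integrity surface: least-cost
corridors linking protected priority areas, and adjacency-constrained
expansion of the protected-area network onto high-integrity land.

Corridors run over a resistance surface derived from the integrity index.
Corridors are meant to follow the land of *highest* integrity, so resistance
is ``1 - LII`` (floored at a small positive value); the literal
use of LII itself as resistance is available behind a flag for comparison.
For each pair of priority areas the accumulated-cost surfaces from both
endpoints are summed and shifted so the least-cost path sits at 0; the
corridor network is the best (lowest) such value per cell, thresholded to
take a fixed fraction (default 30%) of the valid land outside the priority
areas.

Expansion finds connected components of cells above an integrity threshold
(default 0.70, the upper 30% of the study-area distribution) that touch the
existing priority-area network (8-connectivity).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from skimage.graph import MCP_Geometric

from .grid import GridSpec, Raster, rasterize_features
from .lii import LiiSurface

DEFAULT_RESISTANCE_FLOOR = 1e-6
DEFAULT_CORRIDOR_FRACTION = 0.30
DEFAULT_EXPANSION_THRESHOLD = 0.70


@dataclass
class PriorityArea:
    """A protected priority area: polygon + GAP status (1 or 2 = managed
    for biodiversity)."""

    id: str
    geometry: shapely.geometry.base.BaseGeometry
    gap_status: int

    def __post_init__(self) -> None:
        if self.gap_status not in (1, 2):
            raise ValueError(
                f"priority areas require GAP status 1 or 2, got {self.gap_status}"
            )
        if self.geometry.is_empty:
            raise ValueError(f"priority area {self.id!r} has empty geometry")


@dataclass
class CorridorResult:
    pair: tuple[str, str]
    cost_a: Raster
    cost_b: Raster
    corridor_value: Raster


@dataclass
class ExpansionResult:
    threshold: float
    mask: Raster
    regions: list[dict] = field(default_factory=list)
    total_area_km2: float = 0.0


# ---------------------------------------------------------------------------
# Resistance and cost distance
# ---------------------------------------------------------------------------

def resistance_from_lii(
    lii: LiiSurface, floor: float = DEFAULT_RESISTANCE_FLOOR, literal: bool = False
) -> Raster:
    """Resistance surface for corridor routing: ``max(1 - LII, floor)``.

    High integrity means low travel cost. ``literal=True`` instead uses the
    LII value itself as resistance (floored), which routes corridors through
    *degraded* land and is provided only for comparison.
    """
    if floor <= 0:
        raise ValueError("resistance floor must be positive")
    r = lii.values
    vals = np.asarray(r.values, dtype=np.float64)
    res = np.where(r.valid_mask,
                   np.maximum(vals if literal else 1.0 - vals, floor),
                   np.inf)
    return Raster(r.grid, res, nodata=np.inf)


def cost_distance(resistance: Raster, sources: Raster) -> Raster:
    """Minimum accumulated cost from any source cell over 8-connected moves.

    Edge cost between neighboring cells is the mean of their resistances
    times the center-to-center distance in pixel units (1 orthogonal,
    sqrt(2) diagonal). Source cells cost 0; cells unreachable from any
    source are +inf.
    """
    res = np.asarray(resistance.values, dtype=np.float64)
    if np.any(res[np.isfinite(res)] <= 0):
        raise ValueError("resistance must be strictly positive")
    src = np.asarray(sources.values) == 1
    if not src.any():
        raise ValueError("cost_distance: no source cells")
    costs = np.where(resistance.valid_mask & np.isfinite(res), res, -1.0)
    mcp = MCP_Geometric(costs, fully_connected=True)
    cum, _ = mcp.find_costs(list(zip(*np.nonzero(src))))
    return Raster(resistance.grid, cum, nodata=np.inf)


# ---------------------------------------------------------------------------
# Corridors
# ---------------------------------------------------------------------------

def corridor_surface(cost_a: Raster, cost_b: Raster) -> Raster:
    """Summed accumulated costs shifted so the least-cost path sits at 0."""
    if cost_a.grid != cost_b.grid:
        raise ValueError("corridor_surface: cost surfaces on different grids")
    total = np.asarray(cost_a.values, dtype=np.float64) + np.asarray(
        cost_b.values, dtype=np.float64
    )
    finite = np.isfinite(total)
    if not finite.any():
        raise ValueError("corridor_surface: endpoints mutually unreachable")
    return Raster(cost_a.grid, total - total[finite].min(), nodata=np.inf)


def rasterize_priority_areas(areas: list[PriorityArea], grid: GridSpec) -> Raster:
    """Binary cell-center-in-polygon mask of the priority-area network."""
    return rasterize_features(
        [a.geometry for a in areas], grid
    )


def pairwise_corridors(
    resistance: Raster,
    areas: list[PriorityArea],
    pairs: list[tuple[str, str]] | None = None,
) -> list[CorridorResult]:
    """Least-cost corridor surface for each pair of priority areas
    (all pairs by default)."""
    by_id = {a.id: a for a in areas}
    if pairs is None:
        pairs = [(a.id, b.id) for a, b in itertools.combinations(areas, 2)]
    cost_cache: dict[str, Raster] = {}

    def cost_for(area_id: str) -> Raster:
        if area_id not in cost_cache:
            src = rasterize_features([by_id[area_id].geometry], resistance.grid)
            cost_cache[area_id] = cost_distance(resistance, src)
        return cost_cache[area_id]

    results = []
    for ida, idb in pairs:
        ca, cb = cost_for(ida), cost_for(idb)
        results.append(
            CorridorResult(pair=(ida, idb), cost_a=ca, cost_b=cb,
                           corridor_value=corridor_surface(ca, cb))
        )
    return results


def select_corridors(
    corridors: list[Raster],
    priority_mask: Raster,
    fraction: float = DEFAULT_CORRIDOR_FRACTION,
    valid_mask: np.ndarray | None = None,
) -> Raster:
    """Select the corridor network: the given fraction of valid non-priority
    land with corridor values closest to the least-cost optimum.

    The per-cell value is the minimum corridor value across all pairs
    (best corridor wins); the lowest-valued cells are selected up to
    ``round(fraction * n_valid_non_priority)`` cells. Ties at the quantile
    boundary break deterministically in row-major order, which also makes
    the selection nested in ``fraction``. Least-cost-path cells hold value
    0, the best rank, so they are always selected.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if not corridors:
        raise ValueError("no corridor surfaces supplied")
    grid = corridors[0].grid
    best = np.min(
        np.stack([np.asarray(c.values, dtype=np.float64) for c in corridors]), axis=0
    )
    pmask = np.asarray(priority_mask.values) == 1
    eligible = ~pmask & np.isfinite(best)
    if valid_mask is not None:
        eligible &= valid_mask
    n_eligible = int(eligible.sum())
    k = int(round(fraction * n_eligible))
    out = np.zeros(grid.shape, dtype=np.float64)
    if k > 0 and n_eligible > 0:
        flat_vals = np.where(eligible, best, np.inf).ravel()
        order = np.argsort(flat_vals, kind="stable")  # row-major tie-break
        sel = order[:k]
        out.ravel()[sel] = 1.0
    return Raster(grid, out, nodata=-1.0)


# ---------------------------------------------------------------------------
# Protected-area expansion
# ---------------------------------------------------------------------------

def expansion_areas(
    lii: LiiSurface,
    priority_mask: Raster,
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
) -> ExpansionResult:
    """High-integrity land adjacent to the priority-area network.

    Cells with LII strictly above ``threshold`` outside the priority areas
    are grouped into 8-connected components; only components touching the
    priority mask (edge or corner) are kept. Areas are cell count times
    pixel area, in km².
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    r = lii.values
    grid = r.grid
    pmask = np.asarray(priority_mask.values) == 1
    high = r.valid_mask & (np.asarray(r.values, dtype=np.float64) > threshold) & ~pmask

    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    labels, n_labels = ndimage.label(high, structure=structure)
    touch = ndimage.binary_dilation(pmask, structure=structure)
    adjacent_labels = np.unique(labels[touch & (labels > 0)])

    cell_km2 = (grid.pixel_size / 1000.0) ** 2
    keep = np.isin(labels, adjacent_labels) & (labels > 0)
    regions = []
    for lab in adjacent_labels:
        n_cells = int((labels == lab).sum())
        regions.append({"label": int(lab), "n_cells": n_cells,
                        "area_km2": n_cells * cell_km2})
    total = float(sum(rg["area_km2"] for rg in regions))
    mask = Raster(grid, keep.astype(np.float64), nodata=-1.0)
    return ExpansionResult(threshold=threshold, mask=mask, regions=regions,
                           total_area_km2=total)
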