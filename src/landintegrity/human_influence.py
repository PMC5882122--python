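"""Human Influence Index (HII): per-layer Euclidean-distance surfaces,
distance-decay intactness curves, and the minimum composite.

Each human land-use layer is rasterized to a binary presence grid, turned
into a distance-to-nearest-feature surface, and mapped through a
distance-decay curve giving an intactness value in [s, 1]: the site impact
score s right at the feature, rising to 1.0 at the layer's distance of
influence D. The composite HII is the cellwise minimum across layers — the
most impacting land use governs each cell.

Two decay families are used. The *linear* curve is

    f(d) = s + (1 - s) * min(d, D) / D.

The *logistic* curve is a symmetric S-curve with midpoint D/2. Its raw form
``1 / (1 + exp(-k (d - D/2)))`` with ``k = 2 ln((1-eps)/eps) / D`` takes the
values eps at d=0 and 1-eps at d=D; an affine rescaling maps that span onto
[s, 1] so the curve is *exactly* s at 0 and exactly 1 at D, and it is
clamped at 1 beyond D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import DecayParams, Raster


@dataclass(frozen=True)
class DecayCurve:
    """A distance-decay intactness curve for one layer.

    ``epsilon`` is the raw logistic tail mass at d=0 and d=D before
    rescaling; it controls the steepness of the S-curve (smaller epsilon =
    steeper midsection) and is ignored by the linear family.
    """

    params: DecayParams
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.epsilon < 0.5):
            raise ValueError(f"epsilon must be in (0, 0.5), got {self.epsilon}")

    def __call__(self, d):
        return decay_value(d, self)


def euclidean_distance(presence: Raster) -> Raster:
    """Distance (m) from each cell center to the nearest presence cell center.

    Presence cells hold 0. With no presence anywhere, every cell is +inf —
    downstream decay maps that to full intactness. Nodata presence cells are
    treated as absence for the distance computation.
    """
    vals = np.asarray(presence.values, dtype=np.float64)
    pres = (vals == 1) & presence.valid_mask
    uniq = np.unique(vals[presence.valid_mask])
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"presence raster is not binary; values include {uniq[:5]}")
    if not pres.any():
        dist = np.full(presence.grid.shape, np.inf)
    else:
        px = presence.grid.pixel_size
        dist = ndimage.distance_transform_edt(~pres, sampling=(px, px))
    return Raster(presence.grid, dist, nodata=-1.0)


def decay_value(d, curve: DecayCurve):
    """Intactness at distance(s) ``d`` (m) under the given decay curve.

    Scalar in, scalar out; array in, array out. Values are in
    [site_impact, 1], monotone non-decreasing in d, exactly ``site_impact``
    at d=0 and exactly 1 at d >= D. +inf distances map to 1.
    """
    d_arr = np.asarray(d, dtype=np.float64)
    if np.any(d_arr[~np.isnan(d_arr)] < 0):
        raise ValueError("distances must be non-negative")
    s = curve.params.site_impact
    D = curve.params.distance_of_influence
    if curve.params.family == "linear":
        out = s + (1.0 - s) * np.minimum(d_arr, D) / D
    else:
        eps = curve.epsilon
        k = 2.0 * np.log((1.0 - eps) / eps) / D
        with np.errstate(over="ignore"):
            raw = 1.0 / (1.0 + np.exp(-k * (np.minimum(d_arr, D) - D / 2.0)))
        out = s + (1.0 - s) * (raw - eps) / (1.0 - 2.0 * eps)
        out = np.clip(out, None, 1.0)
    out = np.where(np.isinf(d_arr), 1.0, out)
    if np.isscalar(d) or np.ndim(d) == 0:
        return float(out)
    return out


def layer_hii(presence: Raster, curve: DecayCurve) -> Raster:
    """Intactness surface for one layer: decay applied to its distance
    surface. Nodata cells in the presence raster propagate to the output."""
    dist = euclidean_distance(presence)
    vals = decay_value(dist.values, curve)
    nodata = -1.0
    vals = np.where(presence.valid_mask, vals, nodata)
    return Raster(presence.grid, vals, nodata=nodata)


def composite_hii(layers: list[Raster]) -> Raster:
    """Cellwise minimum across layer intactness surfaces.

    The most impacting layer governs each cell. Nodata in any layer makes
    the composite nodata there.
    """
    if not layers:
        raise ValueError("composite_hii requires at least one layer")
    grid = layers[0].grid
    for lyr in layers[1:]:
        if lyr.grid != grid:
            raise ValueError("composite_hii: layers are not on a common grid")
    nodata = -1.0
    stack = np.stack([np.asarray(l.values, dtype=np.float64) for l in layers])
    valid = np.stack([l.valid_mask for l in layers]).all(axis=0)
    out = np.where(valid, np.min(stack, axis=0), nodata)
    return Raster(grid, out, nodata=nodata)


def build_hii(
    presence_layers: dict[str, Raster],
    configs,
    epsilon: float = 0.01,
) -> tuple[Raster, dict[str, Raster]]:
    """Run the per-layer decay model for every configured layer and compose.

    ``presence_layers`` maps layer name -> binary presence raster on the
    model grid; every configured layer must be present (an empty layer is an
    all-zero raster). Returns (composite, per-layer surfaces).
    """
    per_layer: dict[str, Raster] = {}
    for cfg in configs:
        if cfg.name not in presence_layers:
            raise KeyError(f"no presence raster supplied for layer {cfg.name!r}")
        curve = DecayCurve(cfg.decay, epsilon=epsilon)
        per_layer[cfg.name] = layer_hii(presence_layers[cfg.name], curve)
    return composite_hii(list(per_layer.values())), per_layer
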