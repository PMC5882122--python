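"""Raster/vector data model, GeoTIFF and GeoJSON I/O, rasterization and grid
harmonization.

The raster model is deliberately small: a :class:`GridSpec` describing a
north-up, square-pixel grid in a projected CRS (meters), and a
:class:`Raster` pairing a grid with a 2-D value array and a nodata sentinel.
Row 0 is the northernmost row; cells are addressed ``(row, col)``, 0-based,
and a cell's value represents its center.

GeoTIFF files are read and written through :mod:`tifffile` using the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA); only
single-band, square-pixel rasters are supported.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
import tifffile
import yaml
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("landintegrity")

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0

#: Hard cap on a layer's distance of influence (m): beyond this distance
#: human land uses are assumed not to reduce intactness.
MAX_DISTANCE_OF_INFLUENCE = 4000.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """North-up raster grid: square pixels, projected coordinates in meters.

    ``(x_origin, y_origin)`` is the outer corner of cell (0, 0) — the
    north-west corner of the grid.
    """

    x_origin: float
    y_origin: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.pixel_size,
            self.x_origin + self.n_cols * self.pixel_size,
            self.y_origin,
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of cell centers (vectorized over row/col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_origin + (col + 0.5) * self.pixel_size
        y = self.y_origin - (row + 0.5) * self.pixel_size
        return x, y

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)


@dataclass
class Raster:
    """A single-band georeferenced grid of values.

    ``values`` has shape ``(grid.n_rows, grid.n_cols)``. Cells equal to
    ``nodata`` (or NaN) are invalid and are never silently folded into
    statistics.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Raster values must be a 2-D array")
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        vals = self.values
        mask = ~np.isnan(vals.astype(float, copy=False))
        if self.nodata is not None and not math.isnan(self.nodata):
            mask &= vals != self.nodata
        return mask

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=~self.valid_mask)

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        return Raster(self.grid, values, self.nodata if nodata is None else nodata)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.nodata)


DecayFamily = Literal["linear", "logistic"]
_FAMILIES = ("linear", "logistic")


@dataclass(frozen=True)
class DecayParams:
    """Distance-decay parameterization of one human land-use layer.

    ``site_impact`` (s) is the intactness value at zero distance from the
    feature — lower means greater impact. ``distance_of_influence`` (D, m)
    is the distance at which intactness reaches 1.0.
    """

    site_impact: float
    distance_of_influence: float
    family: DecayFamily

    def __post_init__(self) -> None:
        if not (0 < self.site_impact <= 1):
            raise ValueError(
                f"site_impact must be in (0, 1], got {self.site_impact}"
            )
        if self.distance_of_influence <= 0:
            raise ValueError(
                "distance_of_influence must be > 0, got "
                f"{self.distance_of_influence}"
            )
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown decay family {self.family!r}; expected one of {_FAMILIES}"
            )


GeometryKind = Literal["point", "line", "polygon", "raster_mask"]
_GEOMETRY_KINDS = ("point", "line", "polygon", "raster_mask")
LayerCategory = Literal["transportation", "urban_industrial", "managed_landcover"]
_CATEGORIES = ("transportation", "urban_industrial", "managed_landcover")


@dataclass(frozen=True)
class LayerConfig:
    """One human land-use input layer and its decay parameterization."""

    name: str
    category: LayerCategory
    geometry_kind: GeometryKind
    decay: DecayParams
    source_path: str | None = None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown layer category {self.category!r}")
        if self.geometry_kind not in _GEOMETRY_KINDS:
            raise ValueError(f"unknown geometry_kind {self.geometry_kind!r}")


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via tifffile)
# ---------------------------------------------------------------------------

def write_raster(r: Raster, path: str | Path) -> Path:
    """Write a Raster as a single-band float32 GeoTIFF.

    Georeferencing is stored in the ModelPixelScale/ModelTiepoint tags; the
    nodata value in GDAL_NODATA; the CRS identifier as GeoTIFF ASCII params.
    """
    path = Path(path)
    g = r.grid
    values = np.ascontiguousarray(r.values, dtype=np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.pixel_size, g.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_origin, g.y_origin, 0.0)),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, g.crs_id + "|"),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(r.nodata))),
    ]
    tifffile.imwrite(path, values, photometric="minisblack", extratags=extratags)
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a single-band georeferenced GeoTIFF into a Raster.

    Raises on multi-band files and non-square pixels.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-band (multi-page) rasters unsupported")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multi-band input ({page.samplesperpixel} samples)")
        values = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy})")
        tie = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint maps raster (i, j) -> map (x, y); we require the corner form
        i, j, _, x, y, _ = tie[:6]
        x_origin = x - i * sx
        y_origin = y + j * sy
        crs_id = "local"
        if _TAG_GEO_ASCII_PARAMS in tags:
            crs_id = str(tags[_TAG_GEO_ASCII_PARAMS].value).rstrip("|")
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value))
    grid = GridSpec(
        x_origin=float(x_origin),
        y_origin=float(y_origin),
        pixel_size=float(sx),
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        crs_id=crs_id,
    )
    return Raster(grid, values, nodata)


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON via shapely)
# ---------------------------------------------------------------------------

def read_geojson(path: str | Path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into a list of
    ``{"geometry": shapely geometry, "properties": dict}`` records."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return [
        {
            "geometry": geojson_shape(feat["geometry"]),
            "properties": feat.get("properties") or {},
        }
        for feat in data.get("features", [])
    ]


def write_geojson(
    features: Sequence[dict | BaseGeometry], path: str | Path
) -> Path:
    """Write shapely geometries (optionally with properties) as GeoJSON."""
    out = []
    for feat in features:
        if isinstance(feat, BaseGeometry):
            geom, props = feat, {}
        else:
            geom, props = feat["geometry"], feat.get("properties") or {}
        out.append(
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(geom),
                "properties": props,
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": out}, fh)
    return path


def _as_geometries(features: Iterable) -> list[BaseGeometry]:
    geoms = []
    for feat in features:
        if isinstance(feat, BaseGeometry):
            geoms.append(feat)
        elif isinstance(feat, dict) and "geometry" in feat:
            geoms.append(feat["geometry"])
        else:
            raise TypeError(f"not a geometry or feature record: {feat!r}")
    return geoms


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_features(features: Iterable, grid: GridSpec) -> Raster:
    """Burn vector features into a binary presence raster.

    Points and lines mark every cell whose square they touch; polygons mark
    cells whose *center* falls in (or on the boundary of) the polygon. An
    empty collection yields an all-zero raster with a logged warning: an
    area can legitimately lack a given land use.
    """
    geoms = _as_geometries(features)
    out = np.zeros(grid.shape, dtype=np.float64)
    if not geoms:
        logger.warning("rasterize_features: empty feature collection -> all-zero raster")
        return Raster(grid, out, nodata=DEFAULT_NODATA)

    px = grid.pixel_size
    xmin_g, ymin_g, xmax_g, ymax_g = grid.bounds
    cx, cy = grid.center_grids()

    for geom in geoms:
        if geom.is_empty:
            continue
        gxmin, gymin, gxmax, gymax = geom.bounds
        # candidate cell index window (clipped to the grid)
        c0 = max(int(math.floor((gxmin - xmin_g) / px)), 0)
        c1 = min(int(math.floor((gxmax - xmin_g) / px)), grid.n_cols - 1)
        r0 = max(int(math.floor((ymax_g - gymax) / px)), 0)
        r1 = min(int(math.floor((ymax_g - gymin) / px)), grid.n_rows - 1)
        if c1 < c0 or r1 < r0:
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        if _polygonal(geom):
            pts = shapely.points(cx[rr, cc].ravel(), cy[rr, cc].ravel())
            hit = shapely.covers(geom, pts).reshape(rr.shape)
        else:
            x0 = xmin_g + cc * px
            y1 = ymax_g - rr * px
            boxes = shapely.box(
                x0.ravel(), (y1 - px).ravel(), (x0 + px).ravel(), y1.ravel()
            )
            hit = shapely.intersects(geom, boxes).reshape(rr.shape)
        out[rr[hit], cc[hit]] = 1.0
    return Raster(grid, out, nodata=DEFAULT_NODATA)


def _polygonal(geom: BaseGeometry) -> bool:
    return geom.geom_type in ("Polygon", "MultiPolygon")


# ---------------------------------------------------------------------------
# Resampling and harmonization
# ---------------------------------------------------------------------------

def resample(
    r: Raster, target: GridSpec, method: Literal["nearest", "bilinear"] = "nearest"
) -> Raster:
    """Resample a raster onto a target grid by nearest-neighbour or bilinear
    interpolation of cell-center values.

    Nearest is appropriate for categorical/binary data, bilinear for
    continuous fields; both keep values within the source range. Target
    cells outside the source extent (or, for bilinear, touching nodata)
    become nodata.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    sxmin, symin, sxmax, symax = r.grid.bounds
    txmin, tymin, txmax, tymax = target.bounds
    if txmin >= sxmax or txmax <= sxmin or tymin >= symax or tymax <= symin:
        raise ValueError("target grid extent is disjoint from the source raster")

    tx, ty = target.center_grids()
    # fractional source indices of target cell centers
    fi = (r.grid.y_origin - ty) / r.grid.pixel_size - 0.5
    fj = (tx - r.grid.x_origin) / r.grid.pixel_size - 0.5

    nodata = float(r.nodata)
    out = np.full(target.shape, nodata, dtype=np.float64)

    if method == "nearest":
        ii = np.rint(fi).astype(int)
        jj = np.rint(fj).astype(int)
        inside = (ii >= 0) & (ii < r.grid.n_rows) & (jj >= 0) & (jj < r.grid.n_cols)
        out[inside] = np.asarray(r.values, dtype=np.float64)[ii[inside], jj[inside]]
    else:
        from scipy.ndimage import map_coordinates

        vals = np.asarray(r.values, dtype=np.float64)
        valid = r.valid_mask.astype(np.float64)
        vals_f = np.where(r.valid_mask, vals, 0.0)
        # clamp to edge cells so border centers interpolate from the margin
        fi_c = np.clip(fi, 0, r.grid.n_rows - 1)
        fj_c = np.clip(fj, 0, r.grid.n_cols - 1)
        coords = np.stack([fi_c.ravel(), fj_c.ravel()])
        num = map_coordinates(vals_f, coords, order=1, mode="nearest").reshape(target.shape)
        den = map_coordinates(valid, coords, order=1, mode="nearest").reshape(target.shape)
        inside = (
            (fi > -0.5) & (fi < r.grid.n_rows - 0.5)
            & (fj > -0.5) & (fj < r.grid.n_cols - 0.5)
        )
        ok = inside & (den >= 1.0 - 1e-12)
        out[ok] = num[ok] / den[ok]
    return Raster(target, out, nodata=nodata)


def snap_grid(template: GridSpec, bounds: tuple[float, float, float, float],
              pixel_size: float | None = None) -> GridSpec:
    """Build a grid covering ``bounds`` whose origin snaps to the template's
    pixel lattice. All model grids snap to the HII grid this way so that
    "equal extents" means the intersection of the inputs."""
    px = pixel_size or template.pixel_size
    xmin, ymin, xmax, ymax = bounds
    x0 = template.x_origin + math.floor((xmin - template.x_origin) / px) * px
    y0 = template.y_origin - math.floor((template.y_origin - ymax) / px) * px
    n_cols = max(int(math.ceil((xmax - x0) / px)), 1)
    n_rows = max(int(math.ceil((y0 - ymin) / px)), 1)
    return GridSpec(x0, y0, px, n_rows, n_cols, template.crs_id)


# ---------------------------------------------------------------------------
# Layer configuration
# ---------------------------------------------------------------------------

def _layer_from_record(rec: dict) -> LayerConfig:
    required = {"name", "category", "geometry_kind", "site_impact", "distance_m", "decay"}
    missing = required - rec.keys()
    if missing:
        raise ValueError(f"layer config entry missing fields: {sorted(missing)}")
    decay = DecayParams(
        site_impact=float(rec["site_impact"]),
        distance_of_influence=float(rec["distance_m"]),
        family=str(rec["decay"]),
    )
    return LayerConfig(
        name=str(rec["name"]),
        category=str(rec["category"]),
        geometry_kind=str(rec["geometry_kind"]),
        decay=decay,
        source_path=rec.get("source_path"),
    )


def load_layer_config(
    path: str | Path, max_distance: float = MAX_DISTANCE_OF_INFLUENCE,
    allow_long_range: bool = False,
) -> list[LayerConfig]:
    """Load a YAML layer configuration into LayerConfig records.

    Distances of influence beyond 4 km are rejected by default: effects of
    human development on wildlife are rarely measurable farther out, and the
    model treats 4 km as the global maximum. Pass ``allow_long_range=True``
    to override.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "layers" not in doc:
        raise ValueError(f"{path}: expected a top-level 'layers' list")
    layers = [_layer_from_record(rec) for rec in doc["layers"]]
    names = [lc.name for lc in layers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names in configuration")
    if not allow_long_range:
        for lc in layers:
            if lc.decay.distance_of_influence > max_distance:
                raise ValueError(
                    f"layer {lc.name!r}: distance of influence "
                    f"{lc.decay.distance_of_influence} m exceeds the "
                    f"{max_distance} m maximum (allow_long_range=True to override)"
                )
    return layers


def default_layer_config_path() -> Path:
    """Path of the shipped default (16-layer) configuration."""
    return Path(__file__).parent / "data" / "default_layers.yaml"


def default_layer_config() -> list[LayerConfig]:
    return load_layer_config(default_layer_config_path())
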