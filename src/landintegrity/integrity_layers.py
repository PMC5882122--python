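"""Non-footprint integrity indicators: stacked terrestrial-vertebrate species
richness and inverse vegetation departure, both normalized to [0, 1] on the
same low-to-high integrity gradient as the HII.

Richness comes from per-species categorical habitat-suitability rasters
(240-m grid): each is binarized on a declared set of "suitable" codes, the
binaries are summed cellwise, and the counts are min-max normalized over the
analysis extent. Vegetation departure (VDEP) is a 0-100 measure of how far
current vegetation has moved from reference conditions; the indicator is its
normalized inverse, (100 - VDEP) / 100, so 1 means unchanged vegetation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import Raster

logger = logging.getLogger("landintegrity")


@dataclass
class HabitatModel:
    """One species' categorical habitat-suitability raster."""

    species_id: str
    suitability: Raster
    code_set: frozenset[int] = frozenset({0, 1, 2, 3})


@dataclass
class RichnessSurface:
    counts: Raster
    normalized: Raster


@dataclass
class VdepSurface:
    raw: Raster
    normalized_inverse: Raster


def binarize_habitat(h: HabitatModel, suitable_codes: set[int]) -> Raster:
    """1 where the suitability code is in ``suitable_codes``, else 0.

    Nodata cells are preserved. Codes outside the model's declared code set
    are rejected.
    """
    suitable = set(suitable_codes)
    if not suitable:
        raise ValueError("suitable_codes must be non-empty")
    unknown = suitable - set(h.code_set)
    if unknown:
        raise ValueError(
            f"suitable_codes {sorted(unknown)} not in declared code set "
            f"{sorted(h.code_set)}"
        )
    r = h.suitability
    vals = np.asarray(r.values)
    out = np.isin(vals, sorted(suitable)).astype(np.float64)
    nodata = -1.0
    out = np.where(r.valid_mask, out, nodata)
    return Raster(r.grid, out, nodata=nodata)


def stack_richness(binaries: list[Raster]) -> RichnessSurface:
    """Cellwise sum of binary habitat layers, min-max normalized.

    Normalization uses the observed minimum and maximum counts over valid
    cells of the analysis extent. If every cell has the same count the
    surface carries no discriminating information; a neutral constant 0.5 is
    emitted with a warning rather than dividing by zero.
    """
    if not binaries:
        raise ValueError("stack_richness requires at least one binary layer")
    grid = binaries[0].grid
    for b in binaries[1:]:
        if b.grid != grid:
            raise ValueError("stack_richness: layers are not on a common grid")
    valid = np.stack([b.valid_mask for b in binaries]).all(axis=0)
    counts = np.zeros(grid.shape, dtype=np.float64)
    for b in binaries:
        counts += np.asarray(b.values, dtype=np.float64)
    nodata = -1.0
    counts = np.where(valid, counts, nodata)
    counts_r = Raster(grid, counts, nodata=nodata)

    cvalid = counts[valid]
    cmin, cmax = cvalid.min(), cvalid.max()
    if cmax == cmin:
        logger.warning(
            "stack_richness: uniform richness (%s everywhere); emitting a "
            "neutral constant 0.5 surface", cmin,
        )
        norm = np.full(grid.shape, 0.5)
    else:
        norm = (counts - cmin) / (cmax - cmin)
    norm = np.where(valid, norm, nodata)
    return RichnessSurface(counts=counts_r, normalized=Raster(grid, norm, nodata=nodata))


def normalize_inverse_vdep(v: Raster) -> VdepSurface:
    """Map vegetation departure in [0, 100] to integrity in [0, 1] by the
    fixed-range inverse (100 - v) / 100.

    The theoretical [0, 100] range is used (not the observed min-max):
    departure is an absolute scale, so 0 must always map to full integrity.
    """
    vals = np.asarray(v.values, dtype=np.float64)
    valid = v.valid_mask
    bad = valid & ((vals < 0) | (vals > 100))
    if bad.any():
        lo, hi = vals[bad].min(), vals[bad].max()
        raise ValueError(
            f"VDEP values outside [0, 100]: offending range [{lo}, {hi}]"
        )
    nodata = -1.0
    norm = np.where(valid, (100.0 - vals) / 100.0, nodata)
    return VdepSurface(raw=v, normalized_inverse=Raster(v.grid, norm, nodata=nodata))


def load_species_manifest(path) -> list[tuple[str, str]]:
    """Parse a species manifest: one ``species_id<TAB or space>raster_path``
    per line; blank lines and '#' comments ignored."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"bad manifest line: {line!r}")
            records.append((parts[0], parts[1]))
    return records
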