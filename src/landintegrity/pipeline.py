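"""End-to-end composition: synthetic (or supplied) inputs through HII,
richness and VDEP indicators, the moving-window LII, corridors and
protected-area expansion. Used by the CLI and by the acceptance checks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Raster, default_layer_config, rasterize_features, resample
from .human_influence import build_hii
from .integrity_layers import (HabitatModel, binarize_habitat,
                               normalize_inverse_vdep, stack_richness)
from .lii import LiiSurface, compute_lii
from .planning import (CorridorResult, ExpansionResult, PriorityArea,
                       DEFAULT_CORRIDOR_FRACTION, DEFAULT_EXPANSION_THRESHOLD,
                       expansion_areas, pairwise_corridors,
                       rasterize_priority_areas, resistance_from_lii,
                       select_corridors)
from .synthetic import (LandscapeSpec, generate_features,
                        generate_habitat_stack, generate_priority_areas,
                        generate_vdep)


@dataclass
class PipelineResult:
    hii: Raster
    richness_normalized: Raster
    vdep_normalized: Raster
    lii: LiiSurface
    priority_areas: list[PriorityArea]
    priority_mask: Raster
    ownership: list[dict]
    corridors: list[CorridorResult]
    corridor_mask: Raster
    corridor_fraction_selected: float
    expansion: ExpansionResult
    per_layer_hii: dict[str, Raster] = field(default_factory=dict)


def run_pipeline(
    spec: LandscapeSpec,
    corridor_fraction: float = DEFAULT_CORRIDOR_FRACTION,
    expansion_threshold: float = DEFAULT_EXPANSION_THRESHOLD,
    window_radius: float = 1000.0,
) -> PipelineResult:
    """Run the full model on a synthetic landscape."""
    grid = spec.model_grid()
    configs = default_layer_config()

    features = generate_features(spec)
    presence = {
        cfg.name: rasterize_features(features.get(cfg.name, []), grid)
        for cfg in configs
    }
    hii, per_layer = build_hii(presence, configs)

    models, _truth = generate_habitat_stack(spec)
    binaries = [binarize_habitat(m, {1, 2, 3}) for m in models]
    richness = stack_richness(binaries)
    richness_90 = resample(richness.normalized, grid, method="bilinear")

    vdep = generate_vdep(spec)
    vdep_norm = normalize_inverse_vdep(vdep).normalized_inverse
    vdep_90 = resample(vdep_norm, grid, method="bilinear")

    lii = compute_lii(hii, richness_90, vdep_90, radius=window_radius)

    areas, ownership = generate_priority_areas(spec)
    pmask = rasterize_priority_areas(areas, grid)
    resistance = resistance_from_lii(lii)
    corridors = pairwise_corridors(resistance, areas)
    corridor_mask = select_corridors(
        [c.corridor_value for c in corridors], pmask, fraction=corridor_fraction,
        valid_mask=lii.values.valid_mask,
    )
    eligible = lii.values.valid_mask & (np.asarray(pmask.values) != 1)
    frac = float(np.asarray(corridor_mask.values)[eligible].sum() / eligible.sum())

    expansion = expansion_areas(lii, pmask, threshold=expansion_threshold)

    return PipelineResult(
        hii=hii,
        richness_normalized=richness_90,
        vdep_normalized=vdep_90,
        lii=lii,
        priority_areas=areas,
        priority_mask=pmask,
        ownership=ownership,
        corridors=corridors,
        corridor_mask=corridor_mask,
        corridor_fraction_selected=frac,
        expansion=expansion,
        per_layer_hii=per_layer,
    )
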