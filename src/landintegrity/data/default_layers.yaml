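# Default Human Influence Index layer parameterization: 16 human land-use
# inputs, each with a site impact score (intactness at distance 0; lower =
# greater impact), a distance of influence in meters (distance at which
# intactness reaches 1.0), and a distance-decay family. High-stress inputs
# use logistic decay; low/moderate-stress inputs use linear or logistic.
layers:
  # --- Transportation ---
  - name: primitive_roads
    category: transportation
    geometry_kind: line
    site_impact: 0.75
    distance_m: 500
    decay: linear
  - name: local_roads
    category: transportation
    geometry_kind: line
    site_impact: 0.3
    distance_m: 1500
    decay: logistic
  - name: major_highways
    category: transportation
    geometry_kind: line
    site_impact: 0.015
    distance_m: 4000
    decay: logistic
  # --- Urban and industrial development ---
  - name: low_density_development
    category: urban_industrial
    geometry_kind: polygon
    site_impact: 0.6
    distance_m: 1000
    decay: logistic
  - name: medium_density_development
    category: urban_industrial
    geometry_kind: polygon
    site_impact: 0.35
    distance_m: 2000
    decay: logistic
  - name: high_density_development
    category: urban_industrial
    geometry_kind: polygon
    site_impact: 0.015
    distance_m: 4000
    decay: logistic
  - name: communication_towers
    category: urban_industrial
    geometry_kind: point
    site_impact: 0.6
    distance_m: 200
    decay: linear
  - name: powerlines
    category: urban_industrial
    geometry_kind: line
    site_impact: 0.6
    distance_m: 200
    decay: linear
  - name: mines_wellpads
    category: urban_industrial
    geometry_kind: point
    site_impact: 0.2
    distance_m: 1000
    decay: logistic
  - name: urban_polygons
    category: urban_industrial
    geometry_kind: polygon
    site_impact: 0.015
    distance_m: 4000
    decay: logistic
  - name: high_impervious_surfaces
    category: urban_industrial
    geometry_kind: raster_mask
    site_impact: 0.3
    distance_m: 1000
    decay: logistic
  # --- Managed and modified land cover ---
  - name: low_agriculture_invasives
    category: managed_landcover
    geometry_kind: raster_mask
    site_impact: 0.7
    distance_m: 500
    decay: linear
  - name: pasture
    category: managed_landcover
    geometry_kind: raster_mask
    site_impact: 0.7
    distance_m: 500
    decay: linear
  - name: grazing_allotments
    category: managed_landcover
    geometry_kind: polygon
    site_impact: 0.7
    distance_m: 500
    decay: linear
  - name: introduced_vegetation
    category: managed_landcover
    geometry_kind: raster_mask
    site_impact: 0.6
    distance_m: 500
    decay: linear
  - name: cultivated_agriculture
    category: managed_landcover
    geometry_kind: raster_mask
    site_impact: 0.35
    distance_m: 2000
    decay: linear
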