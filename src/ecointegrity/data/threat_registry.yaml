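# Default anthropogenic-threat registry: per-category magnitude of impact
# (0-1) and maximum impact distance (meters).  Impact decays linearly with
# distance and vanishes at the impact distance.
#
# magnitude_rule:
#   fixed            - magnitude used verbatim
#   attribute_scaled - magnitude mapped linearly from the observed range of
#                      `attribute` across the feature set onto magnitude_range
# distance_rule:
#   fixed             - impact_distance_m used verbatim
#   plant_size_scaled - distance = impact_distance_m * magnitude /
#                       distance_scale_reference, capped at impact_distance_m
version: "1.0"
threats:
  human_settlements:
    urban_area:
      magnitude: 0.65
      impact_distance_m: 10000
    village:
      magnitude: 0.35
      impact_distance_m: 3000
  mining:
    construction_material:
      magnitude: 0.6
      impact_distance_m: 5000
    metal:
      magnitude: 0.4
      impact_distance_m: 5000
    non_metal:
      magnitude: 0.1
      impact_distance_m: 5000
  agricultural_land_use:
    crops:
      magnitude: 0.6
      impact_distance_m: 5000
    mosaic_pastureland:
      magnitude: 0.4
      impact_distance_m: 5000
  hydroelectric_plants:
    operating_large:
      magnitude: 0.375
      impact_distance_m: 30000
      distance_rule: plant_size_scaled
      distance_scale_reference: 0.375
    operating_medium:
      magnitude: 0.225
      impact_distance_m: 30000
      distance_rule: plant_size_scaled
      distance_scale_reference: 0.375
    operating_small:
      magnitude: 0.15
      impact_distance_m: 30000
      distance_rule: plant_size_scaled
      distance_scale_reference: 0.375
    under_construction_large:
      magnitude: 0.125
      impact_distance_m: 30000
      distance_rule: plant_size_scaled
      distance_scale_reference: 0.375
    under_construction_medium:
      magnitude: 0.075
      impact_distance_m: 30000
      distance_rule: plant_size_scaled
      distance_scale_reference: 0.375
    under_construction_small:
      magnitude: 0.05
      impact_distance_m: 30000
      distance_rule: plant_size_scaled
      distance_scale_reference: 0.375
  thermoelectric_plants:
    default:
      magnitude: 1.0
      impact_distance_m: 2000
  oil_activities:
    well_operating:
      magnitude: 0.28
      impact_distance_m: 1500
    well_not_operating:
      magnitude: 0.07
      impact_distance_m: 1500
    spill_recent_high_volume:
      magnitude: 0.15
      impact_distance_m: 5000
    spill_recent_low_volume:
      magnitude: 0.09
      impact_distance_m: 5000
    spill_old_high_volume:
      magnitude: 0.075
      impact_distance_m: 5000
    spill_old_low_volume:
      magnitude: 0.015
      impact_distance_m: 5000
    pool_without_treatment:
      magnitude: 0.2
      impact_distance_m: 5000
    pool_recent_with_treatment:
      magnitude: 0.0625
      impact_distance_m: 5000
    pool_old_without_treatment:
      magnitude: 0.0125
      impact_distance_m: 5000
    pipeline_risky_area:
      magnitude: 0.07
      impact_distance_m: 30
    pipeline_out_of_risk:
      magnitude: 0.03
      impact_distance_m: 30
  water_withdrawals:
    default:
      magnitude: 1.0
      impact_distance_m: 1000
      magnitude_rule: attribute_scaled
      attribute: water_volume_m3
      magnitude_range: [0.1, 1.0]
  aquaculture_farms:
    default:
      magnitude: 1.0
      impact_distance_m: 1000
      magnitude_rule: attribute_scaled
      attribute: water_volume_m3
      magnitude_range: [0.1, 1.0]
  roads:
    primary:
      magnitude: 0.5
      impact_distance_m: 1000
    secondary:
      magnitude: 0.3
      impact_distance_m: 1000
    local:
      magnitude: 0.2
      impact_distance_m: 1000
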