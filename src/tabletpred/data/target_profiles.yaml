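# Per-target scalar-descriptor profiles.
#
# Each profile lists which composition-weighted mixture properties and
# engineered geometry/pressure features enter that target's descriptor
# block.  The 9 category ratios and their 21 pairwise interaction terms
# are always included.  Resulting block widths:
#   hardness 44, disintegration_time 45, flow_function 37, cohesion 37,
#   thickness 43.
hardness:
  scalars: [loose_bulk_density, tapped_density, carr_index, hausner_ratio,
            flodex, loss_on_drying, solubility_score, lipophilic_score,
            flowability_score]
  geometry: [r_part_height, r_part_volume, inv_weight, compaction_pressure]
  extras: [pressure_x_inv_weight]
disintegration_time:
  scalars: [loose_bulk_density, tapped_density, carr_index, hausner_ratio,
            flodex, loss_on_drying, solubility_score, lipophilic_score,
            flowability_score]
  geometry: [r_part_height, r_part_volume, inv_weight, compaction_pressure]
  extras: [pressure_x_inv_weight, lod_x_solubility]
flow_function:
  scalars: [loose_bulk_density, tapped_density, carr_index, hausner_ratio,
            flodex, loss_on_drying, flowability_score]
  geometry: []
  extras: []
cohesion:
  scalars: [loose_bulk_density, tapped_density, carr_index, hausner_ratio,
            flodex, loss_on_drying, flowability_score]
  geometry: []
  extras: []
thickness:
  scalars: [loose_bulk_density, tapped_density, carr_index, hausner_ratio,
            flodex, loss_on_drying, solubility_score, lipophilic_score,
            flowability_score]
  geometry: [r_part_height, r_part_volume, inv_weight, compaction_pressure]
  extras: []
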