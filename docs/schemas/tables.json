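{
  "materials.csv": {
    "primary_key": "material_id",
    "columns": {
      "material_id": "string, unique",
      "category": "enum: diluent|disintegrant|polyol|lubricant|binder|glidant|granule|main_component|other",
      "loose_bulk_density": "float g/mL > 0, nullable",
      "tapped_density": "float g/mL >= loose_bulk_density, nullable",
      "carr_index": "float % in [0,100), nullable",
      "hausner_ratio": "float >= 1, nullable",
      "flodex": "float mm, nullable",
      "loss_on_drying": "float %, nullable",
      "solubility_score": "ordinal int, nullable",
      "lipophilic_score": "ordinal int, nullable",
      "flowability_score": "ordinal int, nullable"
    }
  },
  "psd.csv": {
    "primary_key": "material_id",
    "layout": "wide: material_id + 80 frequency columns on the shared grid; or long: (material_id, diameter_um, frequency)",
    "constraints": "frequencies nonnegative, each material sums to 1 within 1e-9"
  },
  "compositions.csv": {
    "columns": {
      "formulation_id": "string",
      "material_id": "string, must exist in materials.csv",
      "mass_fraction": "float >= 0; fractions of a formulation sum to 1 within 1e-9 (renormalized with a warning within 1e-3)"
    }
  },
  "process.csv": {
    "primary_key": "formulation_id",
    "columns": {
      "compaction_force_n": "float N > 0 (compaction_force_kgf accepted, converted x9.80665)",
      "punch_type": "categorical",
      "tablet_diameter_mm": "float mm > 0",
      "target_weight_g": "float g > 0",
      "curvature_radius_mm": "float mm, nullable (flat punch)",
      "fill_depth_mm": "float mm",
      "time_index": "int >= 0 acquisition order; file row order used with a warning when absent"
    }
  },
  "targets.csv": {
    "columns": {
      "formulation_id": "string, must exist in process.csv",
      "target": "enum: hardness|disintegration_time|flow_function|cohesion|thickness",
      "value": "float, finite; hardness/disintegration_time/thickness > 0"
    }
  }
}
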