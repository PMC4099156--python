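{
  "$comment": "Informational schema for mcrpcsim model parameter files (validation is performed by mcrpcsim.model_inputs.read_model, which reports the offending field).",
  "type": "object",
  "required": ["schema_version", "states"],
  "properties": {
    "schema_version": {"const": 1},
    "variant": {"enum": ["current", "alternate", "custom"]},
    "castration_monthly_cost": {"type": "number", "minimum": 0},
    "castration_coverage": {"type": "number", "minimum": 0, "maximum": 1},
    "bone_monthly_cost": {"type": "number", "minimum": 0},
    "bone_coverage": {"type": "number", "minimum": 0, "maximum": 1},
    "otherx_cap": {"type": "integer", "minimum": 1},
    "national_cohort": {"type": "integer", "minimum": 1},
    "initial_distribution": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["state", "fraction"],
        "properties": {
          "state": {"type": "string"},
          "fraction": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "states": {
      "type": "array",
      "minItems": 2,
      "items": {
        "type": "object",
        "required": ["name", "primary_monthly_cost", "min_cycles", "p_progress", "p_death"],
        "properties": {
          "name": {"type": "string"},
          "primary_monthly_cost": {"type": "number", "minimum": 0},
          "min_cycles": {"type": "integer", "minimum": 0},
          "p_progress": {"type": "number", "minimum": 0, "maximum": 1},
          "p_death": {"type": "number", "minimum": 0, "maximum": 1},
          "is_last_line": {"type": "boolean"},
          "cap_cycles": {"type": ["integer", "null"], "minimum": 1},
          "goes_to": {
            "type": ["array", "null"],
            "items": {
              "type": "object",
              "required": ["state", "fraction"],
              "properties": {
                "state": {"type": "string"},
                "fraction": {"type": "number", "minimum": 0, "maximum": 1}
              }
            }
          }
        }
      }
    }
  }
}
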